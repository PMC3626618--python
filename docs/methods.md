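# Methods

## What the package models

Ligand-based virtual screening is a binary classification problem with an
asymmetric data-collection reality: positives (actives) come from activity
databases, while negatives are *assumed* inactive and must be manufactured —
by random or diversity-driven selection from a broad commercial library, from
a narrower drug-like database, or as per-ligand property-matched decoys in
the DUD style. This package treats the negative-set construction itself as
the experimental variable and measures its effect on classifier performance
under two evaluation designs (a shared broad test set vs. test sets matched
to the training construction).

## The decoy builder

For each ligand, pool candidates must match the ligand's H-bond acceptor,
H-bond donor and rotatable-bond counts within an absolute tolerance
(default 0 — exact match) and its molecular weight and logP within a relative
tolerance (default 10 %); candidates with Tanimoto similarity ≥ 0.7 to the
ligand are discarded, and the 36 least-similar survivors are kept. Choices
the original procedure leaves open, fixed here:

* **Window anchoring.** The MW/logP windows are relative to the *ligand's*
  values (so they are mildly asymmetric between ligand and candidate).
* **logP near zero.** A relative window collapses as logP → 0; the effective
  half-width is `max(rel_tol·|logP|, 0.2)` log units. The 0.2 floor keeps the
  filter meaningful for neutral-logP ligands.
* **Cross-ligand duplicates.** De-duplication is first-claim-wins in actives
  order, and a ligand whose pick was already claimed does *not* refill the
  slot. This mirrors reported decoy totals that fall short of
  `ligands × 36`, and makes the builder order-deterministic.
* **Shortfalls** (fewer than 36 eligible candidates) are warnings carried in
  the per-ligand report, not errors; a build yielding zero decoys overall is
  an error that points at the relaxed window (±2 counts, ±20 %).
* **Similarity ties** break by pool order everywhere (stable sorts), so the
  whole build is reproducible and testable against a brute-force oracle.

## Subset selection

Random selection is a seeded uniform draw without replacement; replicate
`i` of a plan uses child seed `base·1000 + i`, recorded in every output.
Diversity selection is greedy MaxMin over Tanimoto distance: the first pick
maximises total distance to the library, each later pick maximises the
minimum distance to the picked set, ties by library order. MaxMin was chosen
as the surrogate for closed-source diversity pickers because it is the
canonical deterministic algorithm and matches their observed behaviour
(repeated runs return the identical subset, so diverse cells have a single
effective iteration). The first pick costs O(N²) similarity evaluations
(bit-packed popcount kernels keep this to seconds for N ≈ 10⁴).

## Dataset assembly

A plan freezes one random active train/test split and varies only the
inactives across cells — the controlled-variable design. In common-test mode
the per-iteration test inactives are drawn from the broad pool once and
shared by all sources; because decoy ids are broad-pool ids, deterministic
diverse training prefixes are reserved out of that draw and random training
draws exclude the test ids, keeping the common test identical across sources
while train/test stay disjoint. In various-test mode a single uniform draw
is split into train and test (random strategy), or the MaxMin ordering is
consumed train-first then test (diverse strategy) — deterministic and
disjoint; the ordering-based rule for the diverse test set is this package's
choice, as the original design is silent on it.

Default composition is 200/300 actives/inactives in training and 300/350 in
test, scaling the published target compositions (roughly 0.7 active:inactive
in train, 0.9 in test) to the synthetic universe; all counts are config.

## Classifiers

* **Bernoulli naive Bayes** with Laplace smoothing α = 1:
  `P(bit|class) = (count + α)/(n_class + 2α)`; decision by log-posterior
  ratio, ties to "active" (screening-oriented: recall-preserving).
* **k-NN** (default k = 1), brute-force search; squared Euclidean distance on
  binary vectors equals Hamming distance and is computed exactly on packed
  bits, so distance ties are integer-exact and break by training order; vote
  ties go to "active".
* **Hyperpipes**: per class and bit position, record which values were seen;
  score a query by the fraction of its bit values contained in the class
  pipe; ties go to the class appearing first in training order. On dense
  binary data with hundreds of training molecules both pipes saturate
  (almost every bit has seen 0 and 1 in both classes), so the method
  degenerates towards the tie rule — a faithful property of the algorithm,
  which also shows up as its near-constant behaviour across inactive
  sources.

Features are always the raw fingerprint bits (no scaling). Heavier methods
are deliberately not re-implemented; `register_adapter` accepts any
`fit(X, y) → predict` factory and the pipeline treats the result identically
to native models.

## The synthetic universe

The generator emulates the statistical structure the study depends on
without any proprietary data:

* **Actives** — 500 molecules over 10 latent scaffolds; a scaffold is a set
  of 40 core bits out of 1024; a member keeps each core bit with probability
  1 − `flip_noise` (default 0.05) and turns any non-core bit on at
  `background_density` (0.05). Descriptors are drug-like and nearly constant
  within a scaffold (chemical series share physicochemistry).
* **Broad ("ZINC-like") pool** — 50 000 molecules from 150 *chemotypes*
  built the same way, each chemotype with its own descriptor centre
  (members jitter: MW ±3 %, logP ±0.05). The coupling of descriptors to
  chemotypes is the load-bearing realism: property-window matching then
  concentrates decoy candidates in the few descriptor-compatible chemotypes,
  which is exactly why DUD-style negatives are topologically narrow. Two
  special groups are embedded: per active scaffold, two *matched* chemotypes
  whose centres sit inside the strict window (guaranteeing ≥ 50 candidates
  per active — checked at generation, hard error otherwise) and one
  *near-active* chemotype sharing half the scaffold's core bits (the
  structural analogues any broad library contains).
* **Narrow ("MDDR-like") pool** — 5 000 molecules from 15 own non-target
  scaffolds plus the most drug-like 60 broad chemotypes (including half the
  near-active ones): narrower descriptors, partial coverage of the broad
  space.

One master seed drives a fixed-order spawn of per-pool child streams, so
pools regenerate independently and the whole universe is byte-reproducible.

What the generator does **not** emulate: real fingerprint bit correlations
within a molecule (bits are conditionally independent given the chemotype),
activity cliffs, assay noise, and any chemically valid structures (synthetic
molecules carry no SMILES). Consequently, passing grids show that the
*set-construction mechanisms* behave as in the study — they do not certify
absolute performance numbers on real libraries, where fingerprint geometry
is richer and class boundaries are softer.

## Numerical and degenerate-input choices

* Tanimoto of two empty fingerprints is 0.0 (logged), so featureless pairs
  are never excluded by the `< 0.7` filter.
* MCC uses the standard square-root denominator, consistent with its
  −1…1 range.
* Zero-denominator precision/recall/MCC are reported as 0.0 with an
  `undefined` flag; aggregation excludes undefined cells and reports their
  count; SD is the sample (n−1) estimator and is absent for single-cell
  groups.
* All stochastic draws flow through explicit seeds; diverse selection and
  the decoy builder contain no randomness at all.

## Observed behaviour on the default universe

With the committed defaults, the common-test grid reproduces the study's
qualitative findings for the distance-based learner most clearly: k-NN mean
MCC orders broad-random ≥ narrow-random ≥ decoy sources with a precision
spread of ≈ 0.27, recall stays at 1.0 for every source, matched-mode decoy
cells reach MCC ≈ 1.0, and replicate SDs stay below 0.02. Two limits are
inherent to the native trio rather than bugs, and the acceptance suite
leaves them visible: pooled naive Bayes is a shared-weight linear model that
cannot encode "this particular chemotype is inactive", so its precision
spread across sources (≈ 0.16) stays below the 0.2 bound the distance
learner clears; and saturated Hyperpipes is nearly constant across sources
(spread ≈ 0), consistent with its reported insensitivity.
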