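"""Synthetic compound universe with the statistical structure of a screening study.

Three pools are generated, emulating the roles of the data sources a
ligand-based virtual-screening benchmark draws on:

``actives``
    compounds clustered on a small number of latent scaffolds: each scaffold
    is a fixed set of core bits, members keep a core bit on with probability
    ``1 - flip_noise`` and turn any non-core bit on at ``background_density``.
    Descriptors are drug-like and nearly constant within a scaffold (a
    chemical series shares size, lipophilicity and H-bonding pattern).

``zinc_like``
    a large, chemically broad pool modelled as a mixture of *chemotypes* --
    latent series with their own core bits and their own descriptor centres.
    Descriptor-chemotype coupling is deliberate: in real libraries compounds
    of one series share both topology and physicochemistry, which is exactly
    what makes property-window decoy matching concentrate on a few series.
    Three special chemotype groups are embedded:

    * *matched* chemotypes (a few per active scaffold) whose descriptor
      centres sit inside the strict decoy match window of that scaffold --
      they guarantee every active has a healthy pool of window-compatible,
      topologically unrelated decoy candidates;
    * *near-active* chemotypes sharing a fraction of an active scaffold's
      core bits (structural analogues present in any broad library);
    * ordinary broad chemotypes.

``mddr_like``
    a narrower, drug-like pool: its own non-target scaffolds (actives
    against other targets) plus the most drug-like slice of the broad
    chemotype space, including some near-active chemotypes.

Everything is reproducible from the single master seed: a fixed-order
``SeedSequence`` spawn gives one child stream per pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .chem import CompoundLibrary, Descriptors, Fingerprint, MoleculeRecord
from .decoys import MatchWindow, window_mask


class GenerationError(RuntimeError):
    """Raised when the generator cannot satisfy its structural contracts."""


@dataclass(frozen=True)
class DescriptorProfile:
    """Pool-level descriptor distribution: normal mw/logp, Poisson counts."""

    mw_mean: float = 350.0
    mw_sd: float = 100.0
    mw_min: float = 100.0
    logp_mean: float = 2.5
    logp_sd: float = 1.8
    hba_mean: float = 4.0
    hbd_mean: float = 2.0
    rotb_mean: float = 5.0

    def sample(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        mw = rng.normal(self.mw_mean, self.mw_sd, n)
        mw = np.clip(mw, self.mw_min, None)
        return {
            "mw": mw,
            "logp": rng.normal(self.logp_mean, self.logp_sd, n),
            "hba": rng.poisson(self.hba_mean, n),
            "hbd": rng.poisson(self.hbd_mean, n),
            "rotb": rng.poisson(self.rotb_mean, n),
        }


@dataclass(frozen=True)
class UniverseParams:
    """Knobs of the synthetic universe; defaults are the study conditions."""

    n_bits: int = 1024
    n_active_scaffolds: int = 10
    bits_per_scaffold: int = 40
    flip_noise: float = 0.05
    background_density: float = 0.05
    n_actives: int = 500
    n_zinc: int = 50_000
    n_mddr: int = 5_000
    seed: int = 42
    # chemotype structure of the broad pool
    n_zinc_chemotypes: int = 150
    near_chemotypes_per_scaffold: int = 1
    near_core_overlap: float = 0.5
    matched_chemotypes_per_scaffold: int = 2
    # composition of the narrow drug-like pool
    n_mddr_own_scaffolds: int = 15
    n_mddr_shared_chemotypes: int = 60
    n_mddr_shared_near: int = 5
    # decoy-candidate guarantee
    min_window_candidates: int = 50
    # descriptor profiles
    zinc_profile: DescriptorProfile = DescriptorProfile()
    mddr_profile: DescriptorProfile = DescriptorProfile(mw_sd=50.0, logp_sd=0.9)
    active_profile: DescriptorProfile = DescriptorProfile(mw_sd=60.0, logp_sd=1.0, mw_min=150.0)

    def __post_init__(self) -> None:
        for name in ("n_bits", "n_active_scaffolds", "bits_per_scaffold", "n_actives",
                     "n_zinc", "n_mddr", "n_zinc_chemotypes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("flip_noise", "background_density", "near_core_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        n_special = self.n_active_scaffolds * (
            self.near_chemotypes_per_scaffold + self.matched_chemotypes_per_scaffold
        )
        if n_special > self.n_zinc_chemotypes:
            raise ValueError("near+matched chemotypes exceed n_zinc_chemotypes")
        if self.n_mddr_shared_near > self.n_active_scaffolds * self.near_chemotypes_per_scaffold:
            raise ValueError("n_mddr_shared_near exceeds available near chemotypes")


@dataclass
class Universe:
    """The generated pools plus generation metadata."""

    actives: CompoundLibrary
    zinc_like: CompoundLibrary
    mddr_like: CompoundLibrary
    params: UniverseParams
    meta: dict = field(default_factory=dict)

    def pools(self) -> dict[str, CompoundLibrary]:
        return {"actives": self.actives, "zinc_like": self.zinc_like,
                "mddr_like": self.mddr_like}


# descriptor jitter half-widths (fractions for mw, absolute for logp).  These
# are sized so that an active and any member of its matched chemotypes always
# sit inside the strict window: mw worst case 1.02*1.03/0.98 - 1 = 7.2% < 10%,
# logp worst case 0.08 + 0.04 + 0.05 = 0.17 < the 0.2 near-zero floor.
_ACTIVE_MW_JITTER = 0.02
_ACTIVE_LOGP_JITTER = 0.08
_MATCHED_CENTER_MW_JITTER = 0.02
_MATCHED_CENTER_LOGP_JITTER = 0.04
_POOL_MW_JITTER = 0.03
_POOL_LOGP_JITTER = 0.05


def _sample_cores(rng: np.random.Generator, n_cores: int, n_bits: int,
                  bits_per_core: int) -> np.ndarray:
    cores = np.empty((n_cores, bits_per_core), dtype=np.int64)
    for i in range(n_cores):
        cores[i] = rng.choice(n_bits, size=bits_per_core, replace=False)
    return cores


def _sample_fingerprints(rng: np.random.Generator, cores: np.ndarray,
                         assign: np.ndarray, n_bits: int, flip_noise: float,
                         background_density: float, chunk: int = 4096) -> np.ndarray:
    """Bernoulli fingerprints: P(on)=1-flip_noise on the assigned core, else bg."""
    prob = np.full((len(cores), n_bits), background_density)
    for k in range(len(cores)):
        prob[k, cores[k]] = 1.0 - flip_noise
    out = np.empty((len(assign), n_bits), dtype=bool)
    for start in range(0, len(assign), chunk):
        stop = min(start + chunk, len(assign))
        out[start:stop] = rng.random((stop - start, n_bits)) < prob[assign[start:stop]]
    return out


def _member_descriptors(rng: np.random.Generator, centers: dict[str, np.ndarray],
                        assign: np.ndarray, mw_jitter: float,
                        logp_jitter: float) -> dict[str, np.ndarray]:
    n = len(assign)
    mw = centers["mw"][assign] * (1.0 + rng.uniform(-mw_jitter, mw_jitter, n))
    logp = centers["logp"][assign] + rng.uniform(-logp_jitter, logp_jitter, n)
    return {
        "mw": mw,
        "logp": logp,
        "hba": centers["hba"][assign],
        "hbd": centers["hbd"][assign],
        "rotb": centers["rotb"][assign],
    }


def _build_records(prefix: str, fps: np.ndarray, desc: dict[str, np.ndarray],
                   scaffold_labels: list[str], assign: np.ndarray,
                   activity: Optional[bool]) -> list[MoleculeRecord]:
    n_bits = fps.shape[1]
    records = []
    for i in range(fps.shape[0]):
        fp = Fingerprint(n_bits=n_bits, on_bits=tuple(np.flatnonzero(fps[i]).tolist()))
        d = Descriptors(mw=float(desc["mw"][i]), logp=float(desc["logp"][i]),
                        hba=int(desc["hba"][i]), hbd=int(desc["hbd"][i]),
                        rotb=int(desc["rotb"][i]))
        records.append(MoleculeRecord(
            id=f"{prefix}{i + 1:06d}", descriptors=d, fingerprint=fp,
            scaffold=scaffold_labels[assign[i]], activity=activity,
        ))
    return records


def generate_universe(params: UniverseParams) -> Universe:
    """Generate the actives / zinc_like / mddr_like pools from one seed.

    The generation contract (checked, raising :class:`GenerationError`):
    every active has at least ``params.min_window_candidates`` zinc_like
    molecules inside the strict decoy match window.
    """
    p = params
    ss = np.random.SeedSequence(p.seed)
    rng_structure, rng_act, rng_zinc, rng_mddr = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    # --- latent structure ---------------------------------------------------
    active_cores = _sample_cores(rng_structure, p.n_active_scaffolds, p.n_bits,
                                 p.bits_per_scaffold)
    n_near = p.n_active_scaffolds * p.near_chemotypes_per_scaffold
    n_matched = p.n_active_scaffolds * p.matched_chemotypes_per_scaffold
    n_far = p.n_zinc_chemotypes - n_near - n_matched

    chemotype_cores = np.empty((p.n_zinc_chemotypes, p.bits_per_scaffold), dtype=np.int64)
    chemotype_kind: list[str] = []
    chemotype_parent: list[int] = []  # active scaffold index or -1
    row = 0
    n_shared = int(round(p.near_core_overlap * p.bits_per_scaffold))
    for s in range(p.n_active_scaffolds):
        for _ in range(p.near_chemotypes_per_scaffold):
            shared = rng_structure.choice(active_cores[s], size=n_shared, replace=False)
            outside = np.setdiff1d(np.arange(p.n_bits), active_cores[s])
            fresh = rng_structure.choice(outside, size=p.bits_per_scaffold - n_shared,
                                         replace=False)
            chemotype_cores[row] = np.concatenate([shared, fresh])
            chemotype_kind.append("near")
            chemotype_parent.append(s)
            row += 1
    for s in range(p.n_active_scaffolds):
        for _ in range(p.matched_chemotypes_per_scaffold):
            chemotype_cores[row] = rng_structure.choice(p.n_bits, p.bits_per_scaffold,
                                                        replace=False)
            chemotype_kind.append("matched")
            chemotype_parent.append(s)
            row += 1
    for _ in range(n_far):
        chemotype_cores[row] = rng_structure.choice(p.n_bits, p.bits_per_scaffold,
                                                    replace=False)
        chemotype_kind.append("far")
        chemotype_parent.append(-1)
        row += 1
    mddr_own_cores = _sample_cores(rng_structure, p.n_mddr_own_scaffolds, p.n_bits,
                                   p.bits_per_scaffold)

    # --- descriptor centres -------------------------------------------------
    act_centers = p.active_profile.sample(rng_act, p.n_active_scaffolds)
    zc = p.zinc_profile.sample(rng_zinc, p.n_zinc_chemotypes)
    kind_arr = np.array(chemotype_kind)
    parent_arr = np.array(chemotype_parent)
    matched_idx = np.flatnonzero(kind_arr == "matched")
    for j in matched_idx:
        s = parent_arr[j]
        zc["mw"][j] = act_centers["mw"][s] * (
            1.0 + rng_zinc.uniform(-_MATCHED_CENTER_MW_JITTER, _MATCHED_CENTER_MW_JITTER))
        zc["logp"][j] = act_centers["logp"][s] + rng_zinc.uniform(
            -_MATCHED_CENTER_LOGP_JITTER, _MATCHED_CENTER_LOGP_JITTER)
        for k in ("hba", "hbd", "rotb"):
            zc[k][j] = act_centers[k][s]
    mddr_own_centers = p.mddr_profile.sample(rng_mddr, p.n_mddr_own_scaffolds)

    # --- actives ------------------------------------------------------------
    act_assign = rng_act.integers(0, p.n_active_scaffolds, p.n_actives)
    act_fps = _sample_fingerprints(rng_act, active_cores, act_assign, p.n_bits,
                                   p.flip_noise, p.background_density)
    act_desc = _member_descriptors(rng_act, act_centers, act_assign,
                                   _ACTIVE_MW_JITTER, _ACTIVE_LOGP_JITTER)
    act_labels = [f"AS{s}" for s in range(p.n_active_scaffolds)]
    actives = CompoundLibrary("actives", _build_records(
        "ACT", act_fps, act_desc, act_labels, act_assign, activity=True))

    # --- zinc_like ----------------------------------------------------------
    zinc_assign = rng_zinc.integers(0, p.n_zinc_chemotypes, p.n_zinc)
    zinc_fps = _sample_fingerprints(rng_zinc, chemotype_cores, zinc_assign, p.n_bits,
                                    p.flip_noise, p.background_density)
    zinc_desc = _member_descriptors(rng_zinc, zc, zinc_assign,
                                    _POOL_MW_JITTER, _POOL_LOGP_JITTER)
    zinc_labels = [f"ZC{k}" for k in range(p.n_zinc_chemotypes)]
    zinc_like = CompoundLibrary("zinc_like", _build_records(
        "ZINC", zinc_fps, zinc_desc, zinc_labels, zinc_assign, activity=None))

    # --- mddr_like ----------------------------------------------------------
    near_idx = np.flatnonzero(kind_arr == "near")
    shared_near = rng_mddr.choice(near_idx, size=p.n_mddr_shared_near, replace=False)
    non_near = np.flatnonzero(kind_arr != "near")
    # the drug-like slice of the broad chemotype space: rank by standardised
    # distance from the drug-like centre and keep the closest
    druglike_score = (np.abs(zc["mw"][non_near] - p.zinc_profile.mw_mean) / p.zinc_profile.mw_sd
                      + np.abs(zc["logp"][non_near] - p.zinc_profile.logp_mean) / p.zinc_profile.logp_sd)
    n_shared_other = p.n_mddr_shared_chemotypes - p.n_mddr_shared_near
    shared_other = non_near[np.argsort(druglike_score, kind="stable")[:n_shared_other]]
    mddr_chemo_idx = np.concatenate([shared_near, shared_other])

    n_mddr_chemo = len(mddr_chemo_idx) + p.n_mddr_own_scaffolds
    mddr_cores = np.vstack([chemotype_cores[mddr_chemo_idx], mddr_own_cores])
    mddr_centers = {
        k: np.concatenate([zc[k][mddr_chemo_idx], mddr_own_centers[k]])
        for k in ("mw", "logp", "hba", "hbd", "rotb")
    }
    mddr_labels = [f"ZC{k}" for k in mddr_chemo_idx] + \
                  [f"MS{k}" for k in range(p.n_mddr_own_scaffolds)]
    mddr_assign = rng_mddr.integers(0, n_mddr_chemo, p.n_mddr)
    mddr_fps = _sample_fingerprints(rng_mddr, mddr_cores, mddr_assign, p.n_bits,
                                    p.flip_noise, p.background_density)
    mddr_desc = _member_descriptors(rng_mddr, mddr_centers, mddr_assign,
                                    _POOL_MW_JITTER, _POOL_LOGP_JITTER)
    mddr_like = CompoundLibrary("mddr_like", _build_records(
        "MDDR", mddr_fps, mddr_desc, mddr_labels, mddr_assign, activity=None))

    universe = Universe(actives=actives, zinc_like=zinc_like, mddr_like=mddr_like,
                        params=p, meta={
                            "chemotype_kind": chemotype_kind,
                            "chemotype_parent": chemotype_parent,
                            "mddr_shared_chemotypes": mddr_chemo_idx.tolist(),
                        })
    _check_window_candidates(universe)
    return universe


def _check_window_candidates(universe: Universe) -> None:
    window = MatchWindow()  # strict defaults
    arrays = universe.zinc_like.descriptor_arrays()
    counts = np.empty(len(universe.actives), dtype=np.int64)
    for i, rec in enumerate(universe.actives):
        counts[i] = int(window_mask(rec.descriptors, arrays, window).sum())
    need = universe.params.min_window_candidates
    short = np.flatnonzero(counts < need)
    universe.meta["window_candidate_counts"] = counts
    if len(short):
        worst = universe.actives[int(short[0])].id
        raise GenerationError(
            f"{len(short)} actives have fewer than {need} window-compatible "
            f"zinc_like candidates (first offender: {worst}); increase the pool "
            "size or the number of matched chemotypes"
        )


def universe_summary(universe: Universe, max_pairs: int = 20_000) -> pd.DataFrame:
    """Per-pool summary: sizes, descriptor stats, sampled mean pairwise Tanimoto."""
    rng = np.random.default_rng(0)  # fixed: the summary must be reproducible
    rows = []
    for name, lib in universe.pools().items():
        row: dict = {"pool": name, "size": len(lib)}
        if len(lib) == 0:
            rows.append(row)
            continue
        arrays = lib.descriptor_arrays()
        for k, v in arrays.items():
            row[f"{k}_mean"] = float(np.mean(v))
            row[f"{k}_sd"] = float(np.std(v, ddof=1)) if len(lib) > 1 else float("nan")
        row["n_scaffolds"] = len({r.scaffold for r in lib if r.scaffold is not None})
        if len(lib) > 1:
            n_pairs = min(max_pairs, len(lib) * (len(lib) - 1) // 2)
            ii = rng.integers(0, len(lib), n_pairs)
            jj = rng.integers(0, len(lib) - 1, n_pairs)
            jj = np.where(jj >= ii, jj + 1, jj)
            mat = lib.bit_matrix()
            inter = (mat[ii] & mat[jj]).sum(axis=1)
            union = (mat[ii] | mat[jj]).sum(axis=1)
            sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
            row["mean_pairwise_tanimoto"] = float(sims.mean())
        rows.append(row)
    return pd.DataFrame(rows)
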