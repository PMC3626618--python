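"""Train/test dataset assembly over the (inactive source x strategy) grid.

Two evaluation designs are supported:

``common_test``
    one shared test set per iteration -- actives plus inactives drawn
    randomly from the broad (zinc-like) pool -- used unchanged for every
    training-set variant.  This emulates prospective virtual screening of a
    broad library.

``various_test``
    each training variant is tested on inactives produced the same way as
    its training inactives (the matched design most benchmark papers use).

Within one plan the active train/test split is frozen, so the only variable
across cells is how the inactives were chosen -- the controlled-variable
design of the study.  Determinism: every draw is derived from
``base_seed`` via the per-iteration child seed (``base*1000 + i``) plus a
fixed stream tag, so a plan re-run reproduces every cell byte-for-byte.

Because decoy ids are ids of the broad pool, a common test draw could
collide with decoy (or diverse-broad) training picks.  Deterministic diverse
training prefixes of such sources are therefore reserved out of the common
test draw (plan-level, identical for every source), and random train draws
exclude the already-drawn test ids; this keeps the common test truly common,
diverse cells identical across iterations, and train/test ids disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np

from .chem import CompoundLibrary, MoleculeRecord
from .selection import child_seed, maxmin_ordering
from .universe import Universe

INACTIVE_SOURCES = ("zinc_random", "zinc_diverse", "mddr_random", "mddr_diverse",
                    "dud_random", "dud_diverse")

# stream tags keeping the independent draws of one cell decoupled
_STREAM_ACTIVE_SPLIT = 11
_STREAM_COMMON_TEST = 12
_STREAM_TRAIN = 13
_STREAM_VARIOUS = 14


def parse_source(tag: str) -> tuple[str, str]:
    """Split an inactive-source tag into (pool key, strategy)."""
    if tag not in INACTIVE_SOURCES:
        raise ValueError(f"unknown inactive source {tag!r}; expected one of {INACTIVE_SOURCES}")
    pool, strategy = tag.split("_")
    return pool, strategy


@dataclass(frozen=True)
class SetComposition:
    """Counts of actives/inactives per split."""

    n_train_act: int
    n_train_inact: int
    n_test_act: int
    n_test_inact: int

    def __post_init__(self) -> None:
        for name in ("n_train_act", "n_train_inact", "n_test_act", "n_test_inact"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class LabeledDataset:
    """Molecules with binary active/inactive labels for one split."""

    records: list[MoleculeRecord]
    labels: np.ndarray  # bool, True = active
    split: Literal["train", "test"]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels length mismatch")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule id in dataset")
        n_bits = {r.fingerprint.n_bits for r in self.records}
        if len(n_bits) > 1:
            raise ValueError(f"mixed fingerprint lengths in dataset: {sorted(n_bits)}")
        self._bit_matrix: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_bits(self) -> int:
        return self.records[0].fingerprint.n_bits

    def items(self) -> Iterator[tuple[MoleculeRecord, bool]]:
        return zip(self.records, self.labels.tolist())

    def bit_matrix(self) -> np.ndarray:
        if self._bit_matrix is None:
            mat = np.zeros((len(self.records), self.n_bits), dtype=bool)
            for i, rec in enumerate(self.records):
                if rec.fingerprint.on_bits:
                    mat[i, list(rec.fingerprint.on_bits)] = True
            self._bit_matrix = mat
        return self._bit_matrix


@dataclass(frozen=True)
class ExperimentPlan:
    mode: Literal["common_test", "various_test"]
    inactive_sources: tuple[str, ...]
    composition: SetComposition
    iterations: int = 10
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("common_test", "various_test"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "inactive_sources", tuple(self.inactive_sources))
        for tag in self.inactive_sources:
            parse_source(tag)
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def effective_iterations(self, source: str) -> int:
        """Diverse strategies are deterministic: a single effective iteration."""
        _, strategy = parse_source(source)
        return 1 if strategy == "diverse" else self.iterations


def split_actives(actives: CompoundLibrary, composition: SetComposition,
                  seed: int) -> tuple[CompoundLibrary, CompoundLibrary]:
    """Disjoint seeded random train/test split of the actives, library order kept."""
    need = composition.n_train_act + composition.n_test_act
    if need > len(actives):
        raise ValueError(f"need {need} actives, library has {len(actives)}")
    rng = np.random.default_rng([seed, _STREAM_ACTIVE_SPLIT])
    perm = rng.permutation(len(actives))
    train_idx = np.sort(perm[:composition.n_train_act])
    test_idx = np.sort(perm[composition.n_train_act:need])
    return actives.subset(train_idx.tolist()), actives.subset(test_idx.tolist())


def _random_subset(pool: CompoundLibrary, n: int, rng: np.random.Generator,
                   exclude_ids: frozenset[str] = frozenset()) -> list[MoleculeRecord]:
    allowed = [i for i in range(len(pool)) if pool.records[i].id not in exclude_ids]
    if n > len(allowed):
        raise ValueError(
            f"pool {pool.source!r} has {len(allowed)} eligible records, need {n}")
    idx = np.sort(rng.choice(len(allowed), size=n, replace=False))
    return [pool.records[allowed[i]] for i in idx]


class PlanContext:
    """Precomputed shared state for all cells of one experiment plan."""

    def __init__(self, plan: ExperimentPlan, universe: Universe,
                 dud_library: Optional[CompoundLibrary] = None):
        self.plan = plan
        self.universe = universe
        self.pools: dict[str, CompoundLibrary] = {
            "zinc": universe.zinc_like,
            "mddr": universe.mddr_like,
        }
        if dud_library is not None:
            self.pools["dud"] = dud_library
        for tag in plan.inactive_sources:
            pool_key, _ = parse_source(tag)
            if pool_key not in self.pools:
                raise ValueError(f"source {tag!r} needs a pre-built decoy library")
        comp = plan.composition
        self.train_actives, self.test_actives = split_actives(
            universe.actives, comp, plan.base_seed)

        # deterministic MaxMin prefixes for every diverse source in the plan
        self._diverse_orderings: dict[str, list[int]] = {}
        for tag in plan.inactive_sources:
            pool_key, strategy = parse_source(tag)
            if strategy == "diverse":
                depth = comp.n_train_inact
                if plan.mode == "various_test":
                    depth += comp.n_test_inact
                self._diverse_orderings[tag] = maxmin_ordering(self.pools[pool_key], depth)

        # ids reserved out of the common test draw: diverse training prefixes of
        # sources whose pools share ids with the broad pool
        reserved: set[str] = set()
        if plan.mode == "common_test":
            zinc_ids = set(universe.zinc_like.ids)
            for tag, ordering in self._diverse_orderings.items():
                pool_key, _ = parse_source(tag)
                pool = self.pools[pool_key]
                prefix_ids = {pool.records[i].id for i in ordering[:comp.n_train_inact]}
                reserved |= prefix_ids & zinc_ids
        self._reserved_common = frozenset(reserved)
        self._common_tests: dict[int, list[MoleculeRecord]] = {}

    def common_test_inactives(self, iteration: int) -> list[MoleculeRecord]:
        if iteration not in self._common_tests:
            rng = np.random.default_rng(
                [child_seed(self.plan.base_seed, iteration), _STREAM_COMMON_TEST])
            self._common_tests[iteration] = _random_subset(
                self.universe.zinc_like, self.plan.composition.n_test_inact, rng,
                self._reserved_common)
        return self._common_tests[iteration]

    def cell(self, source: str, iteration: int) -> tuple[LabeledDataset, LabeledDataset]:
        plan, comp = self.plan, self.plan.composition
        pool_key, strategy = parse_source(source)
        pool = self.pools[pool_key]
        cseed = child_seed(plan.base_seed, iteration)

        if plan.mode == "common_test":
            test_inact = self.common_test_inactives(iteration)
            test_ids = frozenset(r.id for r in test_inact)
            if strategy == "random":
                rng = np.random.default_rng([cseed, _STREAM_TRAIN])
                train_inact = _random_subset(pool, comp.n_train_inact, rng, test_ids)
            else:
                ordering = self._diverse_orderings[source][:comp.n_train_inact]
                train_inact = [pool.records[i] for i in ordering]
        else:  # various_test
            if strategy == "random":
                rng = np.random.default_rng([cseed, _STREAM_VARIOUS])
                both = _random_subset(pool, comp.n_train_inact + comp.n_test_inact, rng)
                # a single uniform draw split in two keeps both subsets uniform
                # and disjoint; re-randomise assignment so neither split is
                # biased toward low library indices
                order = rng.permutation(len(both))
                train_inact = [both[i] for i in order[:comp.n_train_inact]]
                test_inact = [both[i] for i in order[comp.n_train_inact:]]
            else:
                ordering = self._diverse_orderings[source]
                train_inact = [pool.records[i] for i in ordering[:comp.n_train_inact]]
                test_inact = [pool.records[i]
                              for i in ordering[comp.n_train_inact:
                                                comp.n_train_inact + comp.n_test_inact]]

        overlap = {r.id for r in train_inact} & {r.id for r in test_inact}
        if overlap:
            raise RuntimeError(f"train/test inactive overlap: {sorted(overlap)[:5]}")

        provenance = {
            "source": source, "strategy": strategy, "mode": plan.mode,
            "iteration": iteration, "seed": None if strategy == "diverse" else cseed,
            "base_seed": plan.base_seed,
        }
        train = LabeledDataset(
            records=list(self.train_actives.records) + train_inact,
            labels=np.concatenate([np.ones(len(self.train_actives), bool),
                                   np.zeros(len(train_inact), bool)]),
            split="train", provenance=provenance,
        )
        test = LabeledDataset(
            records=list(self.test_actives.records) + test_inact,
            labels=np.concatenate([np.ones(len(self.test_actives), bool),
                                   np.zeros(len(test_inact), bool)]),
            split="test", provenance=dict(provenance),
        )
        return train, test


def assemble_cell(plan: ExperimentPlan, source: str, iteration: int,
                  universe: Universe,
                  dud_library: Optional[CompoundLibrary] = None,
                  context: Optional[PlanContext] = None
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Build the (train, test) datasets of one grid cell.

    Passing a shared :class:`PlanContext` avoids recomputing the active split,
    MaxMin orderings and common test sets across cells.
    """
    if context is None:
        context = PlanContext(plan, universe, dud_library)
    return context.cell(source, iteration)
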