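"""Inactive-subset selection strategies: seeded random and MaxMin diversity.

Random selection is a uniform draw without replacement, deterministic given
its seed, returned in original library order.  Diversity selection is the
canonical greedy MaxMin picker over Tanimoto distance (1 - similarity): the
first pick maximises the total distance to the whole library, every later
pick maximises the minimum distance to the already-picked set, all ties
broken by library order.  MaxMin has no random element, so repeated runs
return the identical subset -- the behaviour commercial diversity pickers
show in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .chem import CompoundLibrary, tanimoto_cross, total_tanimoto_distance


@dataclass(frozen=True)
class SelectionSpec:
    strategy: Literal["random", "diverse"]
    n: int
    seed: Optional[int] = None
    iteration: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strategy not in ("random", "diverse"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n < 1:
            raise ValueError("subset size must be >= 1")


def child_seed(base_seed: int, iteration: int) -> int:
    """Per-iteration replicate seed: base * 1000 + iteration (logged everywhere)."""
    return base_seed * 1000 + iteration


def random_select(library: CompoundLibrary, n: int, seed: int) -> CompoundLibrary:
    """Uniform sample of ``n`` records without replacement, in library order."""
    if n > len(library):
        raise ValueError(f"cannot select {n} from a library of {len(library)}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(library), size=n, replace=False))
    return library.subset(idx.tolist())


def maxmin_ordering(library: CompoundLibrary, n: int) -> list[int]:
    """Indices of the first ``n`` greedy MaxMin picks (deterministic)."""
    if n > len(library):
        raise ValueError(f"cannot select {n} from a library of {len(library)}")
    totals = total_tanimoto_distance(library)
    first = int(np.argmax(totals))  # argmax returns the first maximiser: tie rule
    packed = library.packed()
    pops = library.popcounts()
    picks = [first]
    min_dist = 1.0 - tanimoto_cross(packed[[first]], pops[[first]], packed, pops)[0]
    min_dist[first] = -np.inf
    for _ in range(1, n):
        nxt = int(np.argmax(min_dist))
        picks.append(nxt)
        d = 1.0 - tanimoto_cross(packed[[nxt]], pops[[nxt]], packed, pops)[0]
        np.minimum(min_dist, d, out=min_dist)
        min_dist[nxt] = -np.inf
    return picks


def maxmin_diverse_select(library: CompoundLibrary, n: int) -> CompoundLibrary:
    """Greedy MaxMin diversity subset, in pick order."""
    return library.subset(maxmin_ordering(library, n))
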