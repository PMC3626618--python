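"""Shared fixtures: toy library builders and session-scoped study universes."""

from __future__ import annotations

import numpy as np
import pytest

from inactive_bench import (CompoundLibrary, DecoyConfig, Descriptors,
                            ExperimentPlan, Fingerprint, MoleculeRecord,
                            SetComposition, UniverseParams, build_dud_library,
                            generate_universe, run_grid)
from inactive_bench.assembly import PlanContext

N_BITS_TOY = 16

#: the default study composition (drug-like train/test ratios at desk scale)
DEFAULT_COMPOSITION = SetComposition(n_train_act=200, n_train_inact=300,
                                     n_test_act=300, n_test_inact=350)


def make_molecule(mol_id: str, on_bits=(), n_bits: int = N_BITS_TOY,
                  mw: float = 300.0, logp: float = 2.0, hba: int = 4,
                  hbd: int = 2, rotb: int = 5, **kwargs) -> MoleculeRecord:
    return MoleculeRecord(
        id=mol_id,
        descriptors=Descriptors(mw=mw, logp=logp, hba=hba, hbd=hbd, rotb=rotb),
        fingerprint=Fingerprint(n_bits=n_bits, on_bits=tuple(on_bits)),
        **kwargs,
    )


def make_library(specs, source: str = "custom", n_bits: int = N_BITS_TOY
                 ) -> CompoundLibrary:
    """Library from a list of (id, on_bits) or (id, on_bits, descriptor kwargs)."""
    records = []
    for spec in specs:
        mol_id, on_bits, kwargs = (spec if len(spec) == 3 else (*spec, {}))
        records.append(make_molecule(mol_id, on_bits, n_bits=n_bits, **kwargs))
    return CompoundLibrary(source, records)


def random_library(rng: np.random.Generator, n: int, n_bits: int = 64,
                   density: float = 0.2, source: str = "custom",
                   prefix: str = "M") -> CompoundLibrary:
    records = []
    for i in range(n):
        bits = tuple(np.flatnonzero(rng.random(n_bits) < density).tolist())
        records.append(MoleculeRecord(
            id=f"{prefix}{i:04d}",
            descriptors=Descriptors(
                mw=float(rng.uniform(150, 550)), logp=float(rng.normal(2.5, 1.5)),
                hba=int(rng.poisson(4)), hbd=int(rng.poisson(2)),
                rotb=int(rng.poisson(5))),
            fingerprint=Fingerprint(n_bits=n_bits, on_bits=bits),
        ))
    return CompoundLibrary(source, records)


@pytest.fixture(scope="session")
def small_universe():
    """A reduced universe for structural tests (fast, same machinery)."""
    return generate_universe(UniverseParams(n_actives=100, n_zinc=5000,
                                            n_mddr=2000, seed=7))


@pytest.fixture(scope="session")
def default_universe():
    """The full default study universe (seed 42)."""
    return generate_universe(UniverseParams())


@pytest.fixture(scope="session")
def default_dud(default_universe):
    """Decoy library + report built from the default universe, strict window."""
    return build_dud_library(default_universe.actives, default_universe.zinc_like,
                             DecoyConfig())


@pytest.fixture(scope="session")
def small_dud(small_universe):
    return build_dud_library(small_universe.actives, small_universe.zinc_like,
                             DecoyConfig())


@pytest.fixture(scope="session")
def common_test_grid(default_universe, default_dud):
    """Common-test-mode grid over the four sources the study contrasts."""
    dud_library, _ = default_dud
    plan = ExperimentPlan(
        mode="common_test",
        inactive_sources=("zinc_random", "mddr_random", "dud_random", "dud_diverse"),
        composition=DEFAULT_COMPOSITION, iterations=10, base_seed=1,
    )
    return run_grid(plan, default_universe, dud_library)


@pytest.fixture(scope="session")
def matched_dud_grid(default_universe, default_dud):
    """Various-test-sets mode with decoy inactives on both sides (k-NN)."""
    dud_library, _ = default_dud
    plan = ExperimentPlan(mode="various_test", inactive_sources=("dud_random",),
                          composition=DEFAULT_COMPOSITION, iterations=10, base_seed=1)
    return run_grid(plan, default_universe, dud_library,
                    classifiers={"knn": {"k": 1}})
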