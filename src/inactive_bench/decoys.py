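"""DUD-methodology decoy library construction.

For every active ligand, candidate decoys are pulled from a broad pool by
property-window matching (same H-bond acceptor/donor and rotatable-bond
counts, molecular weight and logP within a relative window), then restricted
to topologically dissimilar structures (Tanimoto strictly below a ceiling),
and finally the ``n_per_ligand`` candidates *least* similar to the ligand are
kept.  The union over ligands, de-duplicated, forms the decoy library.

Conventions the field leaves open, fixed here and stated in every report:

* the MW/logP windows are relative to the *ligand's* values;
* the relative logP window collapses near logP 0, so the effective
  half-width is ``max(rel_tol * |logp|, 0.2)``;
* duplicates across ligands are removed first-claim-wins in actives order,
  and later ligands do not refill slots lost to earlier claims;
* fewer than ``n_per_ligand`` candidates is a logged shortfall, not an error
  (real targets show exactly this); zero decoys in total is an error that
  suggests the relaxed window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import CompoundLibrary, Descriptors, MoleculeRecord, bulk_tanimoto

logger = logging.getLogger(__name__)

#: effective half-width floor for the relative logP window near zero
LOGP_WINDOW_FLOOR = 0.2


class NoDecoysError(RuntimeError):
    """Raised when the whole build yields zero decoys."""


@dataclass(frozen=True)
class MatchWindow:
    """Decoy matching tolerances: relative for MW/logP, absolute for counts.

    Strict defaults: 10% relative, exact count match.  The relaxed variant
    (20%, +-2) mirrors the loosening applied to targets with too few decoys.
    """

    rel_tol: float = 0.10
    abs_tol: int = 0

    def __post_init__(self) -> None:
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")
        if self.abs_tol < 0 or int(self.abs_tol) != self.abs_tol:
            raise ValueError("abs_tol must be a non-negative integer")

    @classmethod
    def strict(cls) -> "MatchWindow":
        return cls(rel_tol=0.10, abs_tol=0)

    @classmethod
    def relaxed(cls) -> "MatchWindow":
        return cls(rel_tol=0.20, abs_tol=2)


@dataclass(frozen=True)
class DecoyConfig:
    window: MatchWindow = MatchWindow()
    tanimoto_max: float = 0.7
    n_per_ligand: int = 36
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.tanimoto_max <= 1.0:
            raise ValueError("tanimoto_max must be in (0, 1]")
        if self.n_per_ligand < 1:
            raise ValueError("n_per_ligand must be >= 1")


def property_window_match(ligand: Descriptors, candidate: Descriptors,
                          window: MatchWindow) -> bool:
    """True iff the candidate sits inside the ligand's property window."""
    if abs(candidate.hba - ligand.hba) > window.abs_tol:
        return False
    if abs(candidate.hbd - ligand.hbd) > window.abs_tol:
        return False
    if abs(candidate.rotb - ligand.rotb) > window.abs_tol:
        return False
    if abs(candidate.mw - ligand.mw) > window.rel_tol * ligand.mw:
        return False
    logp_halfwidth = max(window.rel_tol * abs(ligand.logp), LOGP_WINDOW_FLOOR)
    return abs(candidate.logp - ligand.logp) <= logp_halfwidth


def window_mask(ligand: Descriptors, pool_arrays: dict[str, np.ndarray],
                window: MatchWindow) -> np.ndarray:
    """Vectorised :func:`property_window_match` over a pool's descriptor arrays."""
    mask = (
        (np.abs(pool_arrays["hba"] - ligand.hba) <= window.abs_tol)
        & (np.abs(pool_arrays["hbd"] - ligand.hbd) <= window.abs_tol)
        & (np.abs(pool_arrays["rotb"] - ligand.rotb) <= window.abs_tol)
        & (np.abs(pool_arrays["mw"] - ligand.mw) <= window.rel_tol * ligand.mw)
    )
    logp_halfwidth = max(window.rel_tol * abs(ligand.logp), LOGP_WINDOW_FLOOR)
    mask &= np.abs(pool_arrays["logp"] - ligand.logp) <= logp_halfwidth
    return mask


def _candidate_indices(ligand: MoleculeRecord, pool: CompoundLibrary,
                       config: DecoyConfig,
                       exclude_ids: frozenset[str]) -> tuple[np.ndarray, np.ndarray]:
    """Indices (pool order) and similarities of candidates passing both filters."""
    mask = window_mask(ligand.descriptors, pool.descriptor_arrays(), config.window)
    idx = np.flatnonzero(mask)
    if exclude_ids:
        keep = [i for i in idx if pool.records[i].id not in exclude_ids]
        idx = np.asarray(keep, dtype=np.int64)
    if len(idx) == 0:
        return idx, np.empty(0)
    sims = bulk_tanimoto(pool.subset(idx), ligand.fingerprint)
    passing = sims < config.tanimoto_max
    return idx[passing], sims[passing]


def find_candidate_decoys(ligand: MoleculeRecord, pool: CompoundLibrary,
                          config: DecoyConfig,
                          actives: CompoundLibrary | None = None) -> list[MoleculeRecord]:
    """All pool records matching the property window and the Tanimoto ceiling.

    Returned in pool order; records whose id appears in ``actives`` are
    excluded.  An empty result is allowed.
    """
    exclude = frozenset(actives.ids) if actives is not None else frozenset()
    idx, _ = _candidate_indices(ligand, pool, config, exclude)
    return [pool.records[i] for i in idx]


def select_decoys_per_ligand(ligand: MoleculeRecord,
                             candidates: list[MoleculeRecord],
                             n: int) -> list[MoleculeRecord]:
    """The ``n`` candidates with the lowest Tanimoto to the ligand.

    Ties are broken by candidate order (pool order); a shortfall returns all
    candidates and logs a warning.
    """
    if len(candidates) < n:
        logger.warning("ligand %s: shortfall, only %d of %d requested decoys",
                       ligand.id, len(candidates), n)
    if not candidates:
        return []
    sims = np.array([_pair_tanimoto(ligand, c) for c in candidates])
    order = np.argsort(sims, kind="stable")
    return [candidates[i] for i in order[:n]]


def _pair_tanimoto(a: MoleculeRecord, b: MoleculeRecord) -> float:
    from .chem import tanimoto

    return tanimoto(a.fingerprint, b.fingerprint)


def build_dud_library(actives: CompoundLibrary, pool: CompoundLibrary,
                      config: DecoyConfig = DecoyConfig()
                      ) -> tuple[CompoundLibrary, pd.DataFrame]:
    """Build the decoy library over all ligands plus a per-ligand report.

    Returns the ``dud_generated`` library (union of per-ligand selections,
    de-duplicated first-claim-wins when ``config.dedupe``) and a report frame
    with columns ``ligand_id, n_window_matched, n_after_tanimoto, n_selected,
    shortfall, selected_ids``; ``n_selected`` counts the decoys this ligand
    actually contributed (after cross-ligand dedupe) and ``selected_ids``
    lists them.
    """
    if actives.n_bits is not None and pool.n_bits is not None \
            and actives.n_bits != pool.n_bits:
        raise ValueError("actives and pool fingerprint lengths differ")
    active_ids = frozenset(actives.ids)
    pool_arrays = pool.descriptor_arrays()
    claimed: set[int] = set()
    out_indices: list[int] = []
    claiming: dict[int, str] = {}
    report_rows = []
    for ligand in actives:
        wmask = window_mask(ligand.descriptors, pool_arrays, config.window)
        widx = np.flatnonzero(wmask)
        widx = np.asarray([i for i in widx if pool.records[i].id not in active_ids],
                          dtype=np.int64)
        n_window = len(widx)
        if n_window:
            sims = bulk_tanimoto(pool.subset(widx), ligand.fingerprint)
            keep = sims < config.tanimoto_max
            cidx, csims = widx[keep], sims[keep]
        else:
            cidx, csims = widx, np.empty(0)
        n_candidates = len(cidx)
        order = np.argsort(csims, kind="stable")[:config.n_per_ligand]
        selected = cidx[order]
        shortfall = max(0, config.n_per_ligand - n_candidates)
        if shortfall:
            logger.warning("ligand %s: shortfall of %d decoys", ligand.id, shortfall)
        claimed_ids = []
        for i in selected:
            i = int(i)
            if config.dedupe:
                if i in claimed:
                    continue  # first claim wins; no refill
                claimed.add(i)
            out_indices.append(i)
            claiming.setdefault(i, ligand.id)
            claimed_ids.append(pool.records[i].id)
        report_rows.append({
            "ligand_id": ligand.id,
            "n_window_matched": int(n_window),
            "n_after_tanimoto": int(n_candidates),
            "n_selected": len(claimed_ids),
            "shortfall": int(shortfall),
            "selected_ids": ";".join(claimed_ids),
        })
    if not out_indices:
        raise NoDecoysError(
            "no decoys selected for any ligand; consider the relaxed window "
            "(MatchWindow.relaxed(): +-20% MW/logP, +-2 counts)"
        )
    # a library is id-unique, so even without cross-ligand dedupe the output
    # keeps one copy per pool record (first occurrence, stable order)
    unique_indices = list(dict.fromkeys(out_indices))
    library = pool.subset(unique_indices, source="dud_generated")
    report = pd.DataFrame(report_rows)
    return library, report
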