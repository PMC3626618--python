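"""Core compound data model: descriptors, binary fingerprints, libraries.

Fingerprints are fixed-length binary vectors stored as sorted on-bit index
tuples (0-based).  :class:`CompoundLibrary` keeps insertion order -- that
order is the tie-breaking order used by every downstream stage -- and caches
dense / bit-packed numpy views so similarity kernels stay vectorised.

Similarity conventions
----------------------
* Tanimoto of two all-zero fingerprints is defined as 0.0 (a featureless
  pair is treated as maximally dissimilar so the ``< 0.7`` decoy filter can
  never exclude it); a warning is logged when this happens.
* Euclidean distance on binary vectors is ``sqrt(Hamming distance)``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LIBRARY_SOURCES = ("actives", "zinc_like", "mddr_like", "dud_generated", "custom")

CSV_COLUMNS = ["id", "structure", "mw", "logp", "hba", "hbd", "rotb", "fingerprint"]


class FingerprintLengthError(ValueError):
    """Raised when two fingerprints of different n_bits are compared."""


class DuplicateIdError(ValueError):
    """Raised when a library would contain the same molecule id twice."""


class AdapterRequiredError(ValueError):
    """Raised when structures must be featurised but no chemistry adapter is set."""


@dataclass(frozen=True)
class Descriptors:
    """The five physicochemical descriptors used for decoy property matching.

    mw
        molecular weight in Da, > 0.
    logp
        octanol-water partition coefficient.
    hba, hbd, rotb
        hydrogen-bond acceptor / donor and rotatable-bond counts
        (non-negative integers).
    """

    mw: float
    logp: float
    hba: int
    hbd: int
    rotb: int

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        for name in ("hba", "hbd", "rotb"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value}")
            object.__setattr__(self, name, int(value))


@dataclass(frozen=True)
class Fingerprint:
    """A binary fingerprint: bit-vector length plus the sorted on-bit indices."""

    n_bits: int
    on_bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError(f"n_bits must be positive, got {self.n_bits}")
        bits = tuple(sorted(set(int(b) for b in self.on_bits)))
        if bits and (bits[0] < 0 or bits[-1] >= self.n_bits):
            raise ValueError(f"on-bit index out of range [0, {self.n_bits})")
        object.__setattr__(self, "on_bits", bits)

    @classmethod
    def from_array(cls, bits: np.ndarray) -> "Fingerprint":
        bits = np.asarray(bits)
        return cls(n_bits=bits.shape[0], on_bits=tuple(np.flatnonzero(bits).tolist()))

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=bool)
        if self.on_bits:
            arr[list(self.on_bits)] = True
        return arr

    @property
    def popcount(self) -> int:
        return len(self.on_bits)


@dataclass
class MoleculeRecord:
    """One compound: id, optional structure, descriptors, fingerprint, labels."""

    id: str
    descriptors: Descriptors
    fingerprint: Fingerprint
    structure: Optional[str] = None
    scaffold: Optional[str] = None
    activity: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two equal-length fingerprints."""
    if a.n_bits != b.n_bits:
        raise FingerprintLengthError(f"n_bits mismatch: {a.n_bits} != {b.n_bits}")
    sa, sb = set(a.on_bits), set(b.on_bits)
    union = len(sa | sb)
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return len(sa & sb) / union


def euclidean_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Euclidean distance between binary vectors: sqrt(#differing bits)."""
    if a.n_bits != b.n_bits:
        raise FingerprintLengthError(f"n_bits mismatch: {a.n_bits} != {b.n_bits}")
    return math.sqrt(len(set(a.on_bits) ^ set(b.on_bits)))


def _pack_bits(matrix: np.ndarray) -> np.ndarray:
    """Pack a boolean (n, n_bits) matrix into bytes for popcount kernels."""
    return np.packbits(matrix, axis=1)


class CompoundLibrary:
    """Ordered, id-unique collection of molecules sharing one fingerprint length.

    Insertion order is stable and serves as the global tie-breaking order.
    Dense boolean and packed-byte fingerprint matrices plus descriptor arrays
    are built lazily and cached.
    """

    def __init__(self, source: str, records: Iterable[MoleculeRecord]):
        if source not in LIBRARY_SOURCES:
            raise ValueError(f"unknown source {source!r}; expected one of {LIBRARY_SOURCES}")
        self.source = source
        self.records: list[MoleculeRecord] = list(records)
        self._index: dict[str, int] = {}
        n_bits = None
        for i, rec in enumerate(self.records):
            if rec.id in self._index:
                raise DuplicateIdError(f"duplicate molecule id {rec.id!r}")
            self._index[rec.id] = i
            if n_bits is None:
                n_bits = rec.fingerprint.n_bits
            elif rec.fingerprint.n_bits != n_bits:
                raise FingerprintLengthError(
                    f"record {rec.id!r} has n_bits {rec.fingerprint.n_bits}, library has {n_bits}"
                )
        self.n_bits = n_bits
        self._bit_matrix: Optional[np.ndarray] = None
        self._packed: Optional[np.ndarray] = None
        self._popcounts: Optional[np.ndarray] = None
        self._descriptor_arrays: Optional[dict[str, np.ndarray]] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, key) -> MoleculeRecord:
        if isinstance(key, str):
            return self.records[self._index[key]]
        return self.records[key]

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._index

    def index_of(self, mol_id: str) -> int:
        return self._index[mol_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Sequence[int], source: Optional[str] = None) -> "CompoundLibrary":
        return CompoundLibrary(source or self.source, [self.records[i] for i in indices])

    # -- cached numeric views ----------------------------------------------
    def bit_matrix(self) -> np.ndarray:
        """Boolean (n_records, n_bits) fingerprint matrix in library order."""
        if self._bit_matrix is None:
            if self.n_bits is None:
                return np.zeros((0, 0), dtype=bool)
            mat = np.zeros((len(self.records), self.n_bits), dtype=bool)
            for i, rec in enumerate(self.records):
                if rec.fingerprint.on_bits:
                    mat[i, list(rec.fingerprint.on_bits)] = True
            self._bit_matrix = mat
        return self._bit_matrix

    def packed(self) -> np.ndarray:
        if self._packed is None:
            self._packed = _pack_bits(self.bit_matrix())
        return self._packed

    def popcounts(self) -> np.ndarray:
        if self._popcounts is None:
            self._popcounts = self.bit_matrix().sum(axis=1).astype(np.int64)
        return self._popcounts

    def descriptor_arrays(self) -> dict[str, np.ndarray]:
        if self._descriptor_arrays is None:
            d = {
                "mw": np.array([r.descriptors.mw for r in self.records], dtype=float),
                "logp": np.array([r.descriptors.logp for r in self.records], dtype=float),
                "hba": np.array([r.descriptors.hba for r in self.records], dtype=np.int64),
                "hbd": np.array([r.descriptors.hbd for r in self.records], dtype=np.int64),
                "rotb": np.array([r.descriptors.rotb for r in self.records], dtype=np.int64),
            }
            self._descriptor_arrays = d
        return self._descriptor_arrays


# -- bulk similarity kernels ------------------------------------------------

def bulk_tanimoto(library: CompoundLibrary, fp: Fingerprint) -> np.ndarray:
    """Tanimoto similarity of ``fp`` against every record of ``library``."""
    if library.n_bits is not None and fp.n_bits != library.n_bits:
        raise FingerprintLengthError(f"n_bits mismatch: {fp.n_bits} != {library.n_bits}")
    mat = library.bit_matrix()
    vec = fp.to_array()
    inter = (mat & vec).sum(axis=1)
    union = library.popcounts() + fp.popcount - inter
    with np.errstate(invalid="ignore"):
        sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sims


def hamming_cross(packed_a: np.ndarray, packed_b: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between packed bit rows of a and b.

    Returns an (len(a), len(b)) int64 matrix; squared Euclidean distance on
    binary vectors equals the Hamming distance.
    """
    xor = packed_a[:, None, :] ^ packed_b[None, :, :]
    return np.bitwise_count(xor).sum(axis=2, dtype=np.int64)


def tanimoto_cross(
    packed_a: np.ndarray,
    pop_a: np.ndarray,
    packed_b: np.ndarray,
    pop_b: np.ndarray,
) -> np.ndarray:
    """Pairwise Tanimoto similarities between packed bit rows of a and b."""
    inter = np.bitwise_count(packed_a[:, None, :] & packed_b[None, :, :]).sum(
        axis=2, dtype=np.int64
    )
    union = pop_a[:, None] + pop_b[None, :] - inter
    with np.errstate(invalid="ignore"):
        return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def total_tanimoto_distance(library: CompoundLibrary, block: int = 128) -> np.ndarray:
    """For each record, the summed Tanimoto distance (1 - sim) to all records."""
    packed = library.packed()
    pops = library.popcounts()
    n = len(library)
    totals = np.zeros(n, dtype=float)
    for start in range(0, n, block):
        stop = min(start + block, n)
        sims = tanimoto_cross(packed[start:stop], pops[start:stop], packed, pops)
        totals[start:stop] = (1.0 - sims).sum(axis=1)
    return totals


# -- chemistry adapter boundary ---------------------------------------------

# signature: structure (SMILES) -> (Descriptors, Fingerprint)
ChemistryAdapter = Callable[[str], tuple[Descriptors, Fingerprint]]


def rdkit_adapter(n_bits: int = 1024) -> ChemistryAdapter:
    """Build an adapter computing descriptors and a hashed path fingerprint.

    Emulates Daylight-type fingerprints via RDKit's path-based fingerprint.
    RDKit is imported lazily; the core pipeline never requires it.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors as RDDescriptors, Lipinski

    def adapter(structure: str) -> tuple[Descriptors, Fingerprint]:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {structure!r}")
        desc = Descriptors(
            mw=float(RDDescriptors.MolWt(mol)),
            logp=float(Crippen.MolLogP(mol)),
            hba=int(Lipinski.NumHAcceptors(mol)),
            hbd=int(Lipinski.NumHDonors(mol)),
            rotb=int(Lipinski.NumRotatableBonds(mol)),
        )
        bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
        fp = Fingerprint(n_bits=n_bits, on_bits=tuple(bv.GetOnBits()))
        return desc, fp

    return adapter


# -- library IO --------------------------------------------------------------

def _fingerprint_to_str(fp: Fingerprint) -> str:
    return ";".join(str(b) for b in fp.on_bits)


def _fingerprint_from_str(text: str, n_bits: int) -> Fingerprint:
    text = text.strip()
    bits = tuple(int(tok) for tok in text.split(";")) if text else ()
    return Fingerprint(n_bits=n_bits, on_bits=bits)


def read_library(
    path: str | Path,
    format: str = "csv",
    source: str = "custom",
    adapter: Optional[ChemistryAdapter] = None,
    n_bits: Optional[int] = None,
) -> CompoundLibrary:
    """Read a compound library from CSV or SMILES, preserving file order.

    The CSV layout is ``id,structure,mw,logp,hba,hbd,rotb,fingerprint`` with
    the fingerprint column holding semicolon-separated on-bit indices.  Rows
    giving only a structure are featurised through ``adapter``; without one an
    :class:`AdapterRequiredError` is raised.  SMILES files hold one
    ``SMILES<whitespace>id`` record per line and always need an adapter.
    """
    path = Path(path)
    if format == "smiles":
        if adapter is None:
            raise AdapterRequiredError(
                "SMILES input carries structures only; configure a chemistry adapter"
            )
        records = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'SMILES id', got {line!r}")
                smiles, mol_id = parts[0], parts[1]
                desc, fp = adapter(smiles)
                records.append(
                    MoleculeRecord(id=mol_id, structure=smiles, descriptors=desc, fingerprint=fp)
                )
        return CompoundLibrary(source, records)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'smiles'")

    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with an 'id' column")
        file_n_bits = n_bits
        for lineno, row in enumerate(reader, start=2):
            try:
                mol_id = row["id"]
                structure = (row.get("structure") or "").strip() or None
                has_explicit = all((row.get(c) or "").strip() for c in ("mw", "logp", "hba", "hbd", "rotb"))
                if has_explicit:
                    desc = Descriptors(
                        mw=float(row["mw"]),
                        logp=float(row["logp"]),
                        hba=int(row["hba"]),
                        hbd=int(row["hbd"]),
                        rotb=int(row["rotb"]),
                    )
                    fp_text = (row.get("fingerprint") or "").strip()
                    row_n_bits = (row.get("n_bits") or "").strip()
                    effective_n_bits = int(row_n_bits) if row_n_bits else file_n_bits
                    if effective_n_bits is None:
                        raise ValueError(
                            "fingerprint length unknown: pass n_bits= or include an "
                            "n_bits column"
                        )
                    fp = _fingerprint_from_str(fp_text, effective_n_bits)
                elif structure is not None:
                    if adapter is None:
                        raise AdapterRequiredError(
                            f"{path}:{lineno}: row gives a structure only; "
                            "configure a chemistry adapter"
                        )
                    desc, fp = adapter(structure)
                else:
                    raise ValueError("row has neither descriptors+fingerprint nor a structure")
            except AdapterRequiredError:
                raise
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row: {exc}") from exc
            scaffold = (row.get("scaffold") or "").strip() or None
            activity_text = (row.get("activity") or "").strip()
            activity = {"": None, "1": True, "0": False, "true": True, "false": False}.get(
                activity_text.lower(), None
            )
            records.append(
                MoleculeRecord(
                    id=mol_id,
                    structure=structure,
                    descriptors=desc,
                    fingerprint=fp,
                    scaffold=scaffold,
                    activity=activity,
                )
            )
    return CompoundLibrary(source, records)


def write_library(library: CompoundLibrary, path: str | Path) -> None:
    """Write a library to the CSV interchange format (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS + ["n_bits", "scaffold", "activity"])
        for rec in library:
            d = rec.descriptors
            writer.writerow(
                [
                    rec.id,
                    rec.structure or "",
                    repr(d.mw),
                    repr(d.logp),
                    d.hba,
                    d.hbd,
                    d.rotb,
                    _fingerprint_to_str(rec.fingerprint),
                    rec.fingerprint.n_bits,
                    rec.scaffold or "",
                    "" if rec.activity is None else int(rec.activity),
                ]
            )
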