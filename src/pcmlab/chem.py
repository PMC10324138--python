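"""Ligand curation and descriptors.

Curates raw SMILES/bioactivity tables into the modeling unit of
proteochemometrics — unique (compound, target) pairs with pIC50 responses —
and computes the ligand half of the descriptor space: Morgan count
fingerprints plus a pluggable block of physicochemical descriptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "BioactivityDataset",
    "LigandDescriptorBlock",
    "StandardizationReport",
    "standardize_library",
    "pic50_from_ic50",
    "deduplicate_bioactivities",
    "morgan_count_fingerprint",
    "morgan_fingerprint_block",
    "physchem_descriptors",
    "register_provider",
    "get_provider",
    "read_smiles_file",
    "write_smiles_file",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """A compound identified by ``id`` with its input and canonical SMILES."""

    id: str
    smiles: str
    canonical_form: str

    @classmethod
    def from_smiles(cls, id: str, smiles: str) -> "CompoundRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {id!r}: {smiles!r}")
        return cls(id=id, smiles=smiles, canonical_form=Chem.MolToSmiles(mol))


@dataclass
class BioactivityDataset:
    """Curated (compound, target, pIC50) pairs; pIC50 in -log10 molar units.

    The (compound_id, target_id) pair is the modeling unit: each row of the
    eventual feature matrix corresponds to one pair.
    """

    pairs: pd.DataFrame  # columns: compound_id, target_id, pic50

    def __post_init__(self) -> None:
        required = {"compound_id", "target_id", "pic50"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"bioactivity table missing columns: {sorted(missing)}")
        if self.pairs.duplicated(["compound_id", "target_id"]).any():
            raise ValueError("(compound_id, target_id) pairs must be unique after curation")
        if not np.isfinite(self.pairs["pic50"].to_numpy(float)).all():
            raise ValueError("pIC50 values must be finite")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def row_keys(self) -> list[tuple[str, str]]:
        return list(zip(self.pairs["compound_id"], self.pairs["target_id"]))

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BioactivityDataset":
        df = pd.read_csv(path, dtype={"compound_id": str, "target_id": str})
        if "pic50" not in df.columns and "ic50_nM" in df.columns:
            df["pic50"] = [pic50_from_ic50(v) for v in df["ic50_nM"]]
            df = df.drop(columns=["ic50_nM"])
        return cls(pairs=df[["compound_id", "target_id", "pic50"]])


@dataclass
class LigandDescriptorBlock:
    """Compound-by-descriptor matrix with per-column provenance.

    Provenance is ``"fingerprint"`` for Morgan count columns and
    ``"physchem"`` for physicochemical columns.
    """

    matrix: pd.DataFrame  # index: compound id, columns: descriptor names
    provenance: pd.Series  # per-column provenance tag

    def __post_init__(self) -> None:
        if list(self.provenance.index) != list(self.matrix.columns):
            raise ValueError("provenance index must match matrix columns")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    @staticmethod
    def concat(blocks: Sequence["LigandDescriptorBlock"]) -> "LigandDescriptorBlock":
        matrix = pd.concat([b.matrix for b in blocks], axis=1)
        if matrix.columns.duplicated().any():
            raise ValueError("descriptor blocks have overlapping column names")
        prov = pd.concat([b.provenance for b in blocks])
        return LigandDescriptorBlock(matrix=matrix, provenance=prov)

    def to_csv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "compound_id", out.index)
        header = pd.DataFrame(
            [["#provenance"] + list(self.provenance)], columns=out.columns
        )
        pd.concat([header, out]).to_csv(path, index=False)


@dataclass
class StandardizationReport:
    """What :func:`standardize_library` kept and why it dropped the rest."""

    n_input: int = 0
    kept_ids: list[str] = field(default_factory=list)
    removals: list[dict] = field(default_factory=list)  # {id, reason, detail}

    def add_removal(self, id: str, reason: str, detail: str = "") -> None:
        self.removals.append({"id": id, "reason": reason, "detail": detail})

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def _is_organic(mol: Chem.Mol) -> bool:
    """Organic = contains at least one carbon atom."""
    return any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms())


def standardize_library(
    records: Iterable[tuple[str, str]],
) -> tuple[list[CompoundRecord], StandardizationReport]:
    """Standardize a SMILES library: canonicalize, drop duplicates and inorganics.

    Parameters
    ----------
    records
        Iterable of ``(id, smiles)`` pairs.

    Returns
    -------
    kept, report
        ``kept`` holds one :class:`CompoundRecord` per distinct canonical
        structure; ``report`` lists every removal with its reason
        (``unparseable``, ``inorganic`` or ``duplicate``).

    Notes
    -----
    Molecules are never excluded for halogen count or molecular mass, and an
    unparseable SMILES is recorded in the report rather than raised. The
    operation is idempotent: re-standardizing the kept records changes nothing.
    """
    report = StandardizationReport()
    kept: list[CompoundRecord] = []
    seen: dict[str, str] = {}  # canonical smiles -> id of keeper
    for id, smiles in records:
        report.n_input += 1
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            report.add_removal(id, "unparseable", smiles)
            continue
        if not _is_organic(mol):
            report.add_removal(id, "inorganic", "no carbon atom")
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            report.add_removal(id, "duplicate", f"duplicate of {seen[canonical]}")
            continue
        seen[canonical] = id
        kept.append(CompoundRecord(id=id, smiles=smiles, canonical_form=canonical))
        report.kept_ids.append(id)
    return kept, report


def pic50_from_ic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in molar), with IC50 given in nM.

    1 nM maps to 9.0; a ten-fold increase in IC50 lowers pIC50 by one unit.
    """
    if not (ic50_nM > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    return -math.log10(ic50_nM * 1e-9)


def deduplicate_bioactivities(
    raw_pairs: pd.DataFrame,
) -> tuple[BioactivityDataset, int]:
    """Collapse replicate (compound, target) measurements to their mean pIC50.

    Returns the curated dataset and the number of rows collapsed away.
    """
    df = raw_pairs[["compound_id", "target_id", "pic50"]].copy()
    if not np.isfinite(df["pic50"].to_numpy(float)).all():
        raise ValueError("pIC50 values must be finite before deduplication")
    collapsed = (
        df.groupby(["compound_id", "target_id"], as_index=False, sort=False)["pic50"]
        .mean()
    )
    n_collapsed = len(df) - len(collapsed)
    return BioactivityDataset(pairs=collapsed), n_collapsed


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def _mol_for(record: CompoundRecord | str, id: str | None = None) -> Chem.Mol:
    if isinstance(record, CompoundRecord):
        smiles, id = record.canonical_form, record.id
    else:
        smiles = record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable molecule {id or smiles!r}")
    return mol


def morgan_count_fingerprint(
    record: CompoundRecord | str, radius: int = 2, length: int = 512
) -> np.ndarray:
    """Hashed Morgan count fingerprint of fixed ``length``.

    Radius 2 captures circular substructures up to a diameter of four bonds.
    Counts record how many atom environments hash to each position, so the
    entries are nonnegative integers and invariant to SMILES atom ordering.
    """
    mol = _mol_for(record)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(length, dtype=np.int64)
    for bit, count in fp.GetNonzeroElements().items():
        vec[bit] = count
    return vec


def unhashed_morgan_environments(
    record: CompoundRecord | str, radius: int = 2
) -> dict[int, int]:
    """Sparse Morgan environment identifiers -> counts (no hashing to a fixed length).

    Exposed as a divergence switch: fixed-length hashed counts are the default
    representation, but the raw environment identifiers let a dataset-level
    unhashed count array be assembled when interpretability matters more than
    a fixed column count.
    """
    mol = _mol_for(record)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return dict(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def morgan_fingerprint_block(
    records: Sequence[CompoundRecord], radius: int = 2, length: int = 512
) -> LigandDescriptorBlock:
    """Morgan count fingerprints for a library, as a descriptor block.

    Columns are named ``fp_0 .. fp_{length-1}`` after the hashed bit index.
    """
    rows = np.vstack([morgan_count_fingerprint(r, radius, length) for r in records])
    names = [f"fp_{i}" for i in range(length)]
    matrix = pd.DataFrame(rows, index=[r.id for r in records], columns=names)
    prov = pd.Series("fingerprint", index=names)
    return LigandDescriptorBlock(matrix=matrix, provenance=prov)


# ---------------------------------------------------------------------------
# physicochemical descriptors (pluggable providers)
# ---------------------------------------------------------------------------

# a provider maps a Chem.Mol to an ordered {name: value} mapping
PhyschemProvider = Callable[[Chem.Mol], Mapping[str, float]]

_PROVIDERS: dict[str, PhyschemProvider] = {}


def register_provider(name: str, provider: PhyschemProvider) -> None:
    """Register a physicochemical descriptor provider under ``name``."""
    _PROVIDERS[name] = provider


def get_provider(name: str) -> PhyschemProvider:
    if name not in _PROVIDERS:
        raise KeyError(
            f"no physchem provider {name!r}; registered: {sorted(_PROVIDERS)}"
        )
    return _PROVIDERS[name]


_MINIMAL_DESCRIPTORS: list[tuple[str, Callable[[Chem.Mol], float]]] = [
    ("HeavyAtomCount", Descriptors.HeavyAtomCount),
    ("RingCount", Descriptors.RingCount),
    ("AromaticRingCount", rdMolDescriptors.CalcNumAromaticRings),
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Descriptors.MolLogP),
    ("TPSA", Descriptors.TPSA),
    ("NumHAcceptors", Descriptors.NumHAcceptors),
    ("NumHDonors", Descriptors.NumHDonors),
    ("NumRotatableBonds", Descriptors.NumRotatableBonds),
    ("FractionCSP3", Descriptors.FractionCSP3),
    ("Chi0", Descriptors.Chi0),
    ("Chi1", Descriptors.Chi1),
    ("Chi0v", Descriptors.Chi0v),
    ("Chi1v", Descriptors.Chi1v),
    ("Kappa1", Descriptors.Kappa1),
    ("Kappa2", Descriptors.Kappa2),
    ("BalabanJ", Descriptors.BalabanJ),
    ("BertzCT", Descriptors.BertzCT),
    ("LabuteASA", Descriptors.LabuteASA),
    ("HallKierAlpha", Descriptors.HallKierAlpha),
]


def minimal_provider(mol: Chem.Mol) -> dict[str, float]:
    """Bundled provider: simple RDKit 2D topological/physicochemical descriptors."""
    return {name: float(fn(mol)) for name, fn in _MINIMAL_DESCRIPTORS}


register_provider("rdkit-minimal", minimal_provider)


def physchem_descriptors(
    records: Sequence[CompoundRecord],
    provider: str | PhyschemProvider = "rdkit-minimal",
) -> tuple[LigandDescriptorBlock, list[str]]:
    """Physicochemical descriptor matrix from a registered provider.

    A provider failure on one molecule yields NA entries for that row (to be
    imputed downstream) and the id is returned in the failure list; it is
    never fatal.
    """
    fn = get_provider(provider) if isinstance(provider, str) else provider
    rows: list[Mapping[str, float]] = []
    failed: list[str] = []
    columns: list[str] | None = None
    for rec in records:
        try:
            values = fn(_mol_for(rec))
            rows.append(dict(values))
            if columns is None:
                columns = list(values)
        except Exception:
            failed.append(rec.id)
            rows.append({})
    if columns is None:
        raise ValueError("provider failed on every molecule")
    matrix = pd.DataFrame(rows, index=[r.id for r in records], columns=columns)
    prov = pd.Series("physchem", index=columns)
    return LigandDescriptorBlock(matrix=matrix, provenance=prov), failed


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, ``SMILES[<ws>id]``."""
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            records.append((id, smiles))
    return records


def write_smiles_file(path, records: Sequence[CompoundRecord | tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, CompoundRecord):
                fh.write(f"{rec.smiles}\t{rec.id}\n")
            else:
                id, smiles = rec
                fh.write(f"{smiles}\t{id}\n")
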