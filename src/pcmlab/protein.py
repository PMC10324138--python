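"""Binding-site descriptors.

Parses multiple sequence alignments, optionally selects cavity residues from
a structure by distance to a bound ligand, and encodes each site residue with
the five Z-scale amino-acid property descriptors so that homologous targets
share a coordinate-wise comparable descriptor space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser

__all__ = [
    "ZScaleTable",
    "BindingSite",
    "load_zscale_table",
    "read_alignment",
    "select_binding_site",
    "zscale_descriptors",
    "zscale_block",
    "sites_from_alignment",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


# ---------------------------------------------------------------------------
# Z-scale table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZScaleTable:
    """Five principal-property scales (Z1..Z5) for the 20 standard amino acids.

    Values are published constants loaded from the bundled data file (see the
    file header for the citation); they are never typed inline in code.
    """

    values: pd.DataFrame  # index: one-letter code, columns: z1..z5

    def __post_init__(self) -> None:
        if set(self.values.index) != STANDARD_AA:
            raise ValueError("Z-scale table must cover exactly the 20 standard amino acids")
        if list(self.values.columns) != ["z1", "z2", "z3", "z4", "z5"]:
            raise ValueError("Z-scale table must have columns z1..z5")

    def row(self, aa: str) -> np.ndarray:
        if aa not in self.values.index:
            raise KeyError(f"no Z-scale entry for residue {aa!r}")
        return self.values.loc[aa].to_numpy(float)


def load_zscale_table() -> ZScaleTable:
    """Load the bundled five-scale Z-scale table."""
    ref = resources.files("pcmlab") / "data" / "zscales_sandberg1998.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#", index_col="aa")
    return ZScaleTable(values=df)


# ---------------------------------------------------------------------------
# binding sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSite:
    """Ordered site positions and the residues a target presents at them.

    Positions are 1-based alignment-column (or residue-number) indices and
    strictly increasing, so two homologous sites align coordinate-wise.
    """

    target_id: str
    positions: tuple[int, ...]
    residues: str

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.residues):
            raise ValueError("positions and residues must have equal length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        bad = [
            (pos, aa)
            for pos, aa in zip(self.positions, self.residues)
            if aa not in STANDARD_AA
        ]
        if bad:
            raise ValueError(f"nonstandard residues at positions {bad}")

    def __len__(self) -> int:
        return len(self.positions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "target_id": self.target_id,
                    "positions": list(self.positions),
                    "residues": self.residues,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "BindingSite":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            target_id=d["target_id"],
            positions=tuple(d["positions"]),
            residues=d["residues"],
        )


def read_alignment(path, format: str = "fasta"):
    """Read an alignment and build the column -> residue-index map.

    Returns ``(alignment, column_map)`` where ``column_map[seq_id]`` is a list
    over alignment columns holding the 1-based residue index in that sequence,
    or ``None`` where the sequence has a gap. All sequences must share one
    aligned length; a ragged alignment raises with the offending id.
    """
    fmt = {"fasta": "fasta", "clustal": "clustal"}[format.lower()]
    if fmt == "fasta":
        # AlignIO rejects ragged FASTA without naming the culprit; check ourselves
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        length = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != length:
                raise ValueError(
                    f"ragged alignment: sequence {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {length}"
                )
        from Bio.Align import MultipleSeqAlignment

        alignment = MultipleSeqAlignment(records)
    else:
        alignment = AlignIO.read(path, fmt)

    column_map: dict[str, list[int | None]] = {}
    for rec in alignment:
        indices: list[int | None] = []
        count = 0
        for ch in str(rec.seq):
            if ch in ("-", "."):
                indices.append(None)
            else:
                count += 1
                indices.append(count)
        column_map[rec.id] = indices
    return alignment, column_map


def sites_from_alignment(
    alignment, positions: tuple[int, ...] | list[int]
) -> list[BindingSite]:
    """Extract one BindingSite per aligned sequence at 1-based alignment columns."""
    positions = tuple(int(p) for p in positions)
    sites = []
    for rec in alignment:
        seq = str(rec.seq)
        residues = "".join(seq[p - 1] for p in positions)
        sites.append(BindingSite(target_id=rec.id, positions=positions, residues=residues))
    return sites


def select_binding_site(
    structure_path,
    ligand_resname: str,
    cutoff: float = 10.0,
    target_id: str | None = None,
) -> BindingSite:
    """Select cavity residues within ``cutoff`` angstroms of a bound ligand.

    The ligand reference point is the unweighted geometric center of its heavy
    atoms; a residue is included iff any of its own heavy atoms lies within
    ``cutoff`` of that center. Residues are returned in sequence order with
    their residue numbers as positions.

    Raises if the ligand is absent, listing the hetero residues present.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", structure_path)
    model = next(structure.get_models())

    ligand_atoms = []
    hetero_names = set()
    protein_residues = []
    for chain in model:
        for res in chain:
            hetflag = res.id[0].strip()
            if hetflag and hetflag != "W":
                hetero_names.add(res.resname.strip())
            if res.resname.strip() == ligand_resname:
                ligand_atoms.extend(
                    a for a in res.get_atoms() if a.element.strip().upper() != "H"
                )
            elif not hetflag and res.resname.strip() in _THREE_TO_ONE:
                protein_residues.append(res)

    if not ligand_atoms:
        raise ValueError(
            f"ligand {ligand_resname!r} not found; hetero residues present: "
            f"{sorted(hetero_names) or 'none'}"
        )

    center = np.mean([a.coord for a in ligand_atoms], axis=0)

    selected: list[tuple[int, str]] = []
    for res in protein_residues:
        coords = np.array(
            [a.coord for a in res.get_atoms() if a.element.strip().upper() != "H"]
        )
        if coords.size and np.min(np.linalg.norm(coords - center, axis=1)) <= cutoff:
            selected.append((res.id[1], _THREE_TO_ONE[res.resname.strip()]))

    selected.sort(key=lambda t: t[0])
    return BindingSite(
        target_id=target_id or structure.id,
        positions=tuple(p for p, _ in selected),
        residues="".join(aa for _, aa in selected),
    )


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def zscale_descriptors(
    site: BindingSite, table: ZScaleTable | None = None
) -> pd.Series:
    """Five Z-scale values per site residue, position-major.

    An L-residue site yields 5L descriptors named ``Z{k}_Aa{position}``
    (k = 1..5), in position-major, scale-minor order. The encoding is a pure
    table lookup, so identical residues at a position produce identical
    descriptor values across targets.
    """
    table = table or load_zscale_table()
    names: list[str] = []
    values: list[float] = []
    for pos, aa in zip(site.positions, site.residues):
        try:
            row = table.row(aa)
        except KeyError as exc:
            raise ValueError(f"nonstandard residue {aa!r} at position {pos}") from exc
        for k in range(5):
            names.append(f"Z{k + 1}_Aa{pos}")
            values.append(float(row[k]))
    return pd.Series(values, index=names, name=site.target_id)


def zscale_block(
    sites: list[BindingSite], table: ZScaleTable | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack per-site Z-scale descriptors into a target-by-descriptor matrix.

    All sites must share the same position set. Returns the matrix (index:
    target id) and a per-column provenance Series tagged ``"protein-zscale"``.
    """
    table = table or load_zscale_table()
    position_sets = {s.positions for s in sites}
    if len(position_sets) > 1:
        raise ValueError("all binding sites must share the same positions")
    rows = [zscale_descriptors(s, table) for s in sites]
    matrix = pd.DataFrame(rows)
    matrix.index = [s.target_id for s in sites]
    prov = pd.Series("protein-zscale", index=matrix.columns)
    return matrix, prov
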