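"""Shared coordinate/sequence data model and readers/writers.

Coordinate files are read with :mod:`gemmi` (PDB dialect: ATOM records only,
first model by default, altloc duplicates resolved to the highest-occupancy
conformer with ties going to 'A', waters excluded).  Alignments are aligned
FASTA via Biopython; similarity hit tables are 12-column BLAST ``outfmt 6``
TSV via pandas.  All coordinates are 1-based and inclusive: alignment columns,
residue indices and domain intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = set(AA3_TO_1.values())
GAP = "-"
WATER_NAMES = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class Atom:
    """A single atom with Cartesian coordinates in Angstroms."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    """One residue: author numbering plus insertion code identify it."""

    chain_id: str
    seq_num: int
    name3: str
    atoms: list[Atom]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name3} {self.seq_num} has no atoms")

    @property
    def aa1(self) -> str:
        return AA3_TO_1.get(self.name3.upper(), "X")

    @property
    def res_id(self) -> tuple[int, str]:
        return (self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name3}{self.seq_num}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.res_id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate residue identifiers in chain {self.id}")


@dataclass
class Structure:
    """A single-conformer coordinate set (one model)."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in structure {self.id}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id}")

    @property
    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence over the 20 standard letters plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"{self.id}: letters outside alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Gapped rows of equal length; columns are 1-based."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows length mismatch")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate sequence ids in alignment")
        if not self.rows:
            raise FormatError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise KeyError(f"id {row_id!r} not in alignment") from None

    def degap(self, row_id: str) -> SequenceRecord:
        return SequenceRecord(row_id, self.row(row_id).replace(GAP, ""))

    def column(self, col: int) -> str:
        if not 1 <= col <= self.ncol:
            raise IndexError(f"column {col} outside 1..{self.ncol}")
        return "".join(r[col - 1] for r in self.rows)

    def col_to_res(self, row_id: str) -> dict[int, int]:
        """Map alignment column -> 1-based residue index (gaps absent)."""
        mapping: dict[int, int] = {}
        idx = 0
        for col, letter in enumerate(self.row(row_id), start=1):
            if letter != GAP:
                idx += 1
                mapping[col] = idx
        return mapping

    def res_to_col(self, row_id: str) -> dict[int, int]:
        return {res: col for col, res in self.col_to_res(row_id).items()}


@dataclass(frozen=True)
class HitRecord:
    """One line of a BLAST tabular hit table (the five consumed columns)."""

    query_id: str
    subject_id: str
    pct_identity: float
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")


@dataclass
class DomainArchitecture:
    """Ordered domain intervals (1-based inclusive) on one protein."""

    protein_id: str
    domains: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, start, end in self.domains:
            if start > end:
                raise ValueError(f"{self.protein_id}: domain {name} start>{end}")
        self.domains.sort(key=lambda d: (d[1], d[2], d[0]))
        if len(set(self.domains)) != len(self.domains):
            raise ValueError(f"{self.protein_id}: duplicate domain intervals")

    @property
    def names(self) -> list[str]:
        return [d[0] for d in self.domains]


# ---------------------------------------------------------------------------
# readers / writers


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> 'A'."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        # ties resolved toward altloc 'A' (then lexicographic for determinism)
        best = min(group, key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc))
        kept.append(best)
    return kept


def read_structure(
    path: str | Path,
    model_index: int = 0,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB coordinate file into the package's structure model.

    Only ATOM records of the requested model are kept (first model by
    default); waters and HETATM entries are excluded; for altloc duplicates
    the highest-occupancy conformer wins, ties going to altloc 'A'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if model_index >= len(st):
        raise FormatError(
            f"{path}: model index {model_index} absent ({len(st)} model(s))"
        )
    model = st[model_index]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.het_flag != "A":  # ATOM records only (drops HETATM + waters)
                continue
            if gres.name in WATER_NAMES:
                continue
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coord=(ga.pos.x, ga.pos.y, ga.pos.z),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc.strip("\x00") if ga.altloc else "",
                )
                for ga in gres
            ]
            atoms = _resolve_altlocs(atoms)
            if atoms:
                residues.append(
                    Residue(
                        chain_id=gchain.name,
                        seq_num=gres.seqid.num,
                        name3=gres.name,
                        atoms=atoms,
                        icode=(gres.seqid.icode or "").strip(),
                    )
                )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains:
        raise FormatError(f"{path}: no ATOM records")
    return Structure(
        id=structure_id if structure_id is not None else path.stem,
        chains=chains,
        model_index=model_index,
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write fixed-width PDB ATOM records (coordinates to 3 decimals)."""
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB atom-name column rules: 1-letter elements start in col 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:>5d} {padded}{atom.altloc or ' '}"
                    f"{res.name3:>3s} {chain.id[:1]}{res.seq_num:>4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:>5d}      {chain.residues[-1].name3:>3s} "
                     f"{chain.id[:1]}{chain.residues[-1].seq_num:>4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped FASTA sequences."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper().replace(GAP, ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (all records the same gapped length)."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise FormatError(f"{path}: empty alignment file")
    return Alignment(row_ids=ids, rows=rows)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(alignment.row_ids, alignment.rows):
            fh.write(f">{rid}\n{row}\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


#: column names of the 12-column BLAST tabular dialect (outfmt 6)
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column BLAST tabular TSV; order preserved."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise FormatError(f"{path}: expected 12 tab-separated columns")
    for col in ("pident", "evalue", "bitscore"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            bad = df.loc[values.isna()].index[0] + 1
            raise FormatError(f"{path}: unparsable numeric in column {col}, line {bad}")
        df[col] = values
    if df[["qseqid", "sseqid"]].isna().any().any():
        raise FormatError(f"{path}: missing id fields")
    return [
        HitRecord(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            pct_identity=float(row.pident),
            bit_score=float(row.bitscore),
            e_value=float(row.evalue),
        )
        for row in df.itertuples()
    ]


def write_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hit records as 12-column BLAST tabular (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t0\t0\t0"
                f"\t0\t0\t0\t0\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


def read_architectures(path: str | Path) -> list[DomainArchitecture]:
    """Read a domain-architecture TSV: protein_id, domain, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain": str})
    required = {"protein_id", "domain", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    out = []
    for pid, group in df.groupby("protein_id", sort=False):
        domains = [
            (row.domain, int(row.start), int(row.end)) for row in group.itertuples()
        ]
        out.append(DomainArchitecture(protein_id=str(pid), domains=domains))
    return out
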