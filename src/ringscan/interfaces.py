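"""E2/RING-E3 intermolecular interface contact mapping.

Contacts are residue pairs across two disjoint selections whose minimum
heavy-atom distance is within 4.0 A; the subset within 3.5 A is the
close-approach tier (both boundaries inclusive).  Backbone hydrogen bonds
are approximated as cross-chain backbone N...O pairs within 3.5 A with no
angle term, since crystal structures typically lack hydrogens.  Contact
residues are assigned to SCR regions I (N-loop), II (alpha-helix of the
beta-alpha region) and III (C-loop) through the alignment column they map to.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ringscan.core_surface import min_heavy_distance
from ringscan.io_model import Alignment, Residue, Structure

REGION_NUMERALS = {"N-loop": "I", "beta-alpha": "II", "C-loop": "III"}


@dataclass(frozen=True)
class ContactParams:
    contact_cutoff: float = 4.0
    close_cutoff: float = 3.5
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.close_cutoff > self.contact_cutoff:
            raise ValueError("close cutoff must not exceed contact cutoff")


@dataclass(frozen=True)
class Selection:
    """A chain plus optional inclusive residue range, e.g. ``A:381-420``."""

    chain_id: str
    start: int | None = None
    end: int | None = None

    _PATTERN = re.compile(r"^([^:]+)(?::(-?\d+)-(-?\d+))?$")

    @classmethod
    def parse(cls, spec: str) -> "Selection":
        m = cls._PATTERN.match(spec.strip())
        if not m:
            raise ValueError(f"bad selection spec {spec!r} (CHAIN or CHAIN:START-END)")
        chain, start, end = m.groups()
        return cls(chain, int(start) if start else None, int(end) if end else None)

    def residues(self, structure: Structure) -> list[Residue]:
        chain = structure.chain(self.chain_id)
        out = []
        for res in chain.residues:
            if self.start is not None and res.seq_num < self.start:
                continue
            if self.end is not None and res.seq_num > self.end:
                continue
            out.append(res)
        return out

    def overlaps(self, other: "Selection") -> bool:
        if self.chain_id != other.chain_id:
            return False
        lo_a = self.start if self.start is not None else -10**9
        hi_a = self.end if self.end is not None else 10**9
        lo_b = other.start if other.start is not None else -10**9
        hi_b = other.end if other.end is not None else 10**9
        return lo_a <= hi_b and lo_b <= hi_a


@dataclass
class ContactRecord:
    e3_residue: Residue
    e2_residue: Residue
    min_distance: float
    tier: str  # "contact" (<=4.0) or "close" (<=3.5)

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")


@dataclass
class HydrogenBond:
    donor_residue: Residue   # backbone N side
    acceptor_residue: Residue  # backbone O side
    distance: float


@dataclass
class InterfaceSummary:
    n_contact_residues_e3: int
    n_close_residues_e3: int
    region_assignment: dict[str, str]  # e3 residue label -> I/II/III/none
    hbonds: list[HydrogenBond] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)


def ring_selection(structure: Structure, chain_id: str, flank: int = 2) -> Selection:
    """Derive the RING-domain residue range of a chain from its sequence.

    The chain's one-letter sequence is scanned for the eight-position
    zinc-ligand pattern; the selection spans the ligand positions plus
    ``flank`` residues on each side, expressed in author numbering.  Raises
    when no pattern is found.
    """
    from ringscan.io_model import SequenceRecord
    from ringscan.ring_classifier import classify_sequence

    chain = structure.chain(chain_id)
    seq = "".join(r.aa1 for r in chain.residues)
    assignment = classify_sequence(SequenceRecord(f"{structure.id}_{chain_id}", seq))
    if not assignment.ligand_positions:
        raise ValueError(f"no zinc-ligand pattern found in chain {chain_id}")
    first = max(assignment.ligand_positions[0] - flank, 1)
    last = min(assignment.ligand_positions[-1] + flank, len(chain.residues))
    return Selection(
        chain_id,
        chain.residues[first - 1].seq_num,
        chain.residues[last - 1].seq_num,
    )


def extract_contacts(
    structure: Structure,
    e3_selection: Selection,
    e2_selection: Selection,
    params: ContactParams | None = None,
) -> list[ContactRecord]:
    """All cross-selection residue pairs within the contact cutoff.

    One record per pair with min heavy-atom distance <= contact_cutoff; the
    tier is "close" when the distance is also <= close_cutoff.  Records are
    sorted by E3 residue then distance.
    """
    params = params or ContactParams()
    if e3_selection.overlaps(e2_selection):
        raise ValueError("E3 and E2 selections overlap")
    e3_residues = e3_selection.residues(structure)
    e2_residues = e2_selection.residues(structure)
    if not e3_residues or not e2_residues:
        raise ValueError("empty selection")
    records = []
    for r3 in e3_residues:
        for r2 in e2_residues:
            d = min_heavy_distance(r3, r2)
            if d <= params.contact_cutoff:
                tier = "close" if d <= params.close_cutoff else "contact"
                records.append(ContactRecord(r3, r2, d, tier))
    order = {id(r): k for k, r in enumerate(e3_residues)}
    records.sort(key=lambda rec: (order[id(rec.e3_residue)], rec.min_distance))
    return records


def count_close_e3_residues(records: list[ContactRecord]) -> int:
    """Distinct E3 residues with at least one close-tier contact."""
    return len(
        {
            (r.e3_residue.chain_id, r.e3_residue.res_id)
            for r in records
            if r.tier == "close"
        }
    )


def detect_backbone_hbonds(
    structure: Structure,
    e3_selection: Selection,
    e2_selection: Selection,
    cutoff: float = 3.5,
) -> list[HydrogenBond]:
    """Cross-chain backbone N...O pairs within the cutoff (distance only)."""
    e3_residues = e3_selection.residues(structure)
    e2_residues = e2_selection.residues(structure)
    bonds = []
    for donors, acceptors in ((e3_residues, e2_residues), (e2_residues, e3_residues)):
        for rd in donors:
            n_atom = rd.atom("N")
            if n_atom is None:
                continue
            for ra in acceptors:
                o_atom = ra.atom("O")
                if o_atom is None:
                    continue
                d = float(np.linalg.norm(n_atom.xyz - o_atom.xyz))
                if d <= cutoff:
                    bonds.append(HydrogenBond(rd, ra, d))
    bonds.sort(key=lambda b: b.distance)
    return bonds


def assign_contacts_to_regions(
    records: list[ContactRecord],
    scr_segments,
    alignment: Alignment,
    e3_id: str,
    hbonds: list[HydrogenBond] | None = None,
) -> InterfaceSummary:
    """Label each contacting E3 residue with its SCR region (I/II/III).

    E3 residues are mapped to alignment columns through the row named
    ``e3_id`` (1-based residue index within the selection's chain); a residue
    whose column falls inside a labelled SCR gets that region's numeral,
    otherwise "none".  Unmappable residues are labelled none with a
    diagnostic.
    """
    region_of_col: dict[int, str] = {}
    for seg in scr_segments:
        label = getattr(seg, "region_label", None)
        numeral = REGION_NUMERALS.get(label or "", None)
        if numeral:
            for col in seg.columns():
                region_of_col[col] = numeral
    res_to_col = alignment.res_to_col(e3_id)
    diagnostics: list[str] = []
    assignment: dict[str, str] = {}
    contact_keys = set()
    close_keys = set()
    for rec in records:
        res = rec.e3_residue
        key = (res.chain_id, res.res_id)
        contact_keys.add(key)
        if rec.tier == "close":
            close_keys.add(key)
        if res.label in assignment:
            continue
        col = res_to_col.get(res.seq_num)
        if col is None:
            assignment[res.label] = "none"
            diagnostics.append(
                f"{res.label}: residue index {res.seq_num} not mappable to an "
                f"alignment column of {e3_id}"
            )
        else:
            assignment[res.label] = region_of_col.get(col, "none")
    return InterfaceSummary(
        n_contact_residues_e3=len(contact_keys),
        n_close_residues_e3=len(close_keys),
        region_assignment=assignment,
        hbonds=list(hbonds or []),
        diagnostics=diagnostics,
    )
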