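"""Zinc-ligand pattern scanning and RING-type assignment.

A RING (non-U-box) domain chelates two zinc ions through eight ordered
"metal ligand positions".  The residue identities at those positions name the
type: the canonical pattern is C3HC4 (C,C,C,H,C,C,C,C); recognized departures
are an extra His at position 5 (C3H2C3), a His/Cys swap at positions 4/5
(C4HC3), Gly at position 5 (C3HGC3), Asp at position 8 (C3HC3D) or at
position 5 (RING-D), Ser/Thr at positions 2 and/or 6 (RING-S/T), eight
cysteines (C4C4), and the twelve-ligand three-zinc C6H3C2D composition.
U-box domains share the fold but lack the metal-chelating residues and are
assigned only from an upstream annotation hint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ringscan.io_model import SequenceRecord

#: the C3HC4 reference letters at the eight metal ligand positions
REFERENCE_PATTERN = ("C", "C", "C", "H", "C", "C", "C", "C")

#: letters that may ever occupy a metal ligand position
LIGAND_ALPHABET = frozenset("CHDGST")

#: per-position allowed letters (1-based positions 1..8); positions 1, 3 and 7
#: are invariant Cys in every named type
DEFAULT_POSITION_ALPHABET: tuple[frozenset[str], ...] = (
    frozenset("C"),
    frozenset("CST"),
    frozenset("C"),
    frozenset("CH"),
    frozenset("CHGD"),
    frozenset("CST"),
    frozenset("C"),
    frozenset("CD"),
)

#: allowed residue counts between consecutive ligand positions, bracketing the
#: canonical RING spacing C-x2-C-x(9..39)-C-x(1..3)-H-x(2..3)-C-x2-C-x(4..48)-C-x2-C
DEFAULT_GAP_RANGES: tuple[tuple[int, int], ...] = (
    (1, 3),
    (8, 40),
    (1, 4),
    (1, 4),
    (1, 3),
    (3, 50),
    (1, 3),
)

TYPE_LABELS = (
    "C3HC4", "C3H2C3", "C3HC3D", "C4HC3", "C3HGC3", "C4C4",
    "C6H3C2D", "U-box", "RING-D", "RING-S/T", "unclassified",
)


@dataclass(frozen=True)
class LigandSpacingModel:
    """Spacing and per-position alphabet constraints for the 8-position scan."""

    gap_ranges: tuple[tuple[int, int], ...] = DEFAULT_GAP_RANGES
    position_alphabet: tuple[frozenset[str], ...] = DEFAULT_POSITION_ALPHABET

    def __post_init__(self) -> None:
        if len(self.gap_ranges) != len(self.position_alphabet) - 1:
            raise ValueError("need one gap range per consecutive position pair")
        for lo, hi in self.gap_ranges:
            if lo > hi or lo < 0:
                raise ValueError(f"bad gap range ({lo},{hi})")

    @property
    def n_positions(self) -> int:
        return len(self.position_alphabet)


@dataclass
class RingAssignment:
    """Detected metal-ligand positions and the assigned RING type."""

    seq_id: str
    ligand_positions: tuple[int, ...]
    ligand_letters: tuple[str, ...]
    type_label: str
    substitutions: list[tuple[int, str]] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.ligand_positions and list(self.ligand_positions) != sorted(
            set(self.ligand_positions)
        ):
            raise ValueError("ligand positions must be strictly increasing")
        if self.type_label not in TYPE_LABELS:
            raise ValueError(f"unknown type label {self.type_label!r}")


def scan_ligand_positions(
    seq: SequenceRecord | str,
    model: LigandSpacingModel | None = None,
) -> list[tuple[int, ...]]:
    """Find all 8-position ligand candidates satisfying the spacing model.

    Returns candidate position vectors (1-based, strictly increasing) in
    left-to-right order of first position; overlapping candidates allowed.
    """
    model = model or LigandSpacingModel()
    letters = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    n = len(letters)
    npos = model.n_positions
    # index letters once per allowed set for the backtracking scan
    candidates: list[tuple[int, ...]] = []

    def extend(partial: list[int]) -> None:
        k = len(partial)
        if k == npos:
            candidates.append(tuple(partial))
            return
        lo, hi = model.gap_ranges[k - 1]
        prev = partial[-1]
        for pos in range(prev + lo + 1, min(prev + hi + 1, n) + 1):
            if letters[pos - 1] in model.position_alphabet[k]:
                partial.append(pos)
                extend(partial)
                partial.pop()

    for start in range(1, n + 1):
        if letters[start - 1] in model.position_alphabet[0]:
            extend([start])
    candidates.sort()
    return candidates


def classify_ring_type(ligand_letters: tuple[str, ...] | str) -> tuple[str, list[tuple[int, str]]]:
    """Assign a type label to eight ligand letters; total and deterministic.

    The substitutions list records every position whose letter departs from
    the C3HC4 reference.  Combinations the type inventory does not name are
    returned as ``unclassified`` rather than forced into a nearby label.
    """
    p = tuple(str(ligand_letters).upper()) if isinstance(ligand_letters, str) else tuple(
        s.upper() for s in ligand_letters
    )
    if len(p) != 8:
        raise ValueError(f"need exactly 8 ligand letters, got {len(p)}")
    subs = [
        (i, letter)
        for i, (letter, ref) in enumerate(zip(p, REFERENCE_PATTERN), start=1)
        if letter != ref
    ]
    if any(letter not in LIGAND_ALPHABET for letter in p):
        return "unclassified", subs

    def others_are(positions: tuple[int, ...], letter: str = "C") -> bool:
        return all(p[i - 1] == letter for i in positions)

    p2, p4, p5, p6, p8 = p[1], p[3], p[4], p[5], p[7]
    if (p2 in "ST" or p6 in "ST") and (
        p2 in "CST" and p6 in "CST" and p4 == "H" and p5 == "C"
        and others_are((1, 3, 7, 8))
    ):
        return "RING-S/T", subs
    if p5 == "D" and p4 == "H" and others_are((1, 2, 3, 6, 7, 8)):
        return "RING-D", subs
    if (p4, p5) == ("H", "C") and others_are((1, 2, 3, 6, 7)):
        if p8 == "D":
            return "C3HC3D", subs
        if p8 == "C":
            return "C3HC4", subs
    if (p4, p5) == ("H", "H") and others_are((1, 2, 3, 6, 7, 8)):
        return "C3H2C3", subs
    if (p4, p5) == ("C", "H") and others_are((1, 2, 3, 6, 7, 8)):
        return "C4HC3", subs
    if (p4, p5) == ("H", "G") and others_are((1, 2, 3, 6, 7, 8)):
        return "C3HGC3", subs
    if all(letter == "C" for letter in p):
        return "C4C4", subs
    return "unclassified", subs


# -- three-zinc (12-ligand) composition scan --------------------------------

#: spacing for the 12-position scan: uniform permissive gaps, since no
#: canonical spacing is established for the third zinc site
DEFAULT_GAP_RANGES_12 = tuple((1, 20) for _ in range(11))


def _matches_three_zinc_composition(letters: tuple[str, ...]) -> bool:
    """Composition test for C6H3C2D: 3 His, the rest Cys, except that one Asp
    may stand at position 8 or 12.  The ligand order of the third zinc site is
    not fixed, so this is a deliberately permissive composition check."""
    if len(letters) != 12:
        return False
    n_h = letters.count("H")
    n_c = letters.count("C")
    n_d = letters.count("D")
    if n_h != 3 or n_h + n_c + n_d != 12 or n_d > 1:
        return False
    if n_d == 1 and letters[7] != "D" and letters[11] != "D":
        return False
    return True


def scan_three_zinc(
    seq: SequenceRecord | str,
    gap_ranges: tuple[tuple[int, int], ...] = DEFAULT_GAP_RANGES_12,
) -> list[tuple[int, ...]]:
    """12-position scan for the three-zinc C6H3C2D composition."""
    alphabet = tuple(frozenset("CHD") for _ in range(12))
    model = LigandSpacingModel(gap_ranges=gap_ranges, position_alphabet=alphabet)
    letters = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    hits = []
    for cand in scan_ligand_positions(seq, model):
        cand_letters = tuple(letters[i - 1] for i in cand)
        if _matches_three_zinc_composition(cand_letters):
            hits.append(cand)
    return hits


def classify_sequence(
    seq: SequenceRecord,
    model: LigandSpacingModel | None = None,
    annotation_hint: str | None = None,
    enable_three_zinc: bool = False,
) -> RingAssignment:
    """Scan a sequence and assign its RING type.

    The best-scoring candidate (fewest substitutions from the C3HC4
    reference, then leftmost) is classified.  When no candidate exists, an
    upstream "U-box" annotation hint yields the U-box label (U-box domains
    lack the metal-chelating residues entirely); otherwise, if the three-zinc
    scan is enabled and matches, the composition-based C6H3C2D label is
    assigned with an explanatory note; else the sequence is unclassified.
    """
    candidates = scan_ligand_positions(seq, model)
    letters = seq.residues
    scored = []
    for cand in candidates:
        cand_letters = tuple(letters[i - 1] for i in cand)
        label, subs = classify_ring_type(cand_letters)
        scored.append((len(subs), cand, cand_letters, label, subs))
    if scored:
        scored.sort(key=lambda t: (t[0], t[1]))
        _, cand, cand_letters, label, subs = scored[0]
        return RingAssignment(
            seq_id=seq.id,
            ligand_positions=cand,
            ligand_letters=cand_letters,
            type_label=label,
            substitutions=subs,
        )
    if annotation_hint == "U-box":
        return RingAssignment(
            seq_id=seq.id, ligand_positions=(), ligand_letters=(),
            type_label="U-box", note="assigned from domain-annotation hint",
        )
    if enable_three_zinc:
        hits = scan_three_zinc(seq)
        if hits:
            cand = hits[0]
            return RingAssignment(
                seq_id=seq.id,
                ligand_positions=cand,
                ligand_letters=tuple(letters[i - 1] for i in cand),
                type_label="C6H3C2D",
                note="composition-based 12-ligand match; third-site ligand "
                     "order is not verified",
            )
    return RingAssignment(
        seq_id=seq.id, ligand_positions=(), ligand_letters=(),
        type_label="unclassified",
    )
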