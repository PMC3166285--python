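"""Alignment-column consensus and conservation scoring.

A column's consensus is either a single residue letter (identity consensus)
or the most specific residue class whose aggregate fraction of non-gap
entries reaches the consensus level threshold (default 0.8).  Conservation is
an entropy-based 0-9 index; columns scoring above 4 count as conserved.  The
class alphabet and its one-character symbols follow the standard
physico-chemical grouping used for RING-domain alignment annotation.

Specificity order for class consensus: identity first, then the small
specific classes (aliphatic, aromatic, alcohol, tiny, negative, positive),
then charged, hydrophobic, small, polar, bulky — so a column of {I,V,L} reads
'l' (aliphatic) rather than 'h' (hydrophobic) even though both qualify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ringscan.io_model import GAP, STANDARD_AA, Alignment

#: (class name, symbol, members) in the printed alphabet order
RESIDUE_CLASSES: tuple[tuple[str, str, frozenset[str]], ...] = (
    ("aliphatic", "l", frozenset("IVL")),
    ("aromatic", "@", frozenset("YHWF")),
    ("hydrophobic", "h", frozenset("WFYMLIVACTH")),
    ("alcohol", "o", frozenset("ST")),
    ("polar", "p", frozenset("DEHKNQRST")),
    ("tiny", "t", frozenset("AGCS")),
    ("small", "s", frozenset("AGCSVNDTP")),
    ("bulky", "b", frozenset("EFIKLMQRWY")),
    ("positive", "+", frozenset("KRH")),
    ("negative", "−", frozenset("DE")),
    ("charged", "c", frozenset("DEKRH")),
)

CLASS_BY_SYMBOL = {symbol: members for _, symbol, members in RESIDUE_CLASSES}

#: symbols tried in order when no single letter reaches the threshold
CLASS_PRIORITY: tuple[str, ...] = ("l", "@", "o", "t", "−", "+", "c", "h", "s", "p", "b")

HYDROPHOBIC_SYMBOLS = frozenset({"l", "@", "h"})
POLAR_SYMBOLS = frozenset({"p", "+", "−", "c", "o"})

_LN20 = math.log(20.0)


@dataclass
class ColumnProfile:
    """Per-column letter/class fractions, consensus call and conservation."""

    column: int
    n_nongap: int
    fractions: dict[str, float]
    class_fractions: dict[str, float]
    consensus_symbol: str | None
    consensus_level: float
    conservation_index: int
    low_support: bool = False

    @property
    def is_conserved(self) -> bool:
        return self.consensus_symbol is not None and self.conservation_index > 4

    @property
    def consensus_is_class(self) -> bool:
        return self.consensus_symbol in CLASS_BY_SYMBOL


@dataclass
class EquivalentResidueSet:
    """The six role-labelled conserved columns flanking the zinc ligands.

    Roles: hydro1 (N-loop), hydro2/hydro3 (beta-alpha region, in column
    order), hydro4 (C-loop), polar1 (alpha-helix of the beta-alpha region),
    polar2 (C-loop).  ``residue_indices`` maps role -> {row_id: 1-based
    residue index}.  Surplus or missing columns are reported, never silently
    dropped.
    """

    columns: dict[str, int] = field(default_factory=dict)
    residue_indices: dict[str, dict[str, int]] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    ROLES = ("hydro1", "hydro2", "hydro3", "hydro4", "polar1", "polar2")

    @property
    def complete(self) -> bool:
        return all(role in self.columns for role in self.ROLES)


def _column_fractions(column_letters: str) -> tuple[int, dict[str, float]]:
    nongap = [c for c in column_letters if c != GAP]
    counts: dict[str, int] = {}
    for letter in nongap:
        counts[letter] = counts.get(letter, 0) + 1
    n = len(nongap)
    fractions = {letter: c / n for letter, c in counts.items()} if n else {}
    return n, fractions


def conservation_index(fractions: dict[str, float]) -> int:
    """Entropy-based 0-9 conservation score.

    ``round(9 * (1 - H / ln 20))`` with H the Shannon entropy (natural log)
    of the standard-letter frequencies, clamped to 0..9.  A pure column
    scores 9, a uniform column 0, an all-gap column 0.
    """
    std = {k: v for k, v in fractions.items() if k in STANDARD_AA}
    total = sum(std.values())
    if total <= 0:
        return 0
    entropy = -sum((v / total) * math.log(v / total) for v in std.values() if v > 0)
    index = round(9.0 * (1.0 - entropy / _LN20))
    return max(0, min(9, index))


def column_profile(
    alignment: Alignment,
    column: int,
    level_threshold: float = 0.8,
) -> ColumnProfile:
    """Profile one alignment column (1-based).

    Consensus is a single letter if one standard letter's fraction of non-gap
    entries reaches the threshold; otherwise the most specific residue class
    whose aggregate fraction does; otherwise none.  Gaps are excluded from
    the denominator; non-standard letters (X) count as non-gap support but
    join no class.  Columns with more than half gaps are flagged low-support.
    """
    letters = alignment.column(column)
    n_nongap, fractions = _column_fractions(letters)
    class_fractions = {
        symbol: sum(fractions.get(letter, 0.0) for letter in members)
        for _, symbol, members in RESIDUE_CLASSES
    }
    symbol: str | None = None
    level = 0.0
    if n_nongap:
        best_letter = max(
            (letter for letter in fractions if letter in STANDARD_AA),
            key=lambda letter: (fractions[letter], letter),
            default=None,
        )
        if best_letter is not None and fractions[best_letter] >= level_threshold:
            symbol, level = best_letter, fractions[best_letter]
        else:
            for cls in CLASS_PRIORITY:
                if class_fractions[cls] >= level_threshold:
                    symbol, level = cls, class_fractions[cls]
                    break
    return ColumnProfile(
        column=column,
        n_nongap=n_nongap,
        fractions=fractions,
        class_fractions=class_fractions,
        consensus_symbol=symbol,
        consensus_level=level,
        conservation_index=conservation_index(fractions),
        low_support=n_nongap < alignment.nrow / 2,
    )


def profile_alignment(
    alignment: Alignment, level_threshold: float = 0.8
) -> list[ColumnProfile]:
    return [
        column_profile(alignment, col, level_threshold)
        for col in range(1, alignment.ncol + 1)
    ]


def call_conserved_columns(
    alignment: Alignment,
    scr_segments=None,
    level_threshold: float = 0.8,
    index_threshold: int = 4,
    ligand_columns: set[int] | frozenset[int] = frozenset(),
) -> tuple[list[ColumnProfile], list[ColumnProfile]]:
    """Columns with a consensus call and conservation index above threshold.

    Returns ``(additional, ligands)``: the conserved zinc-ligand columns are
    reported separately and excluded from the additional-residue list, since
    the six equivalent residues are defined besides the conserved Cys/His.
    When SCR segments are given, calls are restricted to their columns.
    """
    allowed: set[int] | None = None
    if scr_segments is not None:
        allowed = set()
        for seg in scr_segments:
            allowed.update(range(seg.start_col, seg.end_col + 1))
    additional: list[ColumnProfile] = []
    ligands: list[ColumnProfile] = []
    for col in range(1, alignment.ncol + 1):
        if allowed is not None and col not in allowed and col not in ligand_columns:
            continue
        prof = column_profile(alignment, col, level_threshold)
        if prof.consensus_symbol is None or prof.conservation_index <= index_threshold:
            continue
        if col in ligand_columns:
            ligands.append(prof)
        else:
            additional.append(prof)
    return additional, ligands


def _is_hydrophobic_call(prof: ColumnProfile) -> bool:
    if prof.consensus_symbol is None:
        return False
    if prof.consensus_symbol in CLASS_BY_SYMBOL:
        return prof.consensus_symbol in HYDROPHOBIC_SYMBOLS
    # identity consensus: any hydrophobic-class letter, plus Pro, which the
    # C-loop hydrophobic role is dominated by in real RING sets
    return prof.consensus_symbol in CLASS_BY_SYMBOL["h"] or prof.consensus_symbol == "P"


def _is_polar_call(prof: ColumnProfile) -> bool:
    if prof.consensus_symbol is None:
        return False
    if prof.consensus_symbol in CLASS_BY_SYMBOL:
        return prof.consensus_symbol in POLAR_SYMBOLS
    return prof.consensus_symbol in CLASS_BY_SYMBOL["p"]


def assign_equivalent_residues(
    conserved: list[ColumnProfile],
    scr_segments,
    alignment: Alignment | None = None,
) -> EquivalentResidueSet:
    """Map conserved columns to the six equivalent-residue roles by region.

    ``scr_segments`` must carry region labels (N-loop, beta, beta-alpha,
    C-loop).  Hydrophobic-consensus columns map to hydro1 (N-loop), hydro2
    and hydro3 (beta-alpha, in order), hydro4 (C-loop); polar-consensus
    columns to polar1 (beta-alpha helix) and polar2 (C-loop).  Surplus or
    missing columns become diagnostics.
    """
    result = EquivalentResidueSet()
    region_of: dict[int, str] = {}
    for seg in scr_segments:
        label = getattr(seg, "region_label", None)
        if label:
            for col in range(seg.start_col, seg.end_col + 1):
                region_of[col] = label

    by_region: dict[tuple[str, str], list[int]] = {}
    for prof in sorted(conserved, key=lambda p: p.column):
        region = region_of.get(prof.column)
        if region is None:
            result.diagnostics.append(
                f"column {prof.column}: conserved but outside labelled SCRs"
            )
            continue
        if _is_hydrophobic_call(prof):
            kind = "hydro"
        elif _is_polar_call(prof):
            kind = "polar"
        else:
            result.diagnostics.append(
                f"column {prof.column}: consensus {prof.consensus_symbol!r} is "
                f"neither hydrophobic nor polar"
            )
            continue
        by_region.setdefault((region, kind), []).append(prof.column)

    plan = (
        ("hydro1", "N-loop", "hydro", 0),
        ("hydro2", "beta-alpha", "hydro", 0),
        ("hydro3", "beta-alpha", "hydro", 1),
        ("hydro4", "C-loop", "hydro", 0),
        ("polar1", "beta-alpha", "polar", 0),
        ("polar2", "C-loop", "polar", 0),
    )
    used: dict[tuple[str, str], int] = {}
    for role, region, kind, nth in plan:
        cols = by_region.get((region, kind), [])
        if nth < len(cols):
            result.columns[role] = cols[nth]
            used[(region, kind)] = max(used.get((region, kind), 0), nth + 1)
        else:
            result.diagnostics.append(
                f"{role}: no {kind} consensus column available in {region}"
            )
    for key, cols in by_region.items():
        surplus = cols[used.get(key, 0):]
        if surplus:
            result.diagnostics.append(
                f"surplus {key[1]} columns in {key[0]}: {surplus}"
            )
    if alignment is not None:
        for role, col in result.columns.items():
            result.residue_indices[role] = {
                rid: alignment.col_to_res(rid)[col]
                for rid in alignment.row_ids
                if col in alignment.col_to_res(rid)
            }
    return result
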