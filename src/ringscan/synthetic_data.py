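"""Seeded generators for every input the survey stages consume.

Each generator emits standard-format data (sequences, aligned FASTA, PDB
coordinate sets, BLAST-style hit tables) together with a planted ground
truth, so every stage of the pipeline can be closed-loop tested without
external downloads.  All randomness flows through one ``numpy`` Generator
seeded per spec; identical specs produce identical output.

Synthetic structures are C-alpha traces (3.8 A steps, self-avoiding) with a
single dummy side-chain atom per residue, enough for heavy-atom distance
math; they are not physically realistic decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ringscan.conservation import CLASS_BY_SYMBOL
from ringscan.io_model import (
    STANDARD_AA,
    Alignment,
    Atom,
    Chain,
    HitRecord,
    Residue,
    SequenceRecord,
    Structure,
)
from ringscan.ring_classifier import DEFAULT_GAP_RANGES

#: filler letters that can never occupy a metal ligand position, so planted
#: patterns are the only admissible scan candidates
FILLER_LETTERS = "AEFIKLMNPQRVWY"

STANDARD_LETTERS = sorted(STANDARD_AA)

#: canonical ligand letters per type
TYPE_PATTERNS = {
    "C3HC4": "CCCHCCCC",
    "C3H2C3": "CCCHHCCC",
    "C3HC3D": "CCCHCCCD",
    "C4HC3": "CCCCHCCC",
    "C3HGC3": "CCCHGCCC",
    "C4C4": "CCCCCCCC",
    "RING-D": "CCCHDCCC",
    "RING-S/T": "CSCHCTCC",
}


# ---------------------------------------------------------------------------
# RING sequences with planted ligand patterns


@dataclass(frozen=True)
class RingSequenceSpec:
    seed: int
    counts: tuple[tuple[str, int], ...] = (("C3HC4", 10),)
    flank_range: tuple[int, int] = (5, 25)
    gap_ranges: tuple[tuple[int, int], ...] = DEFAULT_GAP_RANGES


@dataclass(frozen=True)
class PlantedPattern:
    seq_id: str
    type_label: str
    positions: tuple[int, ...]
    letters: tuple[str, ...]


def _random_filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FILLER_LETTERS), size=n)) if n else ""


def gen_ring_sequences(
    spec: RingSequenceSpec,
) -> tuple[list[SequenceRecord], list[PlantedPattern]]:
    """Sequences with one planted ligand pattern each, at random admissible
    spacings inside neutral flanks."""
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth: list[PlantedPattern] = []
    idx = 0
    for type_label, count in spec.counts:
        if type_label not in TYPE_PATTERNS:
            raise ValueError(f"no canonical pattern for type {type_label!r}")
        letters = TYPE_PATTERNS[type_label]
        for _ in range(count):
            idx += 1
            gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in spec.gap_ranges]
            left = int(rng.integers(*spec.flank_range))
            right = int(rng.integers(*spec.flank_range))
            seq = _random_filler(rng, left)
            positions = []
            for k, letter in enumerate(letters):
                positions.append(len(seq) + 1)
                seq += letter
                if k < len(gaps):
                    seq += _random_filler(rng, gaps[k])
            seq += _random_filler(rng, right)
            # pad to satisfy the scanner's minimum-length precondition
            if len(seq) < 40:
                seq += _random_filler(rng, 40 - len(seq))
            seq_id = f"synth_{type_label.replace('/', '')}_{idx:04d}"
            records.append(SequenceRecord(seq_id, seq))
            truth.append(
                PlantedPattern(seq_id, type_label, tuple(positions), tuple(letters))
            )
    return records, truth


def check_ring_truth(records: list[SequenceRecord], truth: list[PlantedPattern]) -> None:
    """Direct check that every planted pattern is present as stated."""
    by_id = {r.id: r for r in records}
    for t in truth:
        seq = by_id[t.seq_id].residues
        for pos, letter in zip(t.positions, t.letters):
            if seq[pos - 1] != letter:
                raise AssertionError(
                    f"{t.seq_id}: letter at {pos} is {seq[pos - 1]}, planted {letter}"
                )


# ---------------------------------------------------------------------------
# superposed structure ensembles with region-specific coordinate noise


@dataclass(frozen=True)
class EnsembleSpec:
    seed: int
    region_plan: tuple[tuple[int, float], ...] = (
        (9, 0.3), (6, 4.0), (7, 0.3), (5, 4.0), (13, 0.3), (5, 4.0), (6, 0.3),
    )
    n_structures: int = 10
    step: float = 3.8
    min_separation: float = 3.0


@dataclass
class EnsembleTruth:
    #: (start_col, end_col, sigma) per region, 1-based inclusive
    regions: list[tuple[int, int, float]]
    template: np.ndarray  # (ncol, 3) C-alpha template


def _self_avoiding_walk(
    rng: np.random.Generator, n: int, step: float, min_sep: float
) -> np.ndarray:
    """C-alpha trace: fixed-length steps, rejecting clashes with earlier
    points (non-adjacent closer than ``min_sep``)."""
    if step <= 0 or min_sep >= 2 * step:
        raise ValueError("non-physical step/separation request")
    pts = [np.zeros(3)]
    attempts_per_step = 200
    for _ in range(n - 1):
        prev_dir = None
        for attempt in range(attempts_per_step):
            v = rng.normal(size=3)
            # bias gently forward to avoid dense clumps
            if len(pts) >= 2:
                forward = pts[-1] - pts[-2]
                v = v + 0.8 * forward / np.linalg.norm(forward)
            v = step * v / np.linalg.norm(v)
            cand = pts[-1] + v
            earlier = np.array(pts[:-1]) if len(pts) > 1 else None
            if earlier is None or len(earlier) == 0:
                break
            d = np.linalg.norm(earlier - cand, axis=1)
            if (d >= min_sep).all():
                break
        else:
            raise RuntimeError("self-avoiding walk failed; relax separation")
        pts.append(cand)
    return np.array(pts)


def _make_structure(
    struct_id: str, coords_ca: np.ndarray, coords_cb: np.ndarray, sequence: str
) -> Structure:
    residues = []
    for k, (ca, cb) in enumerate(zip(coords_ca, coords_cb), start=1):
        residues.append(
            Residue(
                chain_id="A",
                seq_num=k,
                name3=_aa1_to_3(sequence[k - 1]),
                atoms=[
                    Atom("CA", "C", tuple(np.round(ca, 3))),
                    Atom("CB", "C", tuple(np.round(cb, 3))),
                ],
            )
        )
    return Structure(id=struct_id, chains=[Chain(id="A", residues=residues)])


def _aa1_to_3(letter: str) -> str:
    from ringscan.io_model import AA1_TO_3

    return AA1_TO_3.get(letter, "UNK")


def gen_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[Structure], Alignment, EnsembleTruth]:
    """A template backbone plus n members with per-region Gaussian noise.

    The alignment is the trivial columnar one (identical ungapped rows);
    truth carries the region boundaries and noise levels.
    """
    rng = np.random.default_rng(spec.seed)
    ncol = sum(length for length, _ in spec.region_plan)
    template = _self_avoiding_walk(rng, ncol, spec.step, spec.min_separation)
    # one dummy side-chain atom per residue, 1.5 A off the C-alpha
    cb_offsets = rng.normal(size=(ncol, 3))
    cb_offsets = 1.5 * cb_offsets / np.linalg.norm(cb_offsets, axis=1)[:, None]
    template_cb = template + cb_offsets
    sigma_per_col = np.concatenate(
        [np.full(length, sigma) for length, sigma in spec.region_plan]
    )
    sequence = "".join(rng.choice(STANDARD_LETTERS, size=ncol))
    structures = []
    for k in range(spec.n_structures):
        noise_ca = rng.normal(size=(ncol, 3)) * sigma_per_col[:, None]
        noise_cb = rng.normal(size=(ncol, 3)) * sigma_per_col[:, None]
        structures.append(
            _make_structure(
                f"member_{k:03d}", template + noise_ca, template_cb + noise_cb, sequence
            )
        )
    alignment = Alignment(
        row_ids=[s.id for s in structures], rows=[sequence] * spec.n_structures
    )
    regions = []
    start = 1
    for length, sigma in spec.region_plan:
        regions.append((start, start + length - 1, sigma))
        start += length
    return structures, alignment, EnsembleTruth(regions=regions, template=template)


# ---------------------------------------------------------------------------
# two-chain complexes with planted cross-chain atom pairs


@dataclass(frozen=True)
class ComplexSpec:
    seed: int
    #: per planted pair: (distance A, e3 atom name, e2 atom name)
    pair_plan: tuple[tuple[float, str, str], ...] = (
        (3.0, "CA", "CA"), (3.4, "CA", "CA"), (3.8, "CA", "CA"), (4.5, "CA", "CA"),
    )
    spacing: float = 30.0
    background_offset: float = 40.0


@dataclass(frozen=True)
class PlantedContact:
    e3_seq_num: int
    e2_seq_num: int
    distance: float

    @property
    def tier(self) -> str | None:
        if self.distance <= 3.5:
            return "close"
        if self.distance <= 4.0:
            return "contact"
        return None


def gen_complex(spec: ComplexSpec) -> tuple[Structure, list[PlantedContact]]:
    """Two chains with each planned atom pair at exactly its distance.

    Pair sites are spread far apart along x so non-planned atoms stay well
    beyond 8 A of the other chain.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.spacing < 2 * max((d for d, _, _ in spec.pair_plan), default=0) + 8:
        raise ValueError("pair sites too dense for the planned distances")
    res_a: list[Residue] = []
    res_b: list[Residue] = []
    truth: list[PlantedContact] = []
    names = list(STANDARD_LETTERS)
    for k, (dist, atom_a, atom_b) in enumerate(spec.pair_plan, start=1):
        x = spec.spacing * k
        a_pos = np.array([x, 0.0, 0.0])
        # axis-aligned separation keeps the planted distance exact after the
        # writer's 3-decimal rounding, so tier boundaries (3.5/4.0) are sharp
        b_pos = a_pos + np.array([0.0, round(dist, 3), 0.0])
        res_a.append(
            Residue("E", k, _aa1_to_3(str(rng.choice(names))),
                    [Atom(atom_a, atom_a[0], tuple(np.round(a_pos, 3)))])
        )
        res_b.append(
            Residue("F", k, _aa1_to_3(str(rng.choice(names))),
                    [Atom(atom_b, atom_b[0], tuple(np.round(b_pos, 3)))])
        )
        truth.append(PlantedContact(k, k, float(np.linalg.norm(b_pos - a_pos))))
    # distant background residues on each chain
    n_pairs = len(spec.pair_plan)
    for k in range(n_pairs + 1, n_pairs + 4):
        x = spec.spacing * k
        res_a.append(Residue("E", k, "GLY",
                             [Atom("CA", "C", (x, 0.0, 0.0))]))
        res_b.append(Residue("F", k, "GLY",
                             [Atom("CA", "C", (x, spec.background_offset, 0.0))]))
    structure = Structure(
        id="synthetic_complex",
        chains=[Chain(id="E", residues=res_a), Chain(id="F", residues=res_b)],
    )
    return structure, truth


def check_complex_truth(structure: Structure, truth: list[PlantedContact]) -> None:
    from ringscan.core_surface import min_heavy_distance

    chain_e = {r.seq_num: r for r in structure.chain("E").residues}
    chain_f = {r.seq_num: r for r in structure.chain("F").residues}
    for t in truth:
        d = min_heavy_distance(chain_e[t.e3_seq_num], chain_f[t.e2_seq_num])
        if abs(d - t.distance) > 2e-3:  # coordinates rounded to 3 decimals
            raise AssertionError(
                f"pair {t.e3_seq_num}-{t.e2_seq_num}: distance {d:.4f} != "
                f"planted {t.distance:.4f}"
            )


# ---------------------------------------------------------------------------
# alignments with planted class-conserved columns


@dataclass(frozen=True)
class MsaSpec:
    seed: int
    n_rows: int = 30
    n_cols: int = 46
    #: (column, class symbol or letter, target level)
    planted: tuple[tuple[int, str, float], ...] = ()
    level_tolerance: float = 0.05


@dataclass(frozen=True)
class PlantedColumn:
    column: int
    symbol: str
    level: float  # achieved level


def gen_msa(spec: MsaSpec) -> tuple[Alignment, list[PlantedColumn]]:
    """Rows sampled so each planted column hits its target class level.

    A planted column emulates the conserved equivalent-residue columns of
    real RING alignments, which are dominated by a single residue (Ile, Phe,
    Pro, Arg...): one class member takes 85% of the class picks, the rest go
    to at most two other members, and off-class entries draw from three
    fixed outside letters -- so the column is conserved (low entropy) as
    well as class-consensual.  Unplanted columns are uniform over the 20
    letters.
    """
    rng = np.random.default_rng(spec.seed)
    planted_map = {col: (symbol, level) for col, symbol, level in spec.planted}
    for col in planted_map:
        if not 1 <= col <= spec.n_cols:
            raise ValueError(f"planted column {col} outside 1..{spec.n_cols}")
    columns: list[list[str]] = []
    truth: list[PlantedColumn] = []
    for col in range(1, spec.n_cols + 1):
        if col not in planted_map:
            columns.append(list(rng.choice(STANDARD_LETTERS, size=spec.n_rows)))
            continue
        symbol, level = planted_map[col]
        members = sorted(CLASS_BY_SYMBOL.get(symbol, frozenset(symbol)))
        complement = sorted(set(STANDARD_LETTERS) - set(members))
        n_major = int(round(level * spec.n_rows))
        achieved = n_major / spec.n_rows
        if abs(achieved - level) > spec.level_tolerance or not complement and n_major < spec.n_rows:
            raise ValueError(
                f"column {col}: target level {level} unattainable with "
                f"{spec.n_rows} rows"
            )
        dominant = members[int(rng.integers(len(members)))]
        secondary = [m for m in members if m != dominant][:2]
        outside = list(rng.choice(complement, size=min(3, len(complement)),
                                  replace=False))
        entries = []
        for _ in range(n_major):
            if not secondary or rng.random() < 0.85:
                entries.append(dominant)
            else:
                entries.append(str(rng.choice(secondary)))
        entries.extend(str(rng.choice(outside)) for _ in range(spec.n_rows - n_major))
        order = rng.permutation(spec.n_rows)
        columns.append([entries[i] for i in order])
        truth.append(PlantedColumn(column=col, symbol=symbol, level=achieved))
    rows = ["".join(columns[c][r] for c in range(spec.n_cols))
            for r in range(spec.n_rows)]
    ids = [f"row_{r:03d}" for r in range(spec.n_rows)]
    return Alignment(row_ids=ids, rows=rows), truth


def check_msa_truth(alignment: Alignment, truth: list[PlantedColumn]) -> None:
    for t in truth:
        letters = alignment.column(t.column)
        members = CLASS_BY_SYMBOL.get(t.symbol, frozenset(t.symbol))
        frac = sum(1 for c in letters if c in members) / len(letters)
        if abs(frac - t.level) > 1e-9:
            raise AssertionError(
                f"column {t.column}: class fraction {frac} != planted {t.level}"
            )


# ---------------------------------------------------------------------------
# reciprocal hit tables with planted best hits


@dataclass(frozen=True)
class HitsSpec:
    seed: int
    size_a: int = 300
    size_b: int = 300
    n_orthologs: int = 200
    noise_rate: float = 0.10
    n_tie_cases: int = 0


def gen_hits(spec: HitsSpec) -> tuple[list[HitRecord], list[HitRecord], list[tuple[str, str]]]:
    """Two directional hit tables with planted mutual best hits.

    Planted pairs score in [150, 300) bits; decoys strictly lower in
    [20, 140).  Tie cases add a decoy matching a planted pair's bit score
    exactly but with a larger e-value, exercising the tie-break rule.
    """
    if spec.n_orthologs > min(spec.size_a, spec.size_b):
        raise ValueError("more planted orthologs than proteome size")
    rng = np.random.default_rng(spec.seed)
    ids_a = [f"A{i:04d}" for i in range(spec.size_a)]
    ids_b = [f"B{i:04d}" for i in range(spec.size_b)]
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    truth: list[tuple[str, str]] = []
    planted_scores: dict[tuple[str, str], float] = {}
    for i in range(spec.n_orthologs):
        a, b = ids_a[i], ids_b[i]
        s_ab = float(np.round(rng.uniform(150, 300), 1))
        s_ba = float(np.round(rng.uniform(150, 300), 1))
        e_ab = 10.0 ** float(rng.uniform(-80, -40))
        e_ba = 10.0 ** float(rng.uniform(-80, -40))
        ident = float(np.round(rng.uniform(30, 95), 2))
        hits_ab.append(HitRecord(a, b, ident, s_ab, e_ab))
        hits_ba.append(HitRecord(b, a, ident, s_ba, e_ba))
        truth.append((a, b))
        planted_scores[(a, b)] = s_ab
    n_noise = int(round(spec.noise_rate * (len(hits_ab) + len(hits_ba))))
    for _ in range(n_noise):
        q = ids_a[int(rng.integers(spec.size_a))]
        s = ids_b[int(rng.integers(spec.size_b))]
        score = float(np.round(rng.uniform(20, 140), 1))
        hits_ab.append(HitRecord(q, s, float(np.round(rng.uniform(10, 40), 2)),
                                 score, 10.0 ** float(rng.uniform(-20, -2))))
        q = ids_b[int(rng.integers(spec.size_b))]
        s = ids_a[int(rng.integers(spec.size_a))]
        score = float(np.round(rng.uniform(20, 140), 1))
        hits_ba.append(HitRecord(q, s, float(np.round(rng.uniform(10, 40), 2)),
                                 score, 10.0 ** float(rng.uniform(-20, -2))))
    for i in range(min(spec.n_tie_cases, spec.n_orthologs)):
        a, b = truth[i]
        decoy_subject = ids_b[(i + 1) % spec.size_b]
        # same bit score as the planted best, worse e-value: the planted pair
        # must still win through the e-value tie-break
        hits_ab.append(
            HitRecord(a, decoy_subject, 25.0, planted_scores[(a, b)], 1e-10)
        )
    return hits_ab, hits_ba, truth


def check_hits_truth(
    hits_ab: list[HitRecord], hits_ba: list[HitRecord], truth: list[tuple[str, str]]
) -> None:
    ab_pairs = {(h.query_id, h.subject_id) for h in hits_ab}
    ba_pairs = {(h.query_id, h.subject_id) for h in hits_ba}
    for a, b in truth:
        if (a, b) not in ab_pairs or (b, a) not in ba_pairs:
            raise AssertionError(f"planted pair {a}-{b} missing from hit tables")
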