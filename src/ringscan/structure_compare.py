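"""Superposition, per-column C-alpha RMSD and SCR detection.

Structures are rigidly superposed by the Kabsch least-squares fit (SVD, with
the reflection excluded).  For an ensemble aligned by a gapped multiple
alignment, every gap-free column yields the RMSD of the equivalent C-alpha
atoms from their centroid; structurally conserved regions (SCRs) are maximal
gap-free runs found with a windowed seed-and-extend scan: a seed is w (=3)
consecutive gap-free columns whose mean centroid RMSD is at or below the
threshold (3.0 A by default; 2.0 A is the stricter preset the survey's
region tables use), extended rightward while the growing segment's mean
stays within the threshold.  Segments shorter than 3 columns are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ringscan.io_model import Alignment, Residue, Structure


@dataclass(frozen=True)
class Superposition:
    """A proper rigid motion (rotation then translation) and its fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant must be +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


@dataclass
class ColumnRmsdProfile:
    """Per-column centroid RMSD over an ensemble; gap columns are undefined."""

    rmsd: np.ndarray            # NaN where undefined
    has_gap: np.ndarray         # boolean per column
    n_structures: int
    notes: list[str]

    @property
    def ncol(self) -> int:
        return len(self.rmsd)

    def value(self, col: int) -> float:
        return float(self.rmsd[col - 1])


@dataclass(frozen=True)
class SCRParams:
    window: int = 3
    threshold: float = 3.0
    min_len: int = 3

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class SCRSegment:
    """A gap-free run of columns with mean centroid RMSD within threshold."""

    start_col: int
    end_col: int
    mean_rmsd: float
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.end_col < self.start_col:
            raise ValueError("end before start")

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1

    def columns(self) -> range:
        return range(self.start_col, self.end_col + 1)


def kabsch_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``coords_mov`` onto ``coords_ref``.

    Returns the proper rotation (det +1; reflections excluded) and
    translation minimizing the RMSD over the paired points, plus that RMSD.
    Requires at least 3 non-collinear pairs.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired Nx3 coordinate arrays required")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 paired points, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear (or coincident) points leave the rotation under-determined
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) input points")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    fitted = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - P) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _calpha(residue: Residue):
    return residue.atom("CA")


def _calpha_by_column(structure: Structure, alignment: Alignment, row_id: str
                      ) -> dict[int, np.ndarray]:
    """Alignment column -> C-alpha coordinate for one structure/row."""
    residues = structure.residues
    col_map = alignment.col_to_res(row_id)
    out: dict[int, np.ndarray] = {}
    for col, res_idx in col_map.items():
        if res_idx <= len(residues):
            ca = _calpha(residues[res_idx - 1])
            if ca is not None:
                out[col] = ca.xyz
    return out


def pairwise_calpha_rmsd(
    struct_a: Structure, struct_b: Structure, alignment: Alignment
) -> float:
    """Post-fit C-alpha RMSD over the mutually ungapped alignment columns."""
    ca_a = _calpha_by_column(struct_a, alignment, struct_a.id)
    ca_b = _calpha_by_column(struct_b, alignment, struct_b.id)
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} mutually ungapped C-alpha pairs between "
            f"{struct_a.id} and {struct_b.id}"
        )
    A = np.array([ca_a[c] for c in shared])
    B = np.array([ca_b[c] for c in shared])
    return kabsch_superpose(A, B).rmsd


def column_rmsd_profile(
    structures: list[Structure],
    alignment: Alignment,
    reference_id: str | None = None,
    superpose: bool = True,
) -> ColumnRmsdProfile:
    """Per-column RMSD from the centroid of the equivalent C-alpha atoms.

    Every structure is first superposed onto the reference (default: the
    first structure) over their mutually ungapped C-alpha pairs; pass
    ``superpose=False`` for ensembles deposited in a common frame.  For each
    column that is gap-free in all rows and has a C-alpha in every structure,
    the RMSD from the centroid, sqrt(mean squared distance), is reported;
    other columns are undefined (NaN).  A column missing a C-alpha in any
    structure is treated as a gap and logged.
    """
    if not structures:
        raise ValueError("no structures")
    reference_id = reference_id or structures[0].id
    ref = next(s for s in structures if s.id == reference_id)
    notes: list[str] = []
    ncol = alignment.ncol
    ca_ref = _calpha_by_column(ref, alignment, ref.id)
    per_structure: list[dict[int, np.ndarray]] = []
    for st in structures:
        ca = _calpha_by_column(st, alignment, st.id)
        if superpose and st.id != ref.id and len(structures) > 1:
            shared = sorted(set(ca) & set(ca_ref))
            if len(shared) >= 3:
                sup = kabsch_superpose(
                    np.array([ca_ref[c] for c in shared]),
                    np.array([ca[c] for c in shared]),
                )
                ca = {c: sup.apply(x[None, :])[0] for c, x in ca.items()}
            else:
                notes.append(f"{st.id}: <3 shared columns with reference; left unfitted")
        per_structure.append(ca)

    rmsd = np.full(ncol, np.nan)
    has_gap = np.zeros(ncol, dtype=bool)
    for col in range(1, ncol + 1):
        coords = []
        missing = False
        for st, ca in zip(structures, per_structure):
            if col in ca:
                coords.append(ca[col])
            else:
                missing = True
                if col in alignment.col_to_res(st.id):
                    notes.append(f"column {col}: missing C-alpha in {st.id}")
                break
        if missing:
            has_gap[col - 1] = True
            continue
        arr = np.array(coords)
        centroid = arr.mean(axis=0)
        rmsd[col - 1] = float(np.sqrt(np.mean(np.sum((arr - centroid) ** 2, axis=1))))
    return ColumnRmsdProfile(
        rmsd=rmsd, has_gap=has_gap, n_structures=len(structures), notes=notes
    )


def detect_scrs(profile: ColumnRmsdProfile, params: SCRParams | None = None
                ) -> list[SCRSegment]:
    """Windowed seed-and-extend scan for structurally conserved regions.

    Scanning left to right, a seed is ``window`` consecutive gap-free columns
    with mean RMSD <= threshold (boundary inclusive).  The segment is then
    extended rightward one column at a time while the extension stays
    gap-free, the trailing ``window``-column mean stays <= threshold and the
    whole segment's mean stays <= threshold; the trailing-window condition
    stops extension at the edge of a high-deviation run instead of letting
    accumulated low-RMSD columns dilute it away.  Scanning resumes after each
    emitted segment; a final merge pass joins adjacent or overlapping
    segments whose union still qualifies; segments shorter than ``min_len``
    are discarded.
    """
    params = params or SCRParams()
    values = profile.rmsd
    usable = ~profile.has_gap & ~np.isnan(values)
    n = profile.ncol
    w = params.window
    segments: list[SCRSegment] = []
    i = 0  # 0-based start of candidate seed
    while i + w <= n:
        window = slice(i, i + w)
        if not usable[window].all() or values[window].mean() > params.threshold:
            i += 1
            continue
        j = i + w  # exclusive end
        while (
            j < n
            and usable[j]
            and values[j - w + 1:j + 1].mean() <= params.threshold
            and values[i:j + 1].mean() <= params.threshold
        ):
            j += 1
        segments.append(
            SCRSegment(start_col=i + 1, end_col=j, mean_rmsd=float(values[i:j].mean()))
        )
        i = j
    # merge pass: join adjacent/overlapping segments when the union qualifies
    merged: list[SCRSegment] = []
    for seg in segments:
        if merged and seg.start_col <= merged[-1].end_col + 1:
            lo, hi = merged[-1].start_col, max(merged[-1].end_col, seg.end_col)
            span = slice(lo - 1, hi)
            if usable[span].all() and values[span].mean() <= params.threshold:
                merged[-1] = SCRSegment(
                    start_col=lo, end_col=hi, mean_rmsd=float(values[span].mean())
                )
                continue
        merged.append(seg)
    return [s for s in merged if s.length >= params.min_len]


def summarize_scr(segment: SCRSegment, profile: ColumnRmsdProfile) -> float:
    """Arithmetic mean centroid RMSD over the segment's columns."""
    vals = profile.rmsd[segment.start_col - 1:segment.end_col]
    return float(np.mean(vals))


def label_segments_by_plan(
    segments: list[SCRSegment], labels: list[str]
) -> list[SCRSegment]:
    """Attach region labels (e.g. N-loop, beta, beta-alpha, C-loop) in order."""
    for seg, label in zip(segments, labels):
        seg.region_label = label
    return segments
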