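"""Hydrophobic patch and solvent-inaccessible core analysis.

Solvent-accessible surface area (SASA) is computed by Shrake-Rupley
sphere-point quadrature: each heavy atom's van der Waals sphere is inflated
by the probe radius (1.4 A, a water molecule) and sampled with a deterministic
golden-spiral point set; points not buried inside any neighbour's inflated
sphere contribute area.  Burial is judged on relative SASA (absolute divided
by the residue's theoretical maximum in an extended Gly-X-Gly context).

The hydrophobic patch machinery finds hydrophobic-class residues within a
heavy-atom distance cutoff (4.0 A) of a query residue, and validates that
the four conserved hydrophobic "equivalent residues" cluster around the
central (second) one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ringscan.conservation import CLASS_BY_SYMBOL
from ringscan.io_model import Residue, Structure

HYDROPHOBIC_SET = CLASS_BY_SYMBOL["h"]

#: van der Waals radii (A) by element; unlisted elements default to carbon
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90, "ZN": 1.39, "F": 1.47,
}
DEFAULT_RADIUS = 1.70

#: theoretical maximum SASA (A^2) per residue, extended tripeptide reference
#: (Tien et al. 2013, theoretical column)
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass(frozen=True)
class CoreParams:
    neighbor_cutoff: float = 4.0
    burial_rel_sasa: float = 0.10
    probe_radius: float = 1.4
    sphere_points: int = 960

    def __post_init__(self) -> None:
        for name in ("neighbor_cutoff", "burial_rel_sasa", "probe_radius", "sphere_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SasaResult:
    """Per-residue absolute (A^2) and relative solvent accessibility."""

    absolute: dict[str, float]
    relative: dict[str, float]
    flagged: list[str] = field(default_factory=list)


@dataclass
class HydrophobicPatch:
    central_residue: str
    members: list[str]
    min_pairwise_distances: np.ndarray


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley SASA per atom for inflated radii ``radii + probe``."""
    coords = np.asarray(coords, dtype=float)
    inflated = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    unit = _sphere_points(sphere_points)
    tree = cKDTree(coords)
    max_r = inflated.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], inflated[i] + max_r)
                     if j != i]
        accessible = np.ones(sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        areas[i] = (
            4.0 * np.pi * inflated[i] ** 2 * accessible.sum() / sphere_points
        )
    return areas


def sasa(structure: Structure, params: CoreParams | None = None) -> SasaResult:
    """Per-residue SASA over all heavy atoms of the structure."""
    params = params or CoreParams()
    atoms = []
    owners = []
    for res in structure.residues:
        heavy = [a for a in res.atoms if a.is_heavy]
        if not heavy:
            raise ValueError(f"residue {res.label} has no heavy atoms")
        for a in heavy:
            atoms.append(a)
            owners.append(res)
    coords = np.array([a.coord for a in atoms])
    radii = np.array([_atom_radius(a.element) for a in atoms])
    per_atom = atom_sasa(coords, radii, params.probe_radius, params.sphere_points)
    absolute: dict[str, float] = {}
    for area, res in zip(per_atom, owners):
        absolute[res.label] = absolute.get(res.label, 0.0) + float(area)
    relative: dict[str, float] = {}
    flagged: list[str] = []
    for res in structure.residues:
        ref = MAX_SASA.get(res.aa1)
        if ref is None:
            flagged.append(f"{res.label}: no max-SASA reference for {res.name3}")
            continue
        rel = absolute[res.label] / ref
        if rel > 1.2:
            flagged.append(f"{res.label}: relative SASA {rel:.2f} exceeds 1.2")
            rel = 1.2
        relative[res.label] = rel
    return SasaResult(absolute=absolute, relative=relative, flagged=flagged)


def buried_core(
    structure: Structure,
    sasa_result: SasaResult,
    burial_threshold: float = 0.10,
) -> list[Residue]:
    """Residues whose relative SASA is below the burial threshold."""
    return [
        res
        for res in structure.residues
        if res.label in sasa_result.relative
        and sasa_result.relative[res.label] < burial_threshold
    ]


def min_heavy_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum heavy-atom pair distance between two residues."""
    A = res_a.heavy_coords()
    B = res_b.heavy_coords()
    if len(A) == 0 or len(B) == 0:
        return float("inf")
    d = np.sqrt(np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=2))
    return float(d.min())


def hydrophobic_neighbors(
    structure: Structure,
    residue: Residue,
    cutoff: float = 4.0,
) -> list[tuple[Residue, float]]:
    """Hydrophobic-class residues with min heavy-atom distance <= cutoff.

    The query itself and its immediate sequence neighbours (author numbering
    offset +/-1 in the same chain) are excluded, so trivially bonded
    contacts do not count.
    """
    out = []
    for res in structure.residues:
        if res is residue:
            continue
        if (res.chain_id == residue.chain_id
                and abs(res.seq_num - residue.seq_num) <= 1):
            continue
        if res.aa1 not in HYDROPHOBIC_SET:
            continue
        d = min_heavy_distance(residue, res)
        if d <= cutoff:
            out.append((res, d))
    out.sort(key=lambda t: t[1])
    return out


def validate_patch(
    hydro_residues: dict[str, Residue],
    cutoff: float = 4.0,
) -> tuple[bool, dict[str, float]]:
    """Check that hydro1/3/4 each approach hydro2 (the central residue).

    ``hydro_residues`` maps the four roles (hydro1..hydro4) to residues of
    one structure.  True iff the min heavy-atom distance from each of
    hydro1, hydro3 and hydro4 to hydro2 is strictly below the cutoff.
    Missing residues make the result indeterminate (raises KeyError with the
    missing role).
    """
    missing = [r for r in ("hydro1", "hydro2", "hydro3", "hydro4")
               if r not in hydro_residues]
    if missing:
        raise KeyError(f"unresolvable patch roles: {missing}")
    center = hydro_residues["hydro2"]
    distances = {
        role: min_heavy_distance(hydro_residues[role], center)
        for role in ("hydro1", "hydro3", "hydro4")
    }
    return all(d < cutoff for d in distances.values()), distances


def hydrophobic_patch(
    structure: Structure,
    central: Residue,
    cutoff: float = 4.0,
) -> HydrophobicPatch:
    """The hydrophobic patch around a central residue: the central residue
    plus every hydrophobic residue within the cutoff of it."""
    neighbors = hydrophobic_neighbors(structure, central, cutoff)
    members = [central] + [r for r, _ in neighbors]
    n = len(members)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = min_heavy_distance(members[i], members[j])
    return HydrophobicPatch(
        central_residue=central.label,
        members=[r.label for r in members],
        min_pairwise_distances=D,
    )
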