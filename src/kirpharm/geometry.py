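"""Rigid-body superposition, RMSD series and numerical surface areas.

Distances and coordinates are in Angstrom throughout; buried interface
areas are reported in nm^2 to match the convention used for
protein-ligand contact surfaces.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsd_series",
    "sphere_points",
    "shrake_rupley",
    "interface_area",
]

# Bondi-style van der Waals radii (Angstrom). Elements missing from the
# table fall back to carbon's radius.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
}
DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto ``target``.

    Returns a proper rotation (det = +1, no reflection) and translation such
    that ``mobile @ R.T + t`` minimises the summed squared deviation from
    ``target``. Degenerate inputs (single point, collinear points) still
    return a valid minimiser; it is just not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch expects two (n, 3) arrays of equal shape")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``target``."""
    R, t = kabsch(mobile, target)
    return np.asarray(mobile, dtype=float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between two (n, 3) arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    coords: np.ndarray,
    analyze_idx: np.ndarray,
    fit_idx: np.ndarray,
    reference: int = 0,
) -> np.ndarray:
    """Per-frame RMSD of ``analyze_idx`` atoms after least-squares fitting
    each frame's ``fit_idx`` atoms onto the reference frame.

    ``coords`` has shape (n_frames, n_atoms, 3). The RMSD at the reference
    frame is exactly zero by construction.
    """
    coords = np.asarray(coords, dtype=float)
    analyze_idx = np.asarray(analyze_idx, dtype=int)
    fit_idx = np.asarray(fit_idx, dtype=int)
    if analyze_idx.size == 0:
        raise ValueError("analyze selection is empty")
    if fit_idx.size < 3:
        raise ValueError(
            f"fit selection has {fit_idx.size} atoms; >=3 required for a "
            "determined superposition"
        )
    if not 0 <= reference < coords.shape[0]:
        raise IndexError(f"reference frame {reference} out of range")
    ref_fit = coords[reference, fit_idx]
    ref_analyze = coords[reference, analyze_idx]
    out = np.empty(coords.shape[0])
    for i in range(coords.shape[0]):
        R, t = kabsch(coords[i, fit_idx], ref_fit)
        moved = coords[i, analyze_idx] @ R.T + t
        out[i] = rmsd(moved, ref_analyze)
    out[reference] = 0.0
    return out


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    if n < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Each atom is covered with ``n_points`` deterministic test points on its
    solvent-expanded sphere (vdW + probe); a point is buried when it falls
    inside another atom's expanded sphere. A point lying exactly *on* a
    neighbour's sphere is counted as buried only when the neighbour has a
    lower index, so a pair of exactly coincident identical spheres exposes
    one sphere's worth of surface in total rather than zero or two.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    n = coords.shape[0]
    R = radii + probe_radius
    unit = sphere_points(n_points)
    areas = np.empty(n)
    eps = 1e-9
    for i in range(n):
        pts = coords[i] + R[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        neighbours = np.nonzero((d_centers < R + R[i]) & (np.arange(n) != i))[0]
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            thresh = R[j] + (eps if j < i else -eps)
            accessible &= d >= thresh
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return areas


def interface_area(
    coords: np.ndarray,
    radii: np.ndarray,
    ligand_idx: np.ndarray,
    receptor_idx: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried interface area in nm^2 between two disjoint selections.

    area = 0.5 * (SASA(ligand alone) + SASA(receptor alone) - SASA(complex))
    """
    ligand_idx = np.asarray(ligand_idx, dtype=int)
    receptor_idx = np.asarray(receptor_idx, dtype=int)
    if ligand_idx.size == 0 or receptor_idx.size == 0:
        raise ValueError("ligand and receptor selections must be non-empty")
    if np.intersect1d(ligand_idx, receptor_idx).size:
        raise ValueError("ligand and receptor selections overlap")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lig = shrake_rupley(coords[ligand_idx], radii[ligand_idx], probe_radius, n_points)
    rec = shrake_rupley(coords[receptor_idx], radii[receptor_idx], probe_radius, n_points)
    both = np.concatenate([ligand_idx, receptor_idx])
    cpx = shrake_rupley(coords[both], radii[both], probe_radius, n_points)
    buried_a2 = 0.5 * (lig.sum() + rec.sum() - cpx.sum())
    return buried_a2 / 100.0  # Angstrom^2 -> nm^2
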