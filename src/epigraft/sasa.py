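"""Solvent-accessible surface area by deterministic Shrake-Rupley quadrature.

Each atom is expanded by the probe radius and covered with a fixed
golden-spiral point set; the accessible fraction is the fraction of points
not inside any neighbouring expanded sphere.

The point set is not held in a global laboratory frame: every atom gets an
orientation frame built from the directions to its two nearest neighbours
(ties broken by atom index).  Because the frame is constructed from the
coordinates themselves, rigidly moving the whole model moves the quadrature
points with it, so SASA is translation- and rotation-invariant to floating
point precision, not merely to quadrature accuracy.  For atoms whose
neighbourhood is collinear (or absent) the azimuthal frame falls back to a
fixed global convention; in those configurations every occluder lies on the
polar axis, so the azimuth cannot affect the result.  A further consequence:
an atom whose local neighbourhood is unchanged between two models (e.g. a
residue far from any binding partner, isolated chain vs. complex) receives
bit-identical quadrature points and occluders in both, so its buried area is
exactly zero rather than zero-within-noise.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

__all__ = ["golden_spiral_points", "shrake_rupley", "compute_sasa", "per_residue_sasa"]

DEFAULT_PROBE = 1.4  # Å, water-sized probe
DEFAULT_N_POINTS = 960

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_COLLINEAR_TOL = 1e-8


def golden_spiral_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (n, 3), deterministic in n."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _orthonormal_to(e3: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to e3 (global fallback)."""
    basis = np.eye(3)
    k = int(np.argmin(np.abs(basis @ e3)))
    v = basis[k] - (basis[k] @ e3) * e3
    return v / np.linalg.norm(v)


def _atom_frames(coords: np.ndarray) -> np.ndarray:
    """Per-atom rotation matrices (n, 3, 3), rows are the frame axes.

    Polar axis points to the nearest neighbour, azimuth reference to the
    second-nearest non-collinear neighbour (Gram-Schmidt).  Equivariant
    under rigid motion wherever the construction is non-degenerate.
    """
    n = len(coords)
    frames = np.tile(np.eye(3), (n, 1, 1))
    if n < 2:
        return frames
    d = np.linalg.norm(coords[None, :, :] - coords[:, None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    for i in range(n):
        order = np.lexsort((np.arange(n), d[i]))
        e3 = coords[order[0]] - coords[i]
        e3 = e3 / np.linalg.norm(e3)
        e1 = None
        for j in order[1:]:
            if not np.isfinite(d[i, j]):
                break
            v = coords[j] - coords[i]
            v = v - (v @ e3) * e3
            nv = np.linalg.norm(v)
            if nv > _COLLINEAR_TOL * d[i, j]:
                e1 = v / nv
                break
        if e1 is None:
            e1 = _orthonormal_to(e3)
        e2 = np.cross(e3, e1)
        frames[i] = np.stack([e1, e2, e3])
    return frames


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Å²) for spheres at ``coords`` with the given radii."""
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)

    unit = golden_spiral_points(n_points)
    frames = _atom_frames(coords)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    sasa = np.empty(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], r=ext[i] + ext.max())
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        area = 4.0 * np.pi * ext[i] ** 2
        if not neigh:
            sasa[i] = area
            continue
        pts = unit @ frames[i] * ext[i] + coords[i]
        accessible = np.ones(n_points, bool)
        for j in neigh:
            dd = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= dd >= ext[j]
        sasa[i] = area * accessible.sum() / n_points
    return sasa


def compute_sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    chain_ids=None,
) -> tuple[np.ndarray, list[tuple]]:
    """SASA of every atom of the selected chains (default: all).

    Returns ``(per_atom_sasa, owners)`` where ``owners[i]`` is the residue
    key ``(chain_id, number, insertion_code)`` of atom ``i``.
    """
    if chain_ids is None:
        chain_ids = list(model.chains)
    coords, radii, owners = model.chain_coords(chain_ids)
    return shrake_rupley(coords, radii, probe_radius, n_points), owners


def per_residue_sasa(per_atom: np.ndarray, owners: list[tuple]) -> dict[tuple, float]:
    """Sum per-atom SASA into per-residue totals keyed by residue key."""
    out: dict[tuple, float] = {}
    for a, key in zip(per_atom, owners):
        out[key] = out.get(key, 0.0) + float(a)
    return out
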