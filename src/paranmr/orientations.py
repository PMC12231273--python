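"""Orientational averaging: Euler conventions, field direction, and
quadrature grids on the unit sphere.

Orientations of a rigid molecule in the lab frame are parametrized by
extrinsic-ZYZ Euler angles (chi, theta, phi).  Every quantity entering the
solution-state average depends only on the external-field direction in the
molecule-fixed frame,

    u(chi, theta) = (-sin(theta) cos(chi), sin(theta) sin(chi), cos(theta)),

so grids store unit field directions directly (no pole singularities) and the
analytic phi-integration is built in: only the lab-frame z component of the
induced field survives, assembled as u . <B_ind>_mol.

Grid catalog
------------
Closed-form Lebedev rules with 6, 14, 26, 38 and 50 points (octahedral
orbits with rational weights and algebraic points, exact through spherical-
harmonic degree 3, 5, 7, 9, 11) plus Gauss-Legendre (theta) x uniform (phi)
product rules of arbitrary even degree for high-accuracy reference averaging.
Weights are normalized to sum to 1 (the 1/4pi of the rotational average is
absorbed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_legendre, sph_harm_y

__all__ = [
    "OrientationGrid", "euler_to_rotation", "field_direction_mol",
    "lebedev_grid", "gauss_grid", "reference_grid", "grid_catalog",
    "orientational_average", "LEBEDEV_SIZES",
]


def euler_to_rotation(chi: float, theta: float, phi: float) -> np.ndarray:
    """Extrinsic-ZYZ rotation matrix R = R(Z,phi) R(Y,theta) R(Z,chi)."""
    cc, sc = np.cos(chi), np.sin(chi)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    rz_chi = np.array([[cc, -sc, 0.0], [sc, cc, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    rz_phi = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz_phi @ ry @ rz_chi


def field_direction_mol(chi: float, theta: float) -> np.ndarray:
    """External-field unit direction in the molecule-fixed frame (independent
    of the third Euler angle)."""
    st = np.sin(theta)
    return np.array([-st * np.cos(chi), st * np.sin(chi), np.cos(theta)])


@dataclass(frozen=True)
class OrientationGrid:
    """Unit field directions with normalized quadrature weights."""

    directions: np.ndarray      # (n, 3)
    weights: np.ndarray         # (n,), sum to 1
    name: str = ""
    degree: int = 0             # exact through this spherical-harmonic degree

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        w = np.asarray(self.weights, dtype=float).reshape(-1)
        if d.shape[0] != w.shape[0] or d.shape[1] != 3:
            raise ValueError("directions must be (n, 3) with matching weights")
        if d.shape[0] == 0:
            raise ValueError("grid must contain at least one point")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("grid directions must be unit vectors")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("grid weights must sum to 1")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.directions.shape[0]


def orientational_average(f, grid: OrientationGrid) -> float:
    """Quadrature average sum_i w_i f(u_i) of a scalar function of the unit
    field direction."""
    vals = np.array([f(u) for u in grid.directions], dtype=float)
    return float(vals @ grid.weights)


# ---------------------------------------------------------------------------
# Lebedev rules (octahedral orbits)
# ---------------------------------------------------------------------------

def _orbit_a1():
    """6 points (+-1, 0, 0) and permutations."""
    pts = []
    for ax in range(3):
        for s in (1.0, -1.0):
            v = np.zeros(3)
            v[ax] = s
            pts.append(v)
    return np.array(pts)


def _orbit_a2():
    """12 points (+-1, +-1, 0)/sqrt(2) and permutations."""
    r = 1.0 / np.sqrt(2.0)
    pts = []
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        for si in (1, -1):
            for sj in (1, -1):
                v = np.zeros(3)
                v[i], v[j] = si * r, sj * r
                pts.append(v)
    return np.array(pts)


def _orbit_a3():
    """8 points (+-1, +-1, +-1)/sqrt(3)."""
    r = 1.0 / np.sqrt(3.0)
    pts = []
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                pts.append(np.array([sx * r, sy * r, sz * r]))
    return np.array(pts)


def _orbit_b(l: float):
    """24 points (+-l, +-l, +-m) and permutations, 2 l^2 + m^2 = 1."""
    m = np.sqrt(max(0.0, 1.0 - 2.0 * l * l))
    pts = []
    for pos in range(3):            # position of the m component
        for sm in (1, -1):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    v = [s1 * l, s2 * l]
                    v.insert(pos, sm * m)
                    pts.append(np.array(v))
    return np.array(pts)


def _orbit_c(p: float):
    """24 points (+-p, +-q, 0) and permutations, p^2 + q^2 = 1."""
    q = np.sqrt(max(0.0, 1.0 - p * p))
    pts = []
    for (i, j) in ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)):
        for sp in (1, -1):
            for sq in (1, -1):
                v = np.zeros(3)
                v[i], v[j] = sp * p, sq * q
                pts.append(v)
    return np.array(pts)


def _lebedev_6():
    return [(_orbit_a1(), 1.0 / 6.0)], 3


def _lebedev_14():
    return [(_orbit_a1(), 1.0 / 15.0), (_orbit_a3(), 3.0 / 40.0)], 5


def _lebedev_26():
    return [(_orbit_a1(), 1.0 / 21.0), (_orbit_a2(), 4.0 / 105.0),
            (_orbit_a3(), 9.0 / 280.0)], 7


def _lebedev_38():
    # c-orbit with p^2 = (1 + 3^-1/2)/2
    p = np.sqrt((1.0 + 1.0 / np.sqrt(3.0)) / 2.0)
    return [(_orbit_a1(), 1.0 / 105.0), (_orbit_a3(), 9.0 / 280.0),
            (_orbit_c(p), 1.0 / 35.0)], 9


def _lebedev_50():
    l = 1.0 / np.sqrt(11.0)
    return [(_orbit_a1(), 4.0 / 315.0), (_orbit_a2(), 64.0 / 2835.0),
            (_orbit_a3(), 27.0 / 1280.0), (_orbit_b(l), 14641.0 / 725760.0)], 11


_LEBEDEV_BUILDERS = {6: _lebedev_6, 14: _lebedev_14, 26: _lebedev_26,
                     38: _lebedev_38, 50: _lebedev_50}

#: available Lebedev rule sizes
LEBEDEV_SIZES = tuple(sorted(_LEBEDEV_BUILDERS))


def lebedev_grid(n_points: int) -> OrientationGrid:
    """Closed-form Lebedev quadrature rule with the given point count."""
    try:
        builder = _LEBEDEV_BUILDERS[n_points]
    except KeyError:
        raise ValueError(
            f"no Lebedev rule with {n_points} points; available sizes: "
            f"{list(LEBEDEV_SIZES)} (use gauss_grid for higher accuracy)"
        ) from None
    orbits, degree = builder()
    pts = np.vstack([o for o, _ in orbits])
    wts = np.concatenate([np.full(len(o), w) for o, w in orbits])
    return OrientationGrid(pts, wts, name=f"lebedev-{n_points}", degree=degree)


# ---------------------------------------------------------------------------
# Gauss-Legendre x uniform product rules
# ---------------------------------------------------------------------------

def gauss_grid(degree: int) -> OrientationGrid:
    """Spherical product rule exact for all spherical harmonics up to
    ``degree``: Gauss-Legendre in cos(theta), uniform in the azimuth."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n_theta = degree // 2 + 1
    n_phi = degree + 1
    x, w = roots_legendre(n_theta)              # nodes in cos(theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - x**2)
    dirs = np.empty((n_theta * n_phi, 3))
    wts = np.empty(n_theta * n_phi)
    k = 0
    for i in range(n_theta):
        for p in range(n_phi):
            dirs[k] = (st[i] * np.cos(phi[p]), st[i] * np.sin(phi[p]), x[i])
            wts[k] = w[i] / (2.0 * n_phi)
            k += 1
    wts /= wts.sum()                            # exact normalization
    return OrientationGrid(dirs, wts, name=f"gauss-{degree}", degree=degree)


def reference_grid() -> OrientationGrid:
    """High-accuracy reference grid (degree 131, 8712 points) used to gauge
    the convergence of the small production grids."""
    return gauss_grid(131)


def grid_catalog() -> list[OrientationGrid]:
    """Sequence of 32 grids of increasing design degree (5 Lebedev rules and
    27 product rules) used for convergence sweeps."""
    grids = [lebedev_grid(n) for n in LEBEDEV_SIZES]
    for deg in range(13, 132, 6):       # 13, 19, ..., 127 -> 20 grids
        grids.append(gauss_grid(deg))
    for deg in (35, 47, 59, 71, 83, 95, 107):
        grids.append(gauss_grid(deg))
    grids.sort(key=lambda g: (g.degree, len(g)))
    return grids


def spherical_harmonic_integral(grid: OrientationGrid, l: int, m: int) -> complex:
    """Quadrature value of the average of Y_l^m over the sphere (zero for
    l > 0 if the grid integrates degree l exactly)."""
    u = grid.directions
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    vals = sph_harm_y(l, m, theta, phi)
    return complex(np.sum(grid.weights * vals))
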