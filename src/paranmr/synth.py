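"""Seeded synthetic spin systems emulating a high-spin Ni(II)-like complex.

Defaults mimic the regime of a pentacoordinate S = 1 nickel complex in
solution: zero-field splitting of a few cm^-1 with rhombicity E/D in
[0, 1/3] and a randomly oriented principal frame, g principal values around
2.1-2.3, and protons 2-6 angstrom from the paramagnetic center with
isotropic hyperfine couplings up to ~1 MHz.  Everything is drawn from one
seeded generator, so a seed fully determines the system bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .spin_core import Nucleus, SpinSystem, zfs_tensor

__all__ = ["synthetic_system", "random_rotation"]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation from a QR decomposition."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def synthetic_system(seed: int, S: float = 1.0, *, n_nuclei: int = 5,
                     d_range_cm1: tuple[float, float] = (2.0, 10.0),
                     g_range: tuple[float, float] = (2.1, 2.3),
                     r_range_angstrom: tuple[float, float] = (2.0, 6.0),
                     a_max_mhz: float = 1.0) -> tuple[SpinSystem, list[Nucleus]]:
    """Deterministic synthetic (SpinSystem, nuclei) pair for a given seed.

    D is built traceless symmetric from a sampled axial magnitude, a
    rhombicity E/D in [0, 1/3] and a random principal-frame rotation; g is
    diagonal in its own random frame with principal values in ``g_range``.
    Nuclei are protons at random directions and distances with A_iso drawn
    uniformly in [-a_max, a_max] MHz.
    """
    rng = np.random.default_rng(seed)
    d_mag = rng.uniform(*d_range_cm1) * rng.choice([-1.0, 1.0])
    e_over_d = rng.uniform(0.0, 1.0 / 3.0)
    D = zfs_tensor(d_mag, e_over_d * abs(d_mag), rotation=random_rotation(rng))
    g_principal = rng.uniform(*g_range, size=3)
    Rg = random_rotation(rng)
    g = Rg @ np.diag(g_principal) @ Rg.T
    system = SpinSystem(S=S, g=g, D_cm1=D)

    nuclei = []
    for i in range(n_nuclei):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = rng.uniform(*r_range_angstrom)
        a_iso = rng.uniform(-a_max_mhz, a_max_mhz)
        nuclei.append(Nucleus.from_isotope(
            label=f"H{i + 1}", position=r * u, A_iso_mhz=a_iso, isotope="1H"))
    return system, nuclei
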