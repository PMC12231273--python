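"""Hyperfine coupling operators: the dH/dM operator triples for Fermi-contact
and point-dipole pseudocontact shifts, and the electronic magnetic moment.

Fermi contact (isotropic hyperfine coupling A_iso):

    dH/dM_i = (A_iso / gamma) S_i

Pseudocontact, point-dipole approximation with the electronic moment treated
as a point dipole at the paramagnetic center:

    dH/dM = -(3 alpha^2 / r^3) (rhat (x) rhat)^aniso . M_el
    (rhat (x) rhat)^aniso_ij = rhat_i rhat_j - delta_ij / 3

with M_el = -dH/dB = -(1/2) g S (spin-Hamiltonian approximation).  All
operators are in Hartree atomic units per unit nuclear moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as const
from .spin_core import Nucleus, SpinSystem

__all__ = ["CouplingOperator", "fc_operator", "pc_operator", "electronic_moment_operator"]

#: below this center-nucleus distance (angstrom) the point-dipole picture is
#: considered broken and pc_operator refuses to proceed
MIN_PDA_DISTANCE_ANGSTROM = 0.5


@dataclass(frozen=True)
class CouplingOperator:
    """Triple of Hermitian dH/dM component operators for one nucleus."""

    components: tuple[np.ndarray, np.ndarray, np.ndarray]
    kind: str                   # "FC" | "PC"
    label: str = ""

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, i):
        return self.components[i]


def fc_operator(system: SpinSystem, nucleus: Nucleus) -> CouplingOperator:
    """Fermi-contact coupling operator (A_iso / gamma) S."""
    if nucleus.gamma_si == 0.0:
        raise ValueError("gamma must be nonzero")
    scale = nucleus.A_iso_au / nucleus.gamma_au
    sops = system.spin_ops()
    return CouplingOperator(
        components=tuple(scale * s for s in sops), kind="FC", label=nucleus.label)


def electronic_moment_operator(system: SpinSystem) -> tuple[np.ndarray, ...]:
    """Electronic magnetic moment M_el = -dH/dB = -(1/2) g S (a.u.):
    M_el,i = -(1/2) sum_k g_ik S_k, the exact field derivative of the Zeeman
    term (1/2) B^T g S for general (also non-symmetric) g."""
    sops = system.spin_ops()
    out = []
    for i in range(3):
        m = np.zeros_like(sops[0])
        for k in range(3):
            if system.g[i, k] != 0.0:
                m = m - 0.5 * system.g[i, k] * sops[k]
        out.append(m)
    return tuple(out)


def pc_operator(system: SpinSystem, nucleus: Nucleus, center=(0.0, 0.0, 0.0),
                min_distance_angstrom: float = MIN_PDA_DISTANCE_ANGSTROM) -> CouplingOperator:
    """Point-dipole pseudocontact coupling operator.

    ``center`` is the paramagnetic center (angstrom, molecule-fixed frame,
    default the origin).  Distances below ``min_distance_angstrom`` raise, as
    the point-dipole approximation has broken down there anyway.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    rvec = nucleus.position - center
    r_ang = float(np.linalg.norm(rvec))
    if r_ang < min_distance_angstrom:
        raise ValueError(
            f"nucleus {nucleus.label}: center-nucleus distance {r_ang:.3f} A is below "
            f"the point-dipole validity guard ({min_distance_angstrom} A)")
    r_au = const.angstrom_to_au(r_ang)
    rhat = rvec / r_ang
    aniso = np.outer(rhat, rhat) - np.eye(3) / 3.0
    mel = electronic_moment_operator(system)
    pref = -3.0 * const.FINE_STRUCTURE**2 / r_au**3
    comps = []
    for i in range(3):
        op = np.zeros_like(mel[0])
        for j in range(3):
            if aniso[i, j] != 0.0:
                op = op + aniso[i, j] * mel[j]
        comps.append(pref * op)
    return CouplingOperator(components=tuple(comps), kind="PC", label=nucleus.label)
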