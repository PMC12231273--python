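"""Spin operator algebra and the electronic Zeeman + zero-field-splitting
Hamiltonian.

The electronic model is a single spin multiplet |S, mS> (mS = S ... -S) with

    H = S^T D S + (1/2) B^T g S          (Hartree atomic units)

where D is the traceless symmetric zero-field-splitting tensor, g the (not
necessarily symmetric) g-matrix and the prefactor 1/2 is the Bohr magneton in
atomic units.  Hyperfine terms are deliberately left out of the diagonalized
Hamiltonian; the nuclear moment enters only through coupling operators
(see :mod:`paranmr.observables`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as const

__all__ = ["SpinSystem", "Nucleus", "spin_matrices", "build_hamiltonian",
           "build_hamiltonian_au", "zfs_tensor"]


def spin_matrices(S: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian spin matrices (Sx, Sy, Sz) for spin quantum number S.

    Basis is |S, mS> ordered mS = S, S-1, ..., -S, so the matrices are
    reproducible bit-for-bit.  Raises ``ValueError`` for non-half-integer S.
    """
    two_s = round(2 * S)
    if two_s < 0 or abs(2 * S - two_s) > 1e-12:
        raise ValueError(f"S must be a non-negative half-integer, got {S}")
    dim = two_s + 1
    m = S - np.arange(dim)                      # S ... -S
    sz = np.diag(m).astype(complex)
    # ladder: S+|S,m> = sqrt(S(S+1)-m(m+1)) |S,m+1>; with our ordering the
    # m+1 state sits one row above.
    cplus = np.sqrt(S * (S + 1) - m[1:] * (m[1:] + 1))
    sp = np.zeros((dim, dim), dtype=complex)
    sp[np.arange(dim - 1), np.arange(1, dim)] = cplus
    sm = sp.conj().T
    sx = 0.5 * (sp + sm)
    sy = -0.5j * (sp - sm)
    return sx, sy, sz


def zfs_tensor(D_cm1: float, E_cm1: float = 0.0, rotation: np.ndarray | None = None) -> np.ndarray:
    """Traceless symmetric D tensor (cm^-1) from axial D, rhombic E and an
    optional principal-axis rotation.

    Principal values are (-D/3 + E, -D/3 - E, 2D/3); ``rotation`` (3x3
    orthogonal) carries the principal frame into the molecular frame.
    """
    d = np.diag([-D_cm1 / 3.0 + E_cm1, -D_cm1 / 3.0 - E_cm1, 2.0 * D_cm1 / 3.0])
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        d = rotation @ d @ rotation.T
    return d


@dataclass(frozen=True)
class SpinSystem:
    """Electronic spin system: S, g matrix, ZFS tensor.

    Parameters
    ----------
    S : half-integer spin quantum number.
    g : (3, 3) dimensionless g-matrix.  Accepted verbatim; no symmetrization.
    D_cm1 : (3, 3) symmetric ZFS tensor in cm^-1.  The trace is projected out
        on input (stored D is exactly traceless); asymmetry is an error.
    """

    S: float
    g: np.ndarray
    D_au: np.ndarray = field(init=False)
    D_cm1: np.ndarray | None = None

    def __post_init__(self):
        two_s = round(2 * self.S)
        if two_s < 0 or abs(2 * self.S - two_s) > 1e-12:
            raise ValueError(f"S must be a non-negative half-integer, got {self.S}")
        g = np.asarray(self.g, dtype=float)
        if g.shape != (3, 3):
            raise ValueError("g must be a 3x3 matrix")
        object.__setattr__(self, "g", g)
        d = np.zeros((3, 3)) if self.D_cm1 is None else np.asarray(self.D_cm1, dtype=float)
        if d.shape != (3, 3):
            raise ValueError("D must be a 3x3 matrix")
        norm = np.linalg.norm(d)
        if norm > 0 and np.linalg.norm(d - d.T) > 1e-10 * norm:
            raise ValueError("D must be symmetric")
        d = 0.5 * (d + d.T)
        d = d - np.eye(3) * (np.trace(d) / 3.0)     # enforce tracelessness
        object.__setattr__(self, "D_cm1", d)
        object.__setattr__(self, "D_au", const.cm1_to_au(d))

    @property
    def dim(self) -> int:
        return round(2 * self.S) + 1

    def spin_ops(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return spin_matrices(self.S)

    def rotated(self, R: np.ndarray) -> "SpinSystem":
        """System with g and D jointly rotated into a new frame: g -> R g R^T."""
        R = np.asarray(R, dtype=float)
        return SpinSystem(S=self.S, g=R @ self.g @ R.T, D_cm1=R @ self.D_cm1 @ R.T)


@dataclass(frozen=True)
class Nucleus:
    """Magnetic nucleus: molecule-fixed position (angstrom), isotropic
    hyperfine coupling (MHz) and gyromagnetic ratio (rad s^-1 T^-1)."""

    label: str
    position: np.ndarray
    A_iso_mhz: float = 0.0
    gamma_si: float = const.GAMMA_PROTON_SI

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"nucleus {self.label}: position must be finite")
        if self.gamma_si == 0.0:
            raise ValueError(f"nucleus {self.label}: gamma must be nonzero")
        object.__setattr__(self, "position", pos)

    @property
    def A_iso_au(self) -> float:
        return const.mhz_to_au(self.A_iso_mhz)

    @property
    def gamma_au(self) -> float:
        return const.gamma_si_to_au(self.gamma_si)

    @classmethod
    def from_isotope(cls, label: str, position, A_iso_mhz: float = 0.0,
                     isotope: str = "1H") -> "Nucleus":
        try:
            gamma = const.GAMMA_SI_BY_ISOTOPE[isotope]
        except KeyError:
            raise ValueError(
                f"unknown isotope {isotope!r}; known: "
                f"{sorted(const.GAMMA_SI_BY_ISOTOPE)} (or pass gamma_si directly)"
            ) from None
        return cls(label=label, position=position, A_iso_mhz=A_iso_mhz, gamma_si=gamma)


def build_hamiltonian(system: SpinSystem, B_mol_tesla) -> np.ndarray:
    """Electronic spin Hamiltonian H = S.D.S + (1/2) B^T g S in hartree.

    ``B_mol_tesla`` is the external field in the molecule-fixed frame
    (tesla); it is converted to atomic units internally (Bohr magneton = 1/2).
    """
    B = np.asarray(B_mol_tesla, dtype=float).reshape(3)
    if not np.all(np.isfinite(B)):
        raise ValueError("B_mol must be finite")
    return build_hamiltonian_au(system, const.tesla_to_au(B))


def build_hamiltonian_au(system: SpinSystem, b_mol_au) -> np.ndarray:
    """Same as :func:`build_hamiltonian` with the field already in atomic
    units (internal workhorse for derivative code)."""
    b_au = np.asarray(b_mol_au, dtype=float).reshape(3)
    sx, sy, sz = system.spin_ops()
    sops = (sx, sy, sz)
    dim = system.dim
    H = np.zeros((dim, dim), dtype=complex)
    D = system.D_au
    for i in range(3):
        for j in range(3):
            if D[i, j] != 0.0:
                H += D[i, j] * (sops[i] @ sops[j])
    zee = const.MU_BOHR_AU * (b_au @ system.g)     # row vector: sum_j B_j g_jk
    for k in range(3):
        if zee[k] != 0.0:
            H += zee[k] * sops[k]
    return 0.5 * (H + H.conj().T)                   # exact hermitization
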