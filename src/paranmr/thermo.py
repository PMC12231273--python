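"""Exact-diagonalization thermodynamics of the electronic manifold.

All Boltzmann factors are computed relative to the ground state, so the
partition function and free energy stay finite at arbitrarily low temperature
and high field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as const
from .spin_core import SpinSystem, build_hamiltonian

__all__ = ["ThermalState", "thermal_state", "thermal_expectation", "induced_field_mol"]


@dataclass(frozen=True)
class ThermalState:
    """Canonical state of a (small) Hermitian Hamiltonian at temperature T.

    ``Z`` is the full partition function sum_i exp(-beta E_i) evaluated with
    the ground-state energy factored out (``Z = Z_rel * exp(-beta E_min)``
    conceptually; the stored ``Z_rel`` is overflow-safe), and
    ``F = E_min - kT ln Z_rel`` is the Helmholtz free energy in hartree.
    """

    eigenvalues: np.ndarray     # ascending, hartree
    eigenvectors: np.ndarray    # columns are eigenstates
    populations: np.ndarray
    Z_rel: float                # sum exp(-beta (E - E_min))
    F: float                    # hartree
    T: float                    # kelvin

    @property
    def beta(self) -> float:
        return 1.0 / (const.KBOLTZ_AU * self.T)


def thermal_state(H: np.ndarray, T: float) -> ThermalState:
    """Diagonalize H (hartree) and build its canonical state at T kelvin."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    H = np.asarray(H)
    evals, evecs = np.linalg.eigh(H)
    beta = 1.0 / (const.KBOLTZ_AU * T)
    w = np.exp(-beta * (evals - evals[0]))
    z_rel = float(np.sum(w))
    pops = w / z_rel
    F = float(evals[0] - np.log(z_rel) / beta)
    return ThermalState(eigenvalues=evals, eigenvectors=evecs, populations=pops,
                        Z_rel=z_rel, F=F, T=T)


def thermal_expectation(state: ThermalState, O: np.ndarray) -> float:
    """Canonical ensemble average (1/Z) sum_i <i|O|i> exp(-beta E_i)."""
    O = np.asarray(O)
    n = state.eigenvalues.shape[0]
    if O.shape != (n, n):
        raise ValueError(f"operator dimension {O.shape} does not match state dimension {n}")
    diag = np.einsum("ji,jk,ki->i", state.eigenvectors.conj(), O, state.eigenvectors)
    return float(np.real(diag @ state.populations))


def induced_field_mol(system: SpinSystem, dHdM, B_mol_tesla, T: float) -> np.ndarray:
    """Electronically averaged induced field at the nucleus, molecule-fixed
    frame, tesla:  <B_ind>_i = -< dH/dM_i >_thermal.

    ``dHdM`` is the triple of Hermitian coupling operators (hartree per a.u.
    nuclear moment), e.g. from :mod:`paranmr.observables`.
    """
    H = build_hamiltonian(system, B_mol_tesla)
    state = thermal_state(H, T)
    b_au = np.array([-thermal_expectation(state, op) for op in dHdM])
    return const.au_to_tesla(b_au)
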