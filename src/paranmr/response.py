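"""Free-energy derivative tensors at zero field.

Two independent routes compute derivatives of the electronic Helmholtz free
energy F(B, M) = -kT ln Tr exp(-beta H) with respect to the external field B
and the nuclear moment M (both molecule-fixed, atomic units):

* a **numerical-differentiation oracle**: the first M-derivative is taken
  analytically through the Hellmann-Feynman identity
  F_Mi(B) = <dH/dM_i>_thermal, and the remaining B-derivatives by central
  differences with Richardson extrapolation;

* an **analytic sum-over-states route**: the imaginary-time (Duhamel)
  expansion of Tr exp(-beta H) expresses the n-th derivative of the partition
  function as a cycle sum of operator matrix elements weighted by confluent
  divided differences of exp(-beta x) over the field-free eigenvalues
  (evaluated in the Opitz matrix-function form, which is uniformly stable
  through exact and near degeneracies); free-energy derivatives then follow
  from the log-derivative (cumulant) formulas.  For second derivatives this
  reduces to the familiar Van Vleck / Van den Heuvel-Soncini expressions.

The physical tensors are

    sigma_ji = F_{Mi Bj}(0)            chemical shielding (dimensionless)
    chi_ij   = -mu0 F_{Bi Bj}(0)       susceptibility (volume / molecule)
    tau4^i_jkl = F_{Mi Bj Bk Bl}(0)/3! with scalar tau = tau4^(4:2)/5
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import constants as const
from .observables import CouplingOperator, fc_operator, pc_operator
from .spin_core import Nucleus, SpinSystem, build_hamiltonian_au
from .thermo import thermal_state

__all__ = [
    "ResponseTensors", "SpinMoments", "NumericDerivative",
    "numeric_free_energy_derivatives", "sos_free_energy_derivatives",
    "spin_moments", "assemble_response", "contract_moments",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _zeeman_ops(system: SpinSystem) -> list[np.ndarray]:
    """dH/dB_j = (1/2) sum_k g_jk S_k (a.u.)."""
    sops = system.spin_ops()
    return [const.MU_BOHR_AU * sum(system.g[j, k] * sops[k] for k in range(3))
            for j in range(3)]


def _hf_vector(system: SpinSystem, ops, b_au, T: float) -> np.ndarray:
    """Hellmann-Feynman first derivatives <ops_i> at field b_au."""
    H = build_hamiltonian_au(system, b_au)
    st = thermal_state(H, T)
    rho = (st.eigenvectors * st.populations) @ st.eigenvectors.conj().T
    return np.array([float(np.real(np.trace(rho @ op))) for op in ops])


# ---------------------------------------------------------------------------
# numerical-differentiation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumericDerivative:
    """Finite-difference derivative tensor with a Richardson error estimate.

    ``converged`` is False when the extrapolation did not reach ``rtol``;
    the value is still returned (flagged, never silent).
    """

    tensor: np.ndarray
    error: float
    converged: bool


def _richardson(seq: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Extrapolate a sequence of O(h^2) central-difference estimates computed
    at steps h, h/2, h/4, ... to zero step (Neville table); the error
    estimate is the relative difference of the last two table diagonals."""
    row = [np.asarray(s, dtype=float) for s in seq]     # column m = 0
    diag = [row[0]]
    for m in range(1, len(seq)):
        fac = 4.0**m
        row = [(fac * row[k + 1] - row[k]) / (fac - 1.0)
               for k in range(len(row) - 1)]
        diag.append(row[0])
    best = diag[-1]
    scale = max(np.max(np.abs(best)), 1e-300)
    return best, float(np.max(np.abs(diag[-1] - diag[-2])) / scale)


def _directional(fun, u, order: int, h0: float, levels: int) -> list[np.ndarray]:
    """Central-difference directional derivatives d^order/dt^order fun(t u)
    at t = 0 for steps h0 / 2^k, k = 0..levels-1."""
    u = np.asarray(u, dtype=float)
    out = []
    for k in range(levels):
        h = h0 / 2.0**k
        if order == 1:
            v = (fun(h * u) - fun(-h * u)) / (2.0 * h)
        elif order == 2:
            v = (fun(h * u) - 2.0 * fun(0.0 * u) + fun(-h * u)) / h**2
        elif order == 3:
            v = (fun(2 * h * u) - 2.0 * fun(h * u)
                 + 2.0 * fun(-h * u) - fun(-2 * h * u)) / (2.0 * h**3)
        else:
            raise ValueError(f"unsupported stencil order {order}")
        out.append(v)
    return out


def _base_step(system: SpinSystem, T: float) -> float:
    """Field step (a.u.) on the scale of the thermal Zeeman nonlinearity:
    0.05 kT / (muB g_max)."""
    gmax = max(np.max(np.abs(system.g)), 0.5)
    return 0.05 * const.KBOLTZ_AU * T / (const.MU_BOHR_AU * gmax)


def numeric_free_energy_derivatives(system: SpinSystem, dHdM=None, *, T: float,
                                    order: int, rtol: float = 1e-6,
                                    levels: int = 5) -> NumericDerivative:
    """Mixed free-energy derivatives at zero field by finite differences.

    With ``dHdM`` (an operator triple) the first slot is the nuclear-moment
    derivative, taken analytically via Hellmann-Feynman, and ``order``-1
    B-derivatives are taken numerically; without it all slots are
    B-derivatives (the first again via Hellmann-Feynman on dH/dB).  Returns
    F_{mu B...B} of shape (3,)*order.
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be 2, 3 or 4")
    ops = list(dHdM) if dHdM is not None else _zeeman_ops(system)
    fun = lambda b: _hf_vector(system, ops, b, T)       # noqa: E731
    h0 = _base_step(system, T)
    eye = np.eye(3)
    n_b = order - 1
    tensor = np.zeros((3,) * order)
    errs = []

    if n_b == 1:
        for j in range(3):
            seq = _directional(fun, eye[j], 1, h0, levels)
            val, err = _richardson(seq)
            tensor[:, j] = val
            errs.append(err)
    elif n_b == 2:
        # d2 g / dBj dBk via polarization of second directional derivatives
        for j in range(3):
            for k in range(j, 3):
                if j == k:
                    seq = _directional(fun, eye[j], 2, h0, levels)
                else:
                    sp = _directional(fun, eye[j] + eye[k], 2, h0, levels)
                    sm = _directional(fun, eye[j] - eye[k], 2, h0, levels)
                    seq = [0.25 * (a - b) for a, b in zip(sp, sm)]
                val, err = _richardson(seq)
                tensor[:, j, k] = val
                tensor[:, k, j] = val
                errs.append(err)
    else:
        # d3 g / dBj dBk dBl via trilinear polarization:
        # T(a,b,c) = (1/48) sum_eps eps1 eps2 eps3 D3 g(eps1 a + eps2 b + eps3 c)
        for j in range(3):
            for k in range(j, 3):
                for l in range(k, 3):
                    acc = None
                    for e1, e2, e3 in itertools.product((1, -1), repeat=3):
                        u = e1 * eye[j] + e2 * eye[k] + e3 * eye[l]
                        seq = _directional(fun, u, 3, h0, levels)
                        term = [e1 * e2 * e3 * s / 48.0 for s in seq]
                        acc = term if acc is None else [a + t for a, t in zip(acc, term)]
                    val, err = _richardson(acc)
                    for perm in set(itertools.permutations((j, k, l))):
                        tensor[(slice(None),) + perm] = val
                    errs.append(err)

    err = float(max(errs))
    return NumericDerivative(tensor=tensor, error=err, converged=err <= rtol)


# ---------------------------------------------------------------------------
# analytic sum-over-states route
# ---------------------------------------------------------------------------

def _divdiff_weights(E: np.ndarray, beta: float, n_ops: int) -> np.ndarray:
    """State-level weight tensor G[n, m1, ..., m_{n_ops-1}] of confluent
    divided differences of exp(-beta x) over (E_n, E_n, E_m1, ..., E_m(k)).

    Computed from the Opitz identity dd[x0..xk] = [f(J)]_{0,k} with J the
    bidiagonal matrix of the nodes, in the scaled variable y = beta E so the
    matrix exponentials stay well conditioned.  Shape (N,) * n_ops.
    """
    y = beta * E
    N = y.shape[0]
    k = n_ops + 1                                 # number of nodes
    idx = np.indices((N,) * n_ops).reshape(n_ops, -1).T    # (batch, n_ops)
    nodes = np.concatenate([y[idx[:, :1]], y[idx]], axis=1)  # duplicate first
    # divided differences are symmetric in the nodes; sorting merges
    # duplicate evaluations
    nodes_sorted = np.sort(nodes, axis=1)
    uniq, inv = np.unique(nodes_sorted, axis=0, return_inverse=True)
    J = np.zeros((uniq.shape[0], k, k))
    for i in range(k):
        J[:, i, i] = -uniq[:, i]
    for i in range(k - 1):
        J[:, i, i + 1] = -1.0
    vals = expm(J)[:, 0, k - 1]
    g = vals[inv] * beta**n_ops
    return g.reshape((N,) * n_ops)


class _SosEngine:
    """Partition-function derivatives of the field-free spin Hamiltonian."""

    def __init__(self, system: SpinSystem, T: float):
        if T <= 0:
            raise ValueError(f"temperature must be > 0 K, got {T}")
        self.system = system
        self.T = T
        self.beta = 1.0 / (const.KBOLTZ_AU * T)
        H0 = build_hamiltonian_au(system, np.zeros(3))
        evals, evecs = np.linalg.eigh(H0)
        self.E = evals - evals[0]                  # overflow-safe shift
        self.U = evecs
        self.Z = float(np.sum(np.exp(-self.beta * self.E)))
        self._G: dict[int, np.ndarray] = {}

    def to_eigenbasis(self, ops) -> np.ndarray:
        return np.stack([self.U.conj().T @ np.asarray(op) @ self.U for op in ops])

    def G(self, n: int) -> np.ndarray:
        if n not in self._G:
            self._G[n] = _divdiff_weights(self.E, self.beta, n)
        return self._G[n]

    # Z-derivative cycle sums; each V* has shape (k, N, N)
    def z1(self, Va: np.ndarray) -> np.ndarray:
        return np.real(np.einsum("ann,n->a", Va, self.G(1)))

    def z2(self, Va: np.ndarray, Vb: np.ndarray) -> np.ndarray:
        g = self.G(2)
        t1 = np.einsum("anm,bmn,nm->ab", Va, Vb, g)
        t2 = np.einsum("bnm,amn,nm->ab", Vb, Va, g)
        return np.real(t1 + t2)

    def z3(self, Va, Vb, Vc) -> np.ndarray:
        g = self.G(3)
        out = 0.0
        slots = {"a": Va, "b": Vb, "c": Vc}
        for p in itertools.permutations("abc"):
            # cycle positions: X1[n,m] X2[m,p] X3[p,n] with weight G3[n,m,p]
            spec = f"{p[0]}nm,{p[1]}mp,{p[2]}pn,nmp->abc"
            out = out + np.einsum(spec, slots[p[0]], slots[p[1]], slots[p[2]], g)
        return np.real(out)

    def z4(self, Va, Vb, Vc, Vd) -> np.ndarray:
        g = self.G(4)
        out = 0.0
        slots = {"a": Va, "b": Vb, "c": Vc, "d": Vd}
        for p in itertools.permutations("abcd"):
            spec = (f"{p[0]}nm,{p[1]}mp,{p[2]}pq,{p[3]}qn,nmpq->abcd")
            out = out + np.einsum(spec, slots[p[0]], slots[p[1]],
                                  slots[p[2]], slots[p[3]], g)
        return np.real(out)


def _sos_f4(eng: _SosEngine, VM: np.ndarray, VB: np.ndarray) -> np.ndarray:
    """F_{Mi Bj Bk Bl}(0) via the cumulant assembly of Z-derivatives."""
    Z, beta = eng.Z, eng.beta
    zM1, zB1 = eng.z1(VM), eng.z1(VB)
    zMB = eng.z2(VM, VB)
    zBB = eng.z2(VB, VB)
    zMBB = eng.z3(VM, VB, VB)
    zBBB = eng.z3(VB, VB, VB)
    z4 = eng.z4(VM, VB, VB, VB)

    L = z4 / Z
    L -= (np.einsum("ijk,l->ijkl", zMBB, zB1) + np.einsum("ijl,k->ijkl", zMBB, zB1)
          + np.einsum("ikl,j->ijkl", zMBB, zB1)
          + np.einsum("jkl,i->ijkl", zBBB, zM1)) / Z**2
    L -= (np.einsum("ij,kl->ijkl", zMB, zBB) + np.einsum("ik,jl->ijkl", zMB, zBB)
          + np.einsum("il,jk->ijkl", zMB, zBB)) / Z**2
    L += 2.0 * (np.einsum("ij,k,l->ijkl", zMB, zB1, zB1)
                + np.einsum("ik,j,l->ijkl", zMB, zB1, zB1)
                + np.einsum("il,j,k->ijkl", zMB, zB1, zB1)
                + np.einsum("jk,i,l->ijkl", zBB, zM1, zB1)
                + np.einsum("jl,i,k->ijkl", zBB, zM1, zB1)
                + np.einsum("kl,i,j->ijkl", zBB, zM1, zB1)) / Z**3
    L -= 6.0 * np.einsum("i,j,k,l->ijkl", zM1, zB1, zB1, zB1) / Z**4
    return -L / beta


def _sos_f3(eng: _SosEngine, VM, VB) -> np.ndarray:
    Z, beta = eng.Z, eng.beta
    zM1, zB1 = eng.z1(VM), eng.z1(VB)
    zMB = eng.z2(VM, VB)
    zBB = eng.z2(VB, VB)
    z3 = eng.z3(VM, VB, VB)
    L = z3 / Z
    L -= (np.einsum("ij,k->ijk", zMB, zB1) + np.einsum("ik,j->ijk", zMB, zB1)
          + np.einsum("jk,i->ijk", zBB, zM1)) / Z**2
    L += 2.0 * np.einsum("i,j,k->ijk", zM1, zB1, zB1) / Z**3
    return -L / beta


def _sos_f2(eng: _SosEngine, Va, Vb) -> np.ndarray:
    Z, beta = eng.Z, eng.beta
    L = eng.z2(Va, Vb) / Z - np.outer(eng.z1(Va), eng.z1(Vb)) / Z**2
    return -L / beta


def sos_free_energy_derivatives(system: SpinSystem, dHdM=None, *, T: float,
                                order: int) -> np.ndarray:
    """Analytic sum-over-states free-energy derivatives at zero field.

    Same conventions and shapes as :func:`numeric_free_energy_derivatives`:
    with ``dHdM`` the first index is the nuclear-moment slot, the remaining
    ``order``-1 indices are field slots; without it all slots are field
    derivatives.
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be 2, 3 or 4")
    eng = _SosEngine(system, T)
    VB = eng.to_eigenbasis(_zeeman_ops(system))
    VM = eng.to_eigenbasis(dHdM) if dHdM is not None else VB
    if order == 2:
        return _sos_f2(eng, VM, VB)
    if order == 3:
        return _sos_f3(eng, VM, VB)
    return _sos_f4(eng, VM, VB)


# ---------------------------------------------------------------------------
# spin moments and tensor assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinMoments:
    """Thermal response tensors of spin-component products.

    ``dyadic``  = <<S_i S_j>>       (free-energy second derivative w.r.t.
    parameters coupling linearly to S; equals -beta <S_i S_j> for D = 0)
    ``tetradic`` = <<S_i S_j S_k S_l>> (fourth derivative; supersymmetric).
    """

    dyadic: np.ndarray
    tetradic: np.ndarray
    T: float


def spin_moments(system: SpinSystem, T: float) -> SpinMoments:
    """Spin dyadic and tetradic of the field-free Hamiltonian S.D.S."""
    eng = _SosEngine(system, T)
    S = eng.to_eigenbasis(system.spin_ops())
    dyadic = _sos_f2(eng, S, S)
    tetradic = _sos_f4(eng, S, S)
    return SpinMoments(dyadic=dyadic, tetradic=tetradic, T=T)


def contract_moments(moments: SpinMoments, coeff_M: np.ndarray,
                     coeff_B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (F_MB, F_BB, F_MBBB) from spin moments for couplings linear
    in spin: dH/dM_i = sum_p coeff_M[i,p] S_p, dH/dB_j = sum_q coeff_B[j,q] S_q."""
    f_mb = np.einsum("ip,jq,pq->ij", coeff_M, coeff_B, moments.dyadic)
    f_bb = np.einsum("ip,jq,pq->ij", coeff_B, coeff_B, moments.dyadic)
    f_mbbb = np.einsum("ip,jq,kr,ls,pqrs->ijkl", coeff_M, coeff_B, coeff_B,
                       coeff_B, moments.tetradic)
    return f_mb, f_bb, f_mbbb


@dataclass(frozen=True)
class ResponseTensors:
    """Zero-field response tensors for one nucleus.

    sigma[j, i] = F_{Mi Bj}(0) (dimensionless); chi_si in m^3 per molecule;
    tau4[i, j, k, l] = F_{Mi Bj Bk Bl}(0)/3! with scalar tau (a.u.).
    ``parts`` holds the FC/PC decomposition of sigma, tau4 and tau.
    """

    sigma: np.ndarray
    chi_au: np.ndarray          # a.u. volume (bohr^3) per molecule
    tau4: np.ndarray
    T: float
    parts: dict = field(default_factory=dict)

    @property
    def chi_si(self) -> np.ndarray:
        return self.chi_au * const.M3_PER_AU_VOL

    @property
    def f_bb(self) -> np.ndarray:
        """Raw free-energy second field derivative F_BB = -chi/mu0 (a.u.)."""
        return -self.chi_au / const.MU0_AU

    @property
    def tau(self) -> float:
        return float(np.einsum("iijj->", self.tau4)) / 5.0

    @property
    def sigma_iso(self) -> float:
        return float(np.trace(self.sigma)) / 3.0


def assemble_response(system: SpinSystem, nucleus: Nucleus, T: float,
                      kinds=("FC", "PC"), center=(0.0, 0.0, 0.0)) -> ResponseTensors:
    """sigma, chi and tau4 for one nucleus via the analytic sum-over-states
    route, with the FC/PC decomposition kept separable."""
    eng = _SosEngine(system, T)
    VB = eng.to_eigenbasis(_zeeman_ops(system))
    f_bb = _sos_f2(eng, VB, VB)
    chi_au = -const.MU0_AU * f_bb

    sigma = np.zeros((3, 3))
    tau4 = np.zeros((3, 3, 3, 3))
    parts = {}
    for kind in kinds:
        if kind == "FC":
            coupling: CouplingOperator = fc_operator(system, nucleus)
        elif kind == "PC":
            coupling = pc_operator(system, nucleus, center=center)
        else:
            raise ValueError(f"unknown contribution kind {kind!r}")
        VM = eng.to_eigenbasis(coupling)
        f_mb = _sos_f2(eng, VM, VB)
        f4 = _sos_f4(eng, VM, VB)
        sig_k = f_mb.T                      # sigma_ji = F_{Mi Bj}
        tau4_k = f4 / 6.0
        sigma += sig_k
        tau4 += tau4_k
        parts[kind] = {"sigma": sig_k, "tau4": tau4_k,
                       "tau": float(np.einsum("iijj->", tau4_k)) / 5.0}
    return ResponseTensors(sigma=sigma, chi_au=chi_au, tau4=tau4, T=T, parts=parts)
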