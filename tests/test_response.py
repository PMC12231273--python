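"""Free-energy derivative tensors: numeric oracle vs analytic sum-over-states,
closed forms, covariance and scaling properties."""

import numpy as np
import pytest

from paranmr import constants as const
from paranmr.observables import fc_operator, pc_operator
from paranmr.response import (assemble_response, contract_moments,
                              numeric_free_energy_derivatives,
                              sos_free_energy_derivatives, spin_moments)
from paranmr.spin_core import Nucleus, SpinSystem, zfs_tensor
from paranmr.synth import random_rotation, synthetic_system

T298 = 298.0


def _beta(T):
    return 1.0 / (const.KBOLTZ_AU * T)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_curie_law_isotropic_doublet():
    """S=1/2, isotropic g, no ZFS: chi = mu0 muB^2 g^2 S(S+1)/(3 kT)."""
    g = 2.0023
    sys_ = SpinSystem(S=0.5, g=g * np.eye(3))
    for T in (100.0, 298.0, 500.0):
        curie = const.MU0_AU * const.MU_BOHR_AU**2 * g**2 * 0.75 / (
            3 * const.KBOLTZ_AU * T)
        chi_sos = -const.MU0_AU * sos_free_energy_derivatives(sys_, T=T, order=2)
        assert np.allclose(chi_sos, curie * np.eye(3), rtol=1e-12)
        nd = numeric_free_energy_derivatives(sys_, T=T, order=2)
        assert np.allclose(-const.MU0_AU * nd.tensor, curie * np.eye(3), rtol=1e-8)
        assert nd.converged


def test_fc_sigma_and_tau_match_tanh_series():
    """Isotropic S=1/2 FC: B_ind = (A/2gamma) tanh(beta g B0/4); the x and
    x^3 series coefficients give sigma_iso and tau."""
    g, T = 2.0, T298
    sys_ = SpinSystem(S=0.5, g=g * np.eye(3))
    nuc = Nucleus.from_isotope("H", [0, 0, 3.0], A_iso_mhz=0.6)
    fc = fc_operator(sys_, nuc)
    A, gam, beta = nuc.A_iso_au, nuc.gamma_au, _beta(T)
    delta0_closed = A * beta * g / (8 * gam)
    tau_closed = (A / (6 * gam)) * (beta * g / 4) ** 3
    sigma = sos_free_energy_derivatives(sys_, fc, T=T, order=2).T
    assert -np.trace(sigma) / 3 == pytest.approx(delta0_closed, rel=1e-12)
    tau4 = sos_free_energy_derivatives(sys_, fc, T=T, order=4) / 6.0
    tau = np.einsum("iijj->", tau4) / 5.0
    assert tau == pytest.approx(tau_closed, rel=1e-10)
    nd = numeric_free_energy_derivatives(sys_, fc, T=T, order=4)
    tau_num = np.einsum("iijj->", nd.tensor / 6.0) / 5.0
    assert tau_num == pytest.approx(tau_closed, rel=1e-8)


def test_one_dimensional_system_all_zero():
    """An S=0 analog (one-dimensional electronic space) has no response."""
    sys_ = SpinSystem(S=0.0, g=2.0 * np.eye(3))
    nuc = Nucleus.from_isotope("H", [0, 0, 2.0], A_iso_mhz=1.0)
    fc = fc_operator(sys_, nuc)
    for order in (2, 3, 4):
        assert np.allclose(sos_free_energy_derivatives(sys_, fc, T=T298, order=order), 0.0)
        assert np.allclose(
            numeric_free_energy_derivatives(sys_, fc, T=T298, order=order).tensor,
            0.0, atol=1e-20)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def _random_system(rng, S):
    d_mag = rng.uniform(1.0, 12.0) * rng.choice([-1, 1])
    D = zfs_tensor(d_mag, rng.uniform(0, 1 / 3) * abs(d_mag),
                   rotation=random_rotation(rng))
    gp = rng.uniform(1.9, 2.4, size=3)
    R = random_rotation(rng)
    return SpinSystem(S=S, g=R @ np.diag(gp) @ R.T, D_cm1=D)


@pytest.mark.parametrize("idx,S", [(i, s) for i, s in enumerate(
    [0.5, 1.0, 1.5, 2.0, 2.5] * 4)])
def test_sos_agrees_with_numeric_oracle(idx, S):
    """20-system seeded suite spanning S=1/2..5/2, rhombic D, anisotropic g:
    analytic sum-over-states derivatives match the finite-difference oracle
    to 1e-6 relative at orders 2 and 4, FC and PC couplings alike."""
    rng = np.random.default_rng(1000 + idx)
    sys_ = _random_system(rng, S)
    nuc = Nucleus.from_isotope("H", rng.uniform(2, 5) * _unit(rng),
                               A_iso_mhz=rng.uniform(-1, 1))
    for ops in (fc_operator(sys_, nuc), pc_operator(sys_, nuc), None):
        for order in (2, 4):
            sos = sos_free_energy_derivatives(sys_, ops, T=T298, order=order)
            num = numeric_free_energy_derivatives(sys_, ops, T=T298, order=order)
            scale = np.max(np.abs(sos))
            assert np.max(np.abs(sos - num.tensor)) <= 1e-6 * scale


def _unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def test_sos_vs_numeric_across_temperatures():
    """S=1 with D != 0: chi(T) from SOS tracks the oracle over 50-400 K
    (Curie plus temperature-independent Van Vleck structure)."""
    sys_ = SpinSystem(S=1.0, g=np.diag([2.1, 2.2, 2.3]), D_cm1=zfs_tensor(8.0, 1.5))
    for T in (50.0, 120.0, 298.0, 400.0):
        sos = sos_free_energy_derivatives(sys_, T=T, order=2)
        num = numeric_free_energy_derivatives(sys_, T=T, order=2)
        assert np.max(np.abs(sos - num.tensor)) <= 1e-6 * np.max(np.abs(sos))


def test_kramers_doublet_arbitrary_g():
    """Exact double degeneracy (Kramers S=1/2 with anisotropic g): the
    confluent SOS treatment agrees with the oracle."""
    rng = np.random.default_rng(9)
    g = 2.0 * np.eye(3) + 0.4 * rng.standard_normal((3, 3))
    sys_ = SpinSystem(S=0.5, g=g)
    nuc = Nucleus.from_isotope("H", [0, 1.5, 2.5], A_iso_mhz=0.7)
    for ops in (fc_operator(sys_, nuc), pc_operator(sys_, nuc)):
        for order in (2, 4):
            sos = sos_free_energy_derivatives(sys_, ops, T=T298, order=order)
            num = numeric_free_energy_derivatives(sys_, ops, T=T298, order=order)
            assert np.max(np.abs(sos - num.tensor)) <= 1e-6 * np.max(np.abs(sos))


# ---------------------------------------------------------------------------
# spin moments
# ---------------------------------------------------------------------------

def test_dyadic_isotropic_limit():
    """D = 0: <<S_i S_j>> = -beta S(S+1)/3 delta_ij."""
    for S in (0.5, 1.0, 2.5):
        sys_ = SpinSystem(S=S, g=2.0 * np.eye(3))
        mom = spin_moments(sys_, T298)
        expected = -_beta(T298) * S * (S + 1) / 3.0
        assert np.allclose(mom.dyadic, expected * np.eye(3), rtol=1e-12)


def test_tetradic_supersymmetric(ni_like):
    system, _ = ni_like
    mom = spin_moments(system, T298)
    assert np.allclose(mom.dyadic, mom.dyadic.T, rtol=1e-12)
    t = mom.tetradic
    import itertools
    avg = np.zeros_like(t)
    for p in itertools.permutations(range(4)):
        avg += np.transpose(t, p)
    avg /= 24.0
    assert np.max(np.abs(t - avg)) < 1e-10 * np.max(np.abs(t))


def test_moments_reassemble_tensors(ni_like):
    """Contracting dyadic/tetradic with the Zeeman and FC coefficient
    matrices reproduces the directly computed F_BB, F_MB and F_MBBB."""
    system, nuclei = ni_like
    nuc = nuclei[0]
    mom = spin_moments(system, T298)
    coeff_m = (nuc.A_iso_au / nuc.gamma_au) * np.eye(3)
    coeff_b = const.MU_BOHR_AU * system.g
    f_mb, f_bb, f_mbbb = contract_moments(mom, coeff_m, coeff_b)
    fc = fc_operator(system, nuc)
    assert np.allclose(f_bb, sos_free_energy_derivatives(system, T=T298, order=2),
                       rtol=1e-8)
    assert np.allclose(f_mb, sos_free_energy_derivatives(system, fc, T=T298, order=2),
                       rtol=1e-8)
    assert np.allclose(f_mbbb, sos_free_energy_derivatives(system, fc, T=T298, order=4),
                       rtol=1e-8)


# ---------------------------------------------------------------------------
# tensor properties
# ---------------------------------------------------------------------------

def test_response_tensor_symmetries(ni_like):
    system, nuclei = ni_like
    resp = assemble_response(system, nuclei[0], T298)
    assert np.allclose(resp.chi_au, resp.chi_au.T, rtol=1e-10)
    t = resp.tau4
    for p in ((0, 1, 3, 2), (0, 2, 1, 3), (0, 3, 2, 1)):
        assert np.max(np.abs(t - np.transpose(t, p))) < 1e-10 * np.max(np.abs(t))
    # pairing the M index with any one B index in the (4:2) contraction is
    # equivalent (asserted, not assumed)
    c1 = np.einsum("iijj->", t)
    c2 = np.einsum("ijij->", t)
    c3 = np.einsum("ijji->", t)
    assert c2 == pytest.approx(c1, rel=1e-10)
    assert c3 == pytest.approx(c1, rel=1e-10)


def test_rotation_covariance(ni_like, rotations):
    """sigma and chi rotate as rank-2 tensors, tau4 as rank-4, under a joint
    rotation of g, D and the nuclear position."""
    system, nuclei = ni_like
    nuc = nuclei[1]
    resp = assemble_response(system, nuc, T298)
    for R in rotations:
        sys_r = system.rotated(R)
        nuc_r = type(nuc)(label=nuc.label, position=R @ nuc.position,
                          A_iso_mhz=nuc.A_iso_mhz, gamma_si=nuc.gamma_si)
        resp_r = assemble_response(sys_r, nuc_r, T298)
        assert np.allclose(resp_r.sigma, R @ resp.sigma @ R.T,
                           atol=1e-8 * np.max(np.abs(resp.sigma)))
        assert np.allclose(resp_r.chi_au, R @ resp.chi_au @ R.T,
                           atol=1e-8 * np.max(np.abs(resp.chi_au)))
        t_rot = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, resp.tau4)
        assert np.max(np.abs(resp_r.tau4 - t_rot)) < 1e-8 * np.max(np.abs(resp.tau4))


def test_high_temperature_scaling():
    """For ZFS << kT, chi ~ 1/T and tau4 ~ 1/T^3 (log-log slopes -1, -3)."""
    sys_ = SpinSystem(S=1.0, g=np.diag([2.1, 2.15, 2.25]), D_cm1=zfs_tensor(3.0, 0.5))
    nuc = Nucleus.from_isotope("H", [0, 0, 3.0], A_iso_mhz=0.5)
    fc = fc_operator(sys_, nuc)
    temps = np.array([500.0, 1000.0, 2000.0, 5000.0])
    chi_norm, tau_norm = [], []
    for T in temps:
        chi_norm.append(np.linalg.norm(sos_free_energy_derivatives(sys_, T=T, order=2)))
        tau_norm.append(np.linalg.norm(sos_free_energy_derivatives(sys_, fc, T=T, order=4)))
    s_chi = np.polyfit(np.log(temps), np.log(chi_norm), 1)[0]
    s_tau = np.polyfit(np.log(temps), np.log(tau_norm), 1)[0]
    assert s_chi == pytest.approx(-1.0, abs=0.02)
    assert s_tau == pytest.approx(-3.0, abs=0.02)


def test_pc_sigma_traceless_for_isotropic_response():
    """Isotropic g, no ZFS: the isotropic average of the PC shielding
    vanishes (the traceless dipolar geometry meets an isotropic chi)."""
    sys_ = SpinSystem(S=1.0, g=2.15 * np.eye(3))
    nuc = Nucleus.from_isotope("H", [2.0, -1.0, 1.5])
    resp = assemble_response(sys_, nuc, T298, kinds=("PC",))
    assert abs(np.trace(resp.sigma)) < 1e-10 * max(np.max(np.abs(resp.sigma)), 1e-30)


def test_numeric_flags_nonconvergence():
    """A deliberately crude extrapolation (2 levels) reports its error honestly."""
    sys_ = SpinSystem(S=1.0, g=np.diag([2.1, 2.2, 2.3]), D_cm1=zfs_tensor(8.0, 1.0))
    nuc = Nucleus.from_isotope("H", [0, 0, 3.0], A_iso_mhz=0.5)
    nd = numeric_free_energy_derivatives(sys_, fc_operator(sys_, nuc), T=T298,
                                         order=4, levels=2, rtol=1e-12)
    assert not nd.converged
    assert nd.error > 1e-12
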