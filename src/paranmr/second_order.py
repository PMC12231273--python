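"""Second-order field-dependent shift assembled from response tensors.

With the orientational average done analytically, the solution shift of a
nucleus is, through second order in the external field,

    delta(B0) = -sigma^(2:1)/3
                + [ (beta/(45 mu0)) sigma^(2:1) chi^(2:1)
                  - (beta/(15 mu0)) (sigma chi)^(2:1)
                  - tau ] B0^2

The two chi-containing terms are the "indirect" contribution (incomplete
rotational averaging of an anisotropic shielding against an anisotropic
susceptibility — residual chemical shift anisotropy); the tau term is the
"direct" contribution (intrinsic nonlinear / saturation response).  For
isotropic sigma and chi the indirect term cancels exactly.  Internally the
chi terms are contracted as beta * sigma * F_BB with the raw free-energy
derivative F_BB = -chi/mu0, so no mu0 round trip occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as const
from .response import ResponseTensors

__all__ = ["SecondOrderShift", "trace_contraction", "second_order_shift",
           "shift_at_fields"]

#: a.u. field -> tesla^2 conversion for the B0^2 coefficients
_PPM = 1e6
_PER_T2 = const.AU_B_PER_TESLA**2


def trace_contraction(tensor, spec: str) -> float:
    """Tensor trace contractions: "(2:1)" = sum_i t_ii for a 3x3 tensor,
    "(4:2)" = sum_ij t_iijj for a rank-4 tensor, "product" = sum_ij a_ij b_ji
    for a pair (a, b)."""
    if spec == "(2:1)":
        t = np.asarray(tensor)
        if t.shape != (3, 3):
            raise ValueError(f"(2:1) trace needs a 3x3 tensor, got shape {t.shape}")
        return float(np.trace(t))
    if spec == "(4:2)":
        t = np.asarray(tensor)
        if t.shape != (3, 3, 3, 3):
            raise ValueError(f"(4:2) trace needs a rank-4 tensor, got shape {t.shape}")
        return float(np.einsum("iijj->", t))
    if spec == "product":
        a, b = (np.asarray(x) for x in tensor)
        if a.shape != (3, 3) or b.shape != (3, 3):
            raise ValueError("product trace needs two 3x3 tensors")
        return float(np.einsum("ij,ji->", a, b))
    raise ValueError(f"unknown contraction spec {spec!r}")


@dataclass(frozen=True)
class SecondOrderShift:
    """Field-independent shift and B0^2 coefficients for one nucleus.

    delta0 in ppm; c_indirect and c_direct in ppm/T^2; ``parts`` holds the
    FC/PC decomposition (each kind again a dict delta0/c_indirect/c_direct).
    """

    delta0: float
    c_indirect: float
    c_direct: float
    T: float
    parts: dict = field(default_factory=dict)

    @property
    def c_total(self) -> float:
        return self.c_indirect + self.c_direct


def _coefficients(sigma: np.ndarray, f_bb: np.ndarray, tau: float,
                  beta: float) -> tuple[float, float, float]:
    delta0 = -trace_contraction(sigma, "(2:1)") / 3.0 * _PPM
    c_ind_au = (-beta / 45.0 * trace_contraction(sigma, "(2:1)")
                * trace_contraction(f_bb, "(2:1)")
                + beta / 15.0 * trace_contraction((sigma, f_bb), "product"))
    c_ind = c_ind_au * _PPM * _PER_T2
    c_dir = -tau * _PPM * _PER_T2
    return delta0, c_ind, c_dir


def second_order_shift(resp: ResponseTensors, T: float) -> SecondOrderShift:
    """Assemble the second-order shift from response tensors computed at the
    same temperature (a mismatch is an error, not a silent re-scale)."""
    if abs(T - resp.T) > 1e-9 * max(T, resp.T):
        raise ValueError(f"temperature mismatch: tensors at {resp.T} K, requested {T} K")
    beta = 1.0 / (const.KBOLTZ_AU * T)
    delta0, c_ind, c_dir = _coefficients(resp.sigma, resp.f_bb, resp.tau, beta)
    parts = {}
    for kind, p in resp.parts.items():
        d0_k, ci_k, cd_k = _coefficients(p["sigma"], resp.f_bb, p["tau"], beta)
        parts[kind] = {"delta0": d0_k, "c_indirect": ci_k, "c_direct": cd_k}
    return SecondOrderShift(delta0=delta0, c_indirect=c_ind, c_direct=c_dir,
                            T=T, parts=parts)


def shift_at_fields(so: SecondOrderShift, fields_tesla) -> np.ndarray:
    """delta(B0) = delta0 + (c_indirect + c_direct) B0^2, in ppm."""
    b = np.asarray(fields_tesla, dtype=float)
    if np.any(b < 0):
        raise ValueError("fields must be >= 0")
    return so.delta0 + so.c_total * b**2
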