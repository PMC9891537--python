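"""Closed-form and numeric steady states of the single-cell models.

The mutual-inactivation model and the monomer-trans/dimer-cis model both
admit closed-form steady states: each reduces to a quadratic whose unique
non-negative root is the physical state.  The quadratics use the effective
degradation rates

    beta1 = beta + k_t * N_ext        (ligand monomer, trans drain added)
    beta2 = beta + k_t * L_ext        (receptor, trans drain added)

A numeric fixed-point solver (long integration followed by damped
root-finding) serves as the independent check for every closed form and as
the only route to steady states of variants without one (cis-activation,
oligomer, compartmental).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .models import (
    CellState,
    ExternalSignal,
    ModelParameters,
    ValidationError,
    mi_rhs,
    t1_rhs,
)

__all__ = [
    "EffectiveRates",
    "SteadyStateError",
    "mi_steady_state",
    "mi_asymptotic",
    "t1_steady_state",
    "t1_receptor_limit",
    "numeric_fixed_point",
]


class SteadyStateError(RuntimeError):
    """Raised when a steady state cannot be computed; carries diagnostics."""

    def __init__(self, msg: str, state=None, residual=None):
        super().__init__(msg)
        self.state = state
        self.residual = residual


@dataclass(frozen=True)
class EffectiveRates:
    """Trans-augmented degradation rates beta1, beta2 (1/hour)."""

    beta1: float
    beta2: float

    @classmethod
    def from_params(cls, p: ModelParameters, ext: ExternalSignal) -> "EffectiveRates":
        k_t = p.k1
        return cls(beta1=p.beta + k_t * ext.N_ext, beta2=p.beta + k_t * ext.L_ext)


def _positive_quadratic_root(half_sum: float, product_term: float) -> float:
    """Root x = h + sqrt(h^2 + q) of x^2 - 2hx - q = 0 with q >= 0.

    This is the '+' branch; the '-' branch is <= 0 whenever q >= 0, so the
    returned root is the unique non-negative one.
    """
    x = half_sum + math.sqrt(half_sum * half_sum + product_term)
    assert x >= 0.0
    return x


def mi_steady_state(p: ModelParameters, ext: ExternalSignal = ExternalSignal()) -> tuple[float, float, float]:
    """Closed-form steady state (L, N, S) of the mutual-inactivation model.

    L solves a quadratic obtained by eliminating N from the paired balance
    equations; N follows from the summed balance
    beta1*L - beta2*N = b_L - b_N, and S = k_t * N * L_ext / beta_S.
    Requires k_ci > 0 (with k_ci = 0 the model is linear and has the trivial
    uncoupled solution, which this routine refuses to silently return).
    """
    k_t, k_ci = p.k1, p.k3
    if k_ci <= 0:
        raise ValidationError(
            "mi_steady_state requires k_ci > 0; with k_ci = 0 use the linear "
            "solution L = b_L/beta1, N = b_N/beta2 directly"
        )
    eff = EffectiveRates.from_params(p, ext)
    b1, b2 = eff.beta1, eff.beta2
    h = (p.b_L - p.b_N) / (2.0 * b1) - b2 / (2.0 * k_ci)
    L = _positive_quadratic_root(h, b2 * p.b_L / (b1 * k_ci))
    N = (b1 * L - (p.b_L - p.b_N)) / b2
    S = k_t * N * ext.L_ext / p.beta_S
    return L, N, S


def mi_asymptotic(p: ModelParameters, ext: ExternalSignal = ExternalSignal()):
    """High-affinity (k_ci -> inf) limit of the mutual-inactivation model.

    Returns ``(label, (L, N))`` where the label is ``"sender"`` (ligand
    production wins: high L, N ~ 0) or ``"receiver"`` (receptor production
    wins).  With b_L == b_N the limit is degenerate and no approximation is
    returned.
    """
    eff = EffectiveRates.from_params(p, ext)
    if p.b_L > p.b_N:
        return "sender", ((p.b_L - p.b_N) / eff.beta1, 0.0)
    if p.b_L < p.b_N:
        return "receiver", (0.0, (p.b_N - p.b_L) / eff.beta2)
    return "degenerate", None


def t1_steady_state(p: ModelParameters, ext: ExternalSignal = ExternalSignal()) -> tuple[float, float, float, float]:
    """Closed-form steady state (L, Lstar, N, S) of the dimer-cis model.

    The monomer equation decouples (it does not involve N or Lstar), giving
    L from a quadratic in beta1 and k_d alone — notably independent of b_N.
    Dimer production k_d*L^2 then plays the role of an effective ligand
    source in a mutual-inactivation-like quadratic for Lstar, and N follows
    from the summed balance beta*Lstar - beta2*N = k_d*L^2 - b_N.
    """
    k_t, k_ci = p.k1, p.k4
    if p.k_d <= 0:
        raise ValidationError(
            "t1_steady_state requires k_d > 0; without dimerization use mi_steady_state"
        )
    if k_ci <= 0:
        raise ValidationError("t1_steady_state requires k_ci > 0")
    eff = EffectiveRates.from_params(p, ext)
    b1, b2 = eff.beta1, eff.beta2
    q = b1 / (4.0 * p.k_d)
    L = math.sqrt(q * q + p.b_L / (2.0 * p.k_d)) - q
    dimer_src = p.k_d * L * L
    A = (dimer_src - p.b_N) / (2.0 * p.beta) - b2 / (2.0 * k_ci)
    Lstar = _positive_quadratic_root(A, b2 * dimer_src / (p.beta * k_ci))
    N = (p.beta * Lstar - (dimer_src - p.b_N)) / b2
    S = k_t * ext.L_ext * N / p.beta_S
    return L, Lstar, N, S


def t1_receptor_limit(p: ModelParameters, ext: ExternalSignal = ExternalSignal()) -> float:
    """High-affinity receptor level of the dimer-cis model.

    When dimer influx k_d*L^2 exceeds receptor production b_N the receptor
    is titrated away (N ~ 0); otherwise the surplus (b_N - k_d*L^2) survives
    at effective degradation beta2.  L is the closed-form monomer level,
    which does not depend on b_N.
    """
    eff = EffectiveRates.from_params(p, ext)
    q = eff.beta1 / (4.0 * p.k_d) if p.k_d > 0 else None
    if q is None:
        return p.b_N / eff.beta2
    L = math.sqrt(q * q + p.b_L / (2.0 * p.k_d)) - q
    dimer_src = p.k_d * L * L
    if p.b_N < dimer_src:
        return 0.0
    return (p.b_N - dimer_src) / eff.beta2


def numeric_fixed_point(
    rhs: Callable,
    p: ModelParameters,
    ext: ExternalSignal = ExternalSignal(),
    init: Sequence[float] | None = None,
    *,
    ndim: int | None = None,
    t_max: float = 1e5,
    window: float = 10.0,
    rel_tol: float = 1e-8,
    scale: float | None = None,
) -> np.ndarray:
    """Steady state of any model RHS by integration plus root refinement.

    Integrates from ``init`` (zero state by default) until the maximum
    relative state change over a trailing ``window`` hours drops below
    ``rel_tol``, then polishes with damped root-finding from the endpoint.
    The returned state has residual below 1e-8 * max(b_L, b_N, 1).

    ``rhs`` is called as ``rhs(state, ext, p)``; pass ``ndim`` when ``init``
    is omitted and the state dimension cannot be probed from a 4-vector.
    """
    if init is None:
        if ndim is None:
            for ndim_try in (4, 3, 6):
                try:
                    rhs(np.zeros(ndim_try), ext, p)
                    ndim = ndim_try
                    break
                except Exception:
                    continue
            if ndim is None:
                raise ValidationError("could not infer state dimension; pass init or ndim")
        init = np.zeros(ndim)
    y0 = np.asarray(init, dtype=float)

    def f(t, y):
        return rhs(np.maximum(y, 0.0), ext, p)

    if scale is None:
        scale = max(p.b_L, p.b_N, 1.0)
    res_tol = 1e-8 * scale
    t, y = 0.0, y0
    chunk = max(window * 10.0, 100.0)
    converged = False
    while t < t_max:
        t_end = min(t + chunk, t_max)
        sol = solve_ivp(f, (t, t_end), y, method="LSODA", rtol=1e-10, atol=1e-10 * scale,
                        t_eval=np.linspace(t, t_end, 21))
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}", state=y)
        ys = sol.y
        t, y = t_end, ys[:, -1]
        # trailing-window relative change
        i0 = np.searchsorted(sol.t, t_end - window)
        seg = ys[:, max(i0 - 1, 0):]
        denom = np.maximum(np.abs(y), 1e-12 * scale)
        delta = np.max(np.abs(seg - y[:, None]) / denom[:, None])
        if delta < rel_tol:
            converged = True
            break
    residual = float(np.max(np.abs(rhs(np.maximum(y, 0.0), ext, p))))
    if not converged and residual > res_tol:
        raise SteadyStateError(
            f"no steady state within t_max={t_max} h (residual {residual:.3e})",
            state=y, residual=residual,
        )
    # polish: damped Newton via scipy root from the integration endpoint.
    # The raw (unclipped) RHS is smooth, which hybr's Jacobian needs; the
    # result is clipped afterwards and re-checked.
    def g(z):
        try:
            return rhs(np.abs(z), ext, p)
        except Exception:
            return np.full_like(z, np.inf)

    sol_root = root(g, y, method="hybr", tol=1e-13)
    # judge the candidate by its measured residual, not the solver's
    # progress flag (MINPACK can flag lack of progress at convergence)
    y_ref = np.abs(sol_root.x)
    res_ref = float(np.max(np.abs(rhs(y_ref, ext, p))))
    if np.all(np.isfinite(y_ref)) and res_ref <= residual:
        y, residual = y_ref, res_ref
    if residual > res_tol:
        raise SteadyStateError(
            f"fixed point residual {residual:.3e} exceeds tolerance {res_tol:.3e}",
            state=y, residual=residual,
        )
    return np.maximum(y, 0.0)
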