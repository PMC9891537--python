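"""Time integration, dose-response sweeps and coupled-cell systems.

"Notch activity" throughout means the steady-state level of free Notch
intracellular domain S — the only productive output in every model variant.

Sweeps come in two experimental geometries:

* *cis* sweeps: a receiving cell exposed to a fixed bath of trans ligand
  (default 1500 molecules of monomer) while its own ligand production or
  dimerization rate varies;
* *trans* sweeps: a sending cell whose ligand production (or dimerization)
  varies, coupled to a receiving cell; the trans input of each cell is the
  ligand level of the other, solved to joint steady state.

Cis-activation rates are zeroed whenever external trans ligand is present;
cis-activation is only simulated for isolated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    CellState,
    ExternalSignal,
    ModelParameters,
    ValidationError,
    cis_activation_rhs,
    compartment_rhs,
    general_rhs,
    oligomer_rhs,
    t1_rhs,
)
from .steady_state import SteadyStateError, numeric_fixed_point

__all__ = [
    "Trajectory",
    "SweepResult",
    "integrate",
    "production_sweep",
    "dimerization_sweep",
    "two_cell_steady_state",
    "two_cell_production_sweep",
    "cis_activation_run",
    "ligand_pulse_dynamics",
    "normalize_activity",
    "oligomer_sweep",
    "compartment_sweep",
    "interior_peak",
]

#: default bath level of trans-presented ligand monomer for cis sweeps
L_EXT_DEFAULT = 1500.0


@dataclass
class Trajectory:
    """Time course of one cell (or one coupled system)."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_vars)
    model: str = ""
    params: ModelParameters | None = None
    columns: tuple[str, ...] = ("L", "Lstar", "N", "S")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) < 0):
            raise ValidationError("trajectory times must be 1-D and non-decreasing")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValidationError("states and times length mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class SweepResult:
    """Steady-state dose-response curve over a parameter grid."""

    param: str
    values: np.ndarray
    activity: np.ndarray          # steady-state S per grid point
    states: np.ndarray | None = None
    normalized: bool = False
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.values.shape != self.activity.shape:
            raise ValidationError("sweep grid and outputs length mismatch")

    def normalize(self) -> "SweepResult":
        return SweepResult(self.param, self.values, normalize_activity(self.activity),
                           states=self.states, normalized=True, label=self.label)


def normalize_activity(values) -> np.ndarray:
    """Scale a set of activity values so the maximum is 1."""
    arr = np.asarray(values, dtype=float)
    m = arr.max() if arr.size else 0.0
    if arr.size == 0 or m <= 0:
        raise ValidationError("normalization undefined: no positive activity value")
    return arr / m


def interior_peak(values) -> bool:
    """True if the discrete argmax sits strictly inside the grid."""
    arr = np.asarray(values, dtype=float)
    i = int(np.argmax(arr))
    return 0 < i < arr.size - 1


def integrate(
    rhs: Callable,
    init: Sequence[float],
    ext: ExternalSignal,
    p: ModelParameters,
    t_span: tuple[float, float],
    output_grid: Sequence[float] | None = None,
    *,
    model: str = "",
    columns: tuple[str, ...] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Adaptive explicit Runge-Kutta integration of one cell.

    ``rhs(state, ext, p)`` is integrated over ``t_span`` and sampled on
    ``output_grid`` (200 even points by default) through dense output.
    States that dip below ``-atol`` abort with an error; smaller negative
    round-off is clipped to zero.
    """
    y0 = np.asarray(init, dtype=float)
    if np.any(y0 < 0):
        raise ValidationError("initial state must be non-negative")
    t0, t1 = map(float, t_span)
    if not (np.isfinite(t0) and np.isfinite(t1)) or t1 < t0:
        raise ValidationError(f"invalid t_span {t_span!r}")
    if t1 == t0:
        cols = columns or ("L", "Lstar", "N", "S")[: y0.size] if y0.size <= 4 else None
        return Trajectory(np.array([t0]), y0[None, :], model=model, params=p,
                          columns=cols or tuple(f"x{i}" for i in range(y0.size)))

    def f(t, y):
        return rhs(np.maximum(y, 0.0), ext, p)

    grid = np.asarray(output_grid, dtype=float) if output_grid is not None \
        else np.linspace(t0, t1, 200)
    sol = solve_ivp(f, (t0, t1), y0, method="RK45", rtol=rtol, atol=atol,
                    t_eval=grid, dense_output=False)
    if not sol.success:
        raise SteadyStateError(f"integration failed: {sol.message}", state=sol.y[:, -1] if sol.y.size else y0)
    states = sol.y.T
    floor = states.min()
    if floor < -100 * atol * max(1.0, p.b_L, p.b_N):
        raise SteadyStateError(f"negative excursion {floor:.3e} during integration", state=states[-1])
    states = np.maximum(states, 0.0)
    if columns is None:
        columns = {3: ("L", "N", "S"), 4: ("L", "Lstar", "N", "S"),
                   6: ("L_c", "Lstar", "N_c", "L_m", "N_m", "S")}.get(
            y0.size, tuple(f"x{i}" for i in range(y0.size)))
    return Trajectory(sol.t, states, model=model, params=p, columns=columns)


# ---------------------------------------------------------------------------
# coupled two-cell system


def _coupled_rhs(rhs, p_a: ModelParameters, p_b: ModelParameters,
                 ext_index: tuple[int, int, int]):
    """RHS of two cells where each cell's trans input is the other's state.

    ``ext_index`` gives the state indices supplying (L_ext, Lstar_ext,
    N_ext) — (0, 1, 2) for whole-cell models, (3, 1, 4) to use membrane
    pools of the compartmental model.
    """
    iL, iLs, iN = ext_index

    def f(y, _ext_unused, _p_unused):
        n = y.size // 2
        a, b = y[:n], y[n:]
        ext_a = ExternalSignal(b[iL], b[iLs], b[iN])
        ext_b = ExternalSignal(a[iL], a[iLs], a[iN])
        return np.concatenate([rhs(a, ext_a, p_a), rhs(b, ext_b, p_b)])

    return f


def _coupled_steady(rhs, p_a, p_b, ndim_cell=4, ext_index=(0, 1, 2)):
    f = _coupled_rhs(rhs, p_a, p_b, ext_index)
    scale = max(p_a.b_L, p_a.b_N, p_b.b_L, p_b.b_N, 1.0)
    y = numeric_fixed_point(f, p_a, ExternalSignal(), init=np.zeros(2 * ndim_cell),
                            scale=scale)
    return y[:ndim_cell], y[ndim_cell:]


def two_cell_steady_state(config: str, p: ModelParameters | None = None,
                          b_L: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Joint steady state of two identical coupled cells.

    ``config`` is a trans-activation variant (T1/T2/T3).  Each cell's trans
    ligand input is the other cell's (monomer, dimer) level — with a single
    neighbour the neighbourhood average is just that neighbour — and its
    N_ext the other's receptor.  Identical cells started identically stay
    identical, so both returned states coincide.
    """
    if p is None:
        p = ModelParameters.trans_config(config)
    if b_L is not None:
        p = p.with_(b_L=b_L)
    return _coupled_steady(general_rhs, p, p)


def two_cell_production_sweep(config: str, b_L_grid, p: ModelParameters | None = None,
                              normalized: bool = True) -> SweepResult:
    """Steady-state activity of two identical cells vs their shared ligand
    production rate, normalized to the curve maximum by default."""
    grid = np.asarray(b_L_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValidationError("b_L grid must be non-empty and non-negative")
    out = np.empty(grid.size)
    for i, b in enumerate(grid):
        a, _ = two_cell_steady_state(config, p=p, b_L=float(b))
        out[i] = a[3]
    res = SweepResult("b_L", grid, out, label=f"two-cell {config}")
    return res.normalize() if normalized else res


# ---------------------------------------------------------------------------
# single-cell sweeps (fixed trans bath)

_CIS_CONFIGS = ("C1", "C2", "C3")
_TRANS_CONFIGS = ("T1", "T2", "T3")


def _receiving_params(model_config: str, **kw) -> ModelParameters:
    mc = model_config.upper()
    if mc in _CIS_CONFIGS:
        return ModelParameters.cis_config(mc, **kw)
    if mc in _TRANS_CONFIGS:
        return ModelParameters.trans_config(mc, **kw)
    raise ValidationError(f"unknown model config {model_config!r}")


def _bath_steady_S(p: ModelParameters, ext: ExternalSignal) -> float:
    y = numeric_fixed_point(general_rhs, p, ext, init=np.zeros(4))
    return float(y[3])


def _sender_receiver_steady_S(p_send: ModelParameters, p_recv: ModelParameters) -> float:
    _, recv = _coupled_steady(general_rhs, p_send, p_recv)
    return float(recv[3])


def production_sweep(model_config: str, b_L_grid, ext: ExternalSignal | None = None,
                     p: ModelParameters | None = None) -> SweepResult:
    """Steady-state Notch activity vs ligand production rate.

    For cis configurations (C1/C2/C3) the swept ``b_L`` is the receiving
    cell's own ligand production, with a fixed trans bath (default
    L_ext = 1500).  For trans configurations (T1/T2/T3) the swept ``b_L``
    belongs to a sending cell coupled to the receiving cell; the sender's
    steady ligand levels (solved jointly) are the receiver's trans input.
    """
    grid = np.asarray(b_L_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValidationError("b_L grid must be non-empty and non-negative")
    mc = model_config.upper()
    base = p if p is not None else _receiving_params(mc)
    out = np.empty(grid.size)
    if mc in _CIS_CONFIGS:
        bath = ext if ext is not None else ExternalSignal(L_ext=L_EXT_DEFAULT)
        for i, b in enumerate(grid):
            out[i] = _bath_steady_S(base.with_(b_L=float(b)), bath)
    else:
        p_recv = base
        # pure sender: expresses ligand, no receptor production by default
        p_send = base.with_(b_N=0.0)
        for i, b in enumerate(grid):
            out[i] = _sender_receiver_steady_S(p_send.with_(b_L=float(b)), p_recv)
    return SweepResult("b_L", grid, out, label=mc)


def dimerization_sweep(model_config: str, k_d_grid, fixed_b_L: float,
                       ext: ExternalSignal | None = None,
                       p: ModelParameters | None = None) -> SweepResult:
    """Steady-state Notch activity vs ligand dimerization rate at high
    ligand production (the top of the companion production sweep).

    Cis configurations vary the receiving cell's own k_d; trans
    configurations vary the sending cell's k_d.
    """
    grid = np.asarray(k_d_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValidationError("k_d grid must be non-empty and non-negative")
    mc = model_config.upper()
    base = p if p is not None else _receiving_params(mc)
    out = np.empty(grid.size)
    if mc in _CIS_CONFIGS:
        bath = ext if ext is not None else ExternalSignal(L_ext=L_EXT_DEFAULT)
        for i, kd in enumerate(grid):
            out[i] = _bath_steady_S(base.with_(b_L=float(fixed_b_L), k_d=float(kd)), bath)
    else:
        p_recv = base
        for i, kd in enumerate(grid):
            p_send = base.with_(b_N=0.0, b_L=float(fixed_b_L), k_d=float(kd))
            out[i] = _sender_receiver_steady_S(p_send, p_recv)
    return SweepResult("k_d", grid, out, label=mc)


# ---------------------------------------------------------------------------
# cis-activation (isolated cell)


def _isolated_rhs(state, _ext, p):
    return cis_activation_rhs(state, p)


def cis_activation_run(scenario: int, b_L_grid, p: ModelParameters | None = None,
                       k_ca: float | None = None, k_d: float | None = None,
                       k_ci: float | None = None) -> SweepResult:
    """Steady-state Notch activity of an isolated cell vs its own ligand
    production, under one of the three cis-activation scenarios.

    The cell has no contacts (all trans inputs zero).  ``k_ca``, ``k_d`` and
    ``k_ci`` override the baseline rates to reproduce rate-titration
    experiments.
    """
    grid = np.asarray(b_L_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValidationError("b_L grid must be non-empty and non-negative")
    if p is None:
        p = ModelParameters.cis_activation(scenario,
                                           k_ca=k_ca if k_ca is not None else ModelParameters.K_CA,
                                           k_ci=k_ci if k_ci is not None else ModelParameters.K_CI)
    else:
        p = ModelParameters.cis_activation(scenario,
                                           k_ca=k_ca if k_ca is not None else (p.k5 or p.k6 or ModelParameters.K_CA),
                                           k_ci=k_ci if k_ci is not None else p.k4,
                                           b_L=p.b_L, b_N=p.b_N, k_d=p.k_d,
                                           beta=p.beta, beta_S=p.beta_S)
    if k_d is not None:
        p = p.with_(k_d=float(k_d))
    out = np.empty(grid.size)
    for i, b in enumerate(grid):
        y = numeric_fixed_point(_isolated_rhs, p.with_(b_L=float(b)), ExternalSignal(), init=np.zeros(4))
        out[i] = y[3]
    return SweepResult("b_L", grid, out, label=f"cis-activation scenario {scenario}")


# ---------------------------------------------------------------------------
# pulse-chase dynamics and oligomer/compartment comparisons


def ligand_pulse_dynamics(p: ModelParameters | None = None, *,
                          L_ext: float = L_EXT_DEFAULT,
                          init: Sequence[float] = (500.0, 9500.0, 0.0, 0.0),
                          t_span: tuple[float, float] = (0.0, 100.0),
                          output_grid=None) -> Trajectory:
    """Relaxation of a cell pre-loaded with ligand, under a fixed trans bath.

    Ligand production is off (b_L = 0) and the initial state carries a large
    ligand store, mostly as dimers (500 monomers, 9500 dimers, no receptor,
    no signal).  Receptor produced de novo is first titrated by the dimer
    pool, so activity S rises only after the dimers decay — a delayed-onset
    trans-activation time course.
    """
    if p is None:
        p = ModelParameters.t1()
    p = p.with_(b_L=0.0)
    ext = ExternalSignal(L_ext=L_ext)
    return integrate(t1_rhs, init, ext, p, t_span, output_grid, model="T1 pulse")


def _setting_runner(setting: str, rhs, p: ModelParameters, ndim: int, ext_index):
    """Return a callable b_L -> steady-state S for one experimental setting."""
    if setting == "fixed-trans":
        bath = ExternalSignal(L_ext=L_EXT_DEFAULT)
        pp = p.with_(k5=0.0, k6=0.0)  # no cis-activation in presence of trans ligand

        def run(b):
            y = numeric_fixed_point(rhs, pp.with_(b_L=float(b)), bath, init=np.zeros(ndim))
            return float(y[-1])
    elif setting == "two-cell":
        pp = p.with_(k5=0.0, k6=0.0)

        def run(b):
            pb = pp.with_(b_L=float(b))
            a, _ = _coupled_steady(rhs, pb, pb, ndim_cell=ndim, ext_index=ext_index)
            return float(a[-1])
    elif setting == "single-cell":
        def run(b):
            y = numeric_fixed_point(rhs, p.with_(b_L=float(b)), ExternalSignal(), init=np.zeros(ndim))
            return float(y[-1])
    else:
        raise ValidationError(f"unknown setting {setting!r}; expected fixed-trans/two-cell/single-cell")
    return run


def oligomer_sweep(setting: str, n: int, b_L_grid, p: ModelParameters | None = None,
                   normalized: bool = True) -> SweepResult:
    """Activity vs ligand production for oligomer size n in one setting.

    Settings: a cell in a fixed trans bath, two identical coupled cells, or
    a single isolated cell (where monomer cis-activation at k_ca provides
    the only signal source).
    """
    grid = np.asarray(b_L_grid, dtype=float)
    if p is None:
        p = ModelParameters(k1=ModelParameters.K_T, k4=ModelParameters.K_CI,
                            k5=ModelParameters.K_CA, n=int(n))
    else:
        p = p.with_(n=int(n))
    run = _setting_runner(setting, oligomer_rhs, p, 4, (0, 1, 2))
    out = np.array([run(b) for b in grid])
    res = SweepResult("b_L", grid, out, label=f"n={n} {setting}")
    return res.normalize() if normalized else res


def compartment_sweep(setting: str, localization: str, b_L_grid,
                      p: ModelParameters | None = None,
                      normalized: bool = True) -> SweepResult:
    """Activity vs ligand production, comparing cis-inhibition localizations.

    ``localization='homogeneous'`` uses the whole-cell dimer model (with
    monomer cis-activation at k_ca); ``'cytoplasmic'`` confines
    dimerization and dimer cis-inhibition to the cytoplasm, with transport
    to the membrane at k_r where trans/cis-activation occur.
    """
    grid = np.asarray(b_L_grid, dtype=float)
    if p is None:
        p = ModelParameters(k1=ModelParameters.K_T, k4=ModelParameters.K_CI,
                            k5=ModelParameters.K_CA)
    if localization == "homogeneous":
        run = _setting_runner(setting, oligomer_rhs, p.with_(n=2), 4, (0, 1, 2))
    elif localization == "cytoplasmic":
        run = _setting_runner(setting, compartment_rhs, p, 6, (3, 1, 4))
    else:
        raise ValidationError(f"unknown localization {localization!r}")
    out = np.array([run(b) for b in grid])
    res = SweepResult("b_L", grid, out, label=f"{localization} {setting}")
    return res.normalize() if normalized else res
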