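"""Local parameter sensitivity of steady-state Notch activity.

Three experimental settings are scanned, matching the single-cell and
coupled-cell simulation geometries elsewhere in the package:

* ``fixed-trans``  — one cell in a fixed bath of trans ligand monomer
  (1500 molecules), monomer trans-activation + dimer cis-inhibition;
* ``two-cell``     — two identical coupled cells, same kinetics;
* ``single-cell``  — an isolated cell with monomer cis-activation and
  dimer cis-inhibition (no trans input at all).

For each parameter, steady-state activity S is recomputed one-at-a-time
over a fold-change grid (all other parameters at baseline).  The summary
index is the absolute log-log derivative |d log S / d log theta| estimated
by central difference at fold 1 (factor 1.05 up and down).  The index is
dimensionless and invariant to rescaling of S; a parameter that the
setting's dynamics never touch (e.g. the trans-activation rate in the
isolated cell) scores exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ExternalSignal, ModelParameters, ValidationError, cis_activation_rhs, t1_rhs
from .steady_state import numeric_fixed_point
from .engine import L_EXT_DEFAULT, _coupled_steady

__all__ = ["SensitivityReport", "sensitivity_scan", "DEFAULT_FOLDS", "SETTINGS", "PARAMETERS"]

DEFAULT_FOLDS = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
SETTINGS = ("fixed-trans", "two-cell", "single-cell")
#: parameter name -> ModelParameters field
PARAMETERS = {
    "b_L": "b_L", "b_N": "b_N", "k_d": "k_d",
    "k_t": "k1", "k_ci": "k4", "k_ca": "k5",
    "beta": "beta", "beta_S": "beta_S",
}

_DIFF_FACTOR = 1.05  # central-difference factor for the index at fold 1


def _baseline_params() -> ModelParameters:
    return ModelParameters(k1=ModelParameters.K_T, k4=ModelParameters.K_CI,
                           k5=ModelParameters.K_CA)


def _steady_S(setting: str, p: ModelParameters) -> float:
    if setting == "fixed-trans":
        y = numeric_fixed_point(t1_rhs, p, ExternalSignal(L_ext=L_EXT_DEFAULT), init=np.zeros(4))
        return float(y[3])
    if setting == "two-cell":
        a, _ = _coupled_steady(t1_rhs, p, p)
        return float(a[3])
    if setting == "single-cell":
        def rhs(state, _ext, pp):
            return cis_activation_rhs(state, pp)
        y = numeric_fixed_point(rhs, p, ExternalSignal(), init=np.zeros(4))
        return float(y[3])
    raise ValidationError(f"unknown setting {setting!r}; expected one of {SETTINGS}")


@dataclass
class SensitivityReport:
    """Long-format scan table plus summary indices.

    ``table`` columns: setting, parameter, fold, S.  ``indices`` maps
    (setting, parameter) to |d log S / d log theta| at baseline, or None
    when baseline S is 0 there (index undefined).
    """

    table: pd.DataFrame
    indices: dict[tuple[str, str], float | None]
    baseline: dict[str, float]

    def index_frame(self) -> pd.DataFrame:
        rows = [{"setting": s, "parameter": q, "index": v}
                for (s, q), v in self.indices.items()]
        return pd.DataFrame(rows)


def sensitivity_scan(settings=SETTINGS, parameters=None, fold_grid=DEFAULT_FOLDS,
                     p: ModelParameters | None = None) -> SensitivityReport:
    """One-at-a-time fold-change scan of steady-state activity.

    The fold grid must contain 1 (the baseline); the returned table's
    fold-1 rows equal the baseline S exactly.
    """
    folds = tuple(float(f) for f in fold_grid)
    if 1.0 not in folds:
        raise ValidationError("fold grid must include the baseline fold 1")
    if any(f <= 0 for f in folds):
        raise ValidationError("fold changes must be > 0")
    names = list(parameters) if parameters is not None else list(PARAMETERS)
    unknown = [q for q in names if q not in PARAMETERS]
    if unknown:
        raise ValidationError(f"unknown parameter(s) {unknown}; known: {list(PARAMETERS)}")
    base = p if p is not None else _baseline_params()

    records = []
    indices: dict[tuple[str, str], float | None] = {}
    baseline_S = {}
    for setting in settings:
        S0 = _steady_S(setting, base)
        baseline_S[setting] = S0
        for q in names:
            fld = PARAMETERS[q]
            theta0 = getattr(base, fld)
            for f in folds:
                S = S0 if f == 1.0 else _steady_S(setting, base.with_(**{fld: theta0 * f}))
                records.append({"setting": setting, "parameter": q, "fold": f, "S": S})
            if S0 <= 0:
                indices[(setting, q)] = None
                continue
            S_hi = _steady_S(setting, base.with_(**{fld: theta0 * _DIFF_FACTOR}))
            S_lo = _steady_S(setting, base.with_(**{fld: theta0 / _DIFF_FACTOR}))
            if S_hi <= 0 or S_lo <= 0:
                indices[(setting, q)] = None
                continue
            d = (math.log(S_hi) - math.log(S_lo)) / (2.0 * math.log(_DIFF_FACTOR))
            # zero-parameter edge: theta0 == 0 means the perturbation is a
            # no-op and the difference is exactly 0
            indices[(setting, q)] = abs(d)
    return SensitivityReport(pd.DataFrame.from_records(records), indices, baseline_S)
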