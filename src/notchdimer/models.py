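"""Model family for Notch receptor/ligand kinetics with ligand oligomerization.

All variants are deterministic mass-action ODE systems over per-cell molecule
counts (continuous, molecules per cell; time in hours).  The general model
tracks four species in a cell:

* ``L``  — Notch ligand monomer,
* ``Lstar`` — ligand dimer (or oligomer of size ``n``),
* ``N``  — Notch receptor,
* ``S``  — free Notch intracellular domain, the model's readout of
  "Notch activity".

Monomers self-associate at rate ``k_d``.  Receptors interact with ligand in
*trans* (ligand on a neighbouring cell: rates ``k1`` for monomers, ``k2`` for
dimers, both productive for S), in *cis* as inhibition (``k3`` monomers,
``k4`` dimers, non-productive) and in *cis* as activation (``k5`` monomers,
``k6`` dimers, productive).  Every named biological scenario — mutual
inactivation, dimer-mediated cis-inhibition, cis-activation scenarios — is a
particular assignment of ``k1..k6``, not a separate code path.  The
constructors on :class:`ModelParameters` encode those assignments.

Rates and states must be non-negative; negative inputs raise
:class:`ValidationError` rather than being clamped, so that integration bugs
surface instead of being masked.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from typing import ClassVar, NamedTuple

import numpy as np

__all__ = [
    "ValidationError",
    "ModelParameters",
    "CellState",
    "CompartmentState",
    "ExternalSignal",
    "general_rhs",
    "mi_rhs",
    "t1_rhs",
    "cis_activation_rhs",
    "oligomer_rhs",
    "compartment_rhs",
]


class ValidationError(ValueError):
    """Raised for negative rates/states or inconsistent model configuration."""


class CellState(NamedTuple):
    """Per-cell molecular species (molecules)."""

    L: float
    Lstar: float
    N: float
    S: float


class CompartmentState(NamedTuple):
    """Cell state split between cytoplasm (``_c``) and membrane (``_m``)."""

    L_c: float
    Lstar: float
    N_c: float
    L_m: float
    N_m: float
    S: float


class ExternalSignal(NamedTuple):
    """Trans-presented species seen by a cell (molecules).

    For a cell in a tissue these are averages over its neighbours; for an
    isolated cell they are experimental bath levels (e.g. plate-bound ligand).
    """

    L_ext: float = 0.0
    Lstar_ext: float = 0.0
    N_ext: float = 0.0


_RATE_FIELDS = (
    "b_L", "b_N", "k_d",
    "k1", "k2", "k3", "k4", "k5", "k6",
    "beta", "beta_S", "k_r",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the model family.

    Parameters
    ----------
    b_L, b_N
        Production rates of ligand and receptor (molecules/hour).
    k_d
        Ligand oligomerization rate (molecules^-(n-1)/hour).
    k1..k6
        Interaction rates (molecules^-1/hour): trans-activation by monomer
        (k1) and dimer (k2); cis-inhibition by monomer (k3) and dimer (k4);
        cis-activation by monomer (k5) and dimer (k6).
    beta, beta_S
        First-order degradation of ligand/receptor and of free intracellular
        domain (1/hour).
    k_r
        Cytoplasm-to-membrane transport (1/hour), used only by the
        compartmental variant.
    n
        Oligomer size (>= 2); 2 means dimers.

    Defaults are the baseline simulation values: production 200 molecules/h
    for both ligand and receptor, k_d = 1e-4, beta = 0.1 (protein half-life
    about 7 h), beta_S = 0.5, k_r = 0.1, with all interaction rates zero
    until a scenario constructor assigns them.
    """

    b_L: float = 200.0
    b_N: float = 200.0
    k_d: float = 1e-4
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    beta: float = 0.1
    beta_S: float = 0.5
    k_r: float = 0.1
    n: int = 2

    #: baseline named rates (trans-activation, cis-inhibition, cis-activation)
    K_T: ClassVar[float] = 5e-5
    K_CI: ClassVar[float] = 6e-4
    K_CA: ClassVar[float] = 5e-6

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"parameter {name} must be finite and >= 0, got {v!r}")
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")
        if self.beta_S <= 0:
            raise ValidationError("beta_S must be > 0")
        if int(self.n) != self.n or self.n < 2:
            raise ValidationError(f"oligomer size n must be an integer >= 2, got {self.n!r}")

    # -- scenario constructors -------------------------------------------

    @classmethod
    def t1(cls, k_t: float = K_T, k_ci: float = K_CI, **kw) -> "ModelParameters":
        """Monomer trans-activation + dimer cis-inhibition (the favoured model)."""
        return cls(k1=k_t, k4=k_ci, **kw)

    @classmethod
    def mutual_inactivation(cls, k_t: float = K_T, k_ci: float = K_CI, **kw) -> "ModelParameters":
        """Monomer trans-activation + monomer cis-inhibition, no dimerization."""
        kw.setdefault("k_d", 0.0)
        return cls(k1=k_t, k3=k_ci, **kw)

    @classmethod
    def cis_config(cls, which: str, k_t: float = K_T, k_ci: float = K_CI, **kw) -> "ModelParameters":
        """Cis-inhibition variants C1 (dimer), C2 (monomer), C3 (both)."""
        table = {"C1": (0.0, k_ci), "C2": (k_ci, 0.0), "C3": (k_ci, k_ci)}
        try:
            k3, k4 = table[which.upper()]
        except KeyError:
            raise ValidationError(f"unknown cis configuration {which!r}; expected C1/C2/C3") from None
        return cls(k1=k_t, k3=k3, k4=k4, **kw)

    @classmethod
    def trans_config(cls, which: str, k_t: float = K_T, k_ci: float = K_CI, **kw) -> "ModelParameters":
        """Trans-activation variants T1 (monomer), T2 (dimer), T3 (both)."""
        table = {"T1": (k_t, 0.0), "T2": (0.0, k_t), "T3": (k_t, k_t)}
        try:
            k1, k2 = table[which.upper()]
        except KeyError:
            raise ValidationError(f"unknown trans configuration {which!r}; expected T1/T2/T3") from None
        return cls(k1=k1, k2=k2, k4=k_ci, **kw)

    @classmethod
    def cis_activation(cls, scenario: int, k_ca: float = K_CA, k_ci: float = K_CI, **kw) -> "ModelParameters":
        """Isolated-cell cis-activation scenarios.

        1: monomers cis-activate; 2: dimers cis-activate; 3: both.  Dimers
        always cis-inhibit (k4 = k_ci); trans rates are zero because the cell
        has no contacts.
        """
        table = {1: (k_ca, 0.0), 2: (0.0, k_ca), 3: (k_ca, k_ca)}
        try:
            k5, k6 = table[scenario]
        except (KeyError, TypeError):
            raise ValidationError(f"cis-activation scenario must be 1, 2 or 3, got {scenario!r}") from None
        return cls(k4=k_ci, k5=k5, k6=k6, **kw)

    # -- named-rate views -------------------------------------------------

    @property
    def k_t(self) -> float:
        """Monomer trans-activation rate (alias of k1)."""
        return self.k1

    @property
    def k_ci(self) -> float:
        """Dimer cis-inhibition rate if set, else monomer rate (k4 or k3)."""
        return self.k4 if self.k4 > 0 else self.k3

    @property
    def k_ca(self) -> float:
        """Cis-activation rate (k5 or k6, whichever is set)."""
        return self.k5 if self.k5 > 0 else self.k6

    def with_(self, **kw) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name not in ("K_T", "K_CI", "K_CA")}


def _check_nonneg(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValidationError(f"{name} must be finite and non-negative, got {values!r}")
    return arr


def general_rhs(state, ext, p: ModelParameters) -> np.ndarray:
    """Time derivative of (L, Lstar, N, S) under the general model.

    Monomers are produced at ``b_L``, degrade at ``beta``, pair up into
    dimers (two monomers consumed per dimer formed, hence the factor 2) and
    are consumed by trans (k1·N_ext), cis-inhibitory (k3·N) and
    cis-activating (k5·N) receptor binding.  Receptor is consumed by every
    ligand interaction; only trans- and cis-activating interactions release
    intracellular domain S.
    """
    L, Ls, N, S = _check_nonneg("state", state)
    L_ext, Ls_ext, N_ext = _check_nonneg("ext", ext)
    dL = p.b_L - p.beta * L - 2.0 * p.k_d * L * L - (p.k1 * N_ext + p.k3 * N + p.k5 * N) * L
    dLs = p.k_d * L * L - p.beta * Ls - (p.k2 * N_ext + p.k4 * N + p.k6 * N) * Ls
    bound = p.k1 * L_ext + p.k2 * Ls_ext + p.k3 * L + p.k4 * Ls + p.k5 * L + p.k6 * Ls
    dN = p.b_N - p.beta * N - bound * N
    dS = (p.k1 * L_ext + p.k2 * Ls_ext + p.k5 * L + p.k6 * Ls) * N - p.beta_S * S
    return np.array([dL, dLs, dN, dS])


def mi_rhs(state, ext, p: ModelParameters) -> np.ndarray:
    """Time derivative of (L, N, S) under mutual inactivation.

    No dimer species: same-cell monomers and receptors titrate each other
    (k_ci), trans monomers activate (k_t).  Uses k1 as k_t and k3 as k_ci.
    """
    L, N, S = _check_nonneg("state", state)
    L_ext, _Ls_ext, N_ext = _check_nonneg("ext", ext)
    k_t, k_ci = p.k1, p.k3
    dL = p.b_L - p.beta * L - k_t * N_ext * L - k_ci * N * L
    dN = p.b_N - p.beta * N - k_t * L_ext * N - k_ci * L * N
    dS = k_t * N * L_ext - p.beta_S * S
    return np.array([dL, dN, dS])


def t1_rhs(state, ext, p: ModelParameters) -> np.ndarray:
    """Monomer trans-activation, dimer cis-inhibition (general model with
    k1=k_t, k4=k_ci and all other interaction rates zero)."""
    L, Ls, N, S = _check_nonneg("state", state)
    L_ext, _Ls_ext, N_ext = _check_nonneg("ext", ext)
    k_t = p.k1
    k_ci = p.k4
    dL = p.b_L - p.beta * L - 2.0 * p.k_d * L * L - k_t * N_ext * L
    dLs = p.k_d * L * L - p.beta * Ls - k_ci * N * Ls
    dN = p.b_N - p.beta * N - k_ci * Ls * N - k_t * L_ext * N
    dS = k_t * L_ext * N - p.beta_S * S
    return np.array([dL, dLs, dN, dS])


def cis_activation_rhs(state, p: ModelParameters, scenario: int | None = None) -> np.ndarray:
    """Isolated cell (no contacts): dimer cis-inhibition plus cis-activation.

    If ``scenario`` is given, k5/k6 are taken from the scenario table with
    the parameters' cis-activation rate; otherwise p.k5/p.k6 are used as-is.
    """
    if scenario is not None:
        if scenario not in (1, 2, 3):
            raise ValidationError(f"cis-activation scenario must be 1, 2 or 3, got {scenario!r}")
        k_ca = p.k5 if p.k5 > 0 else (p.k6 if p.k6 > 0 else ModelParameters.K_CA)
        k5 = k_ca if scenario in (1, 3) else 0.0
        k6 = k_ca if scenario in (2, 3) else 0.0
        p = p.with_(k5=k5, k6=k6)
    L, Ls, N, S = _check_nonneg("state", state)
    k_ci = p.k4
    dL = p.b_L - p.beta * L - 2.0 * p.k_d * L * L - p.k5 * N * L
    dLs = p.k_d * L * L - p.beta * Ls - k_ci * N * Ls - p.k6 * N * Ls
    dN = p.b_N - p.beta * N - k_ci * Ls * N - p.k5 * L * N - p.k6 * Ls * N
    dS = p.k5 * L * N + p.k6 * Ls * N - p.beta_S * S
    return np.array([dL, dLs, dN, dS])


def oligomer_rhs(state, ext, p: ModelParameters) -> np.ndarray:
    """Oligomer-size generalisation: n monomers combine into one oligomer.

    The homogeneous-population form is used: the monomer drain is
    n·k_d·L^n and the oligomer gain k_d·L^n, so the drain is exactly n times
    the gain (mass bookkeeping).  Monomers additionally cis-activate at k5
    (written k_ca), oligomers cis-inhibit at k4 (k_ci); with n=2 and k5=0
    this is exactly the dimer model t1_rhs.
    """
    if p.n < 2:
        raise ValidationError(f"oligomer size n must be >= 2, got {p.n}")
    L, Ls, N, S = _check_nonneg("state", state)
    L_ext, _Ls_ext, N_ext = _check_nonneg("ext", ext)
    k_t, k_ci, k_ca = p.k1, p.k4, p.k5
    Ln = L ** p.n
    dL = p.b_L - p.beta * L - p.n * p.k_d * Ln - k_t * N_ext * L - k_ca * N * L
    dLs = p.k_d * Ln - p.beta * Ls - k_ci * N * Ls
    dN = p.b_N - p.beta * N - k_ci * Ls * N - k_t * L_ext * N - k_ca * L * N
    dS = k_t * L_ext * N + k_ca * L * N - p.beta_S * S
    return np.array([dL, dLs, dN, dS])


def compartment_rhs(state, ext, p: ModelParameters) -> np.ndarray:
    """Cytoplasm/membrane split: dimerization and dimer cis-inhibition are
    cytoplasmic; trans- and cis-activation happen at the membrane.

    Ligand and receptor are produced in the cytoplasm and transported to the
    membrane at rate k_r; dimers never reach the membrane.
    """
    L_c, Ls, N_c, L_m, N_m, S = _check_nonneg("state", state)
    L_ext, _Ls_ext, N_ext = _check_nonneg("ext", ext)
    k_t, k_ci, k_ca = p.k1, p.k4, p.k5
    dL_c = p.b_L - p.beta * L_c - 2.0 * p.k_d * L_c * L_c - p.k_r * L_c
    dLs = p.k_d * L_c * L_c - p.beta * Ls - k_ci * N_c * Ls
    dN_c = p.b_N - p.beta * N_c - k_ci * Ls * N_c - p.k_r * N_c
    dL_m = p.k_r * L_c - p.beta * L_m - k_t * N_ext * L_m - k_ca * N_m * L_m
    dN_m = p.k_r * N_c - p.beta * N_m - k_t * L_ext * N_m - k_ca * L_m * N_m
    dS = k_t * L_ext * N_m + k_ca * L_m * N_m - p.beta_S * S
    return np.array([dL_c, dLs, dN_c, dL_m, dN_m, dS])
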