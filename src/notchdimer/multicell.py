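"""Tissue-level lattice simulations of juxtacrine Notch signalling.

A :class:`Tissue` is a rectangular grid of cells, each running the
single-cell kinetics, coupled through its neighbours: the trans ligand seen
by a cell is the arithmetic mean of the ligand monomer levels over its
neighbours (boundary cells average over the neighbours they have).  Two
patterning set-ups are provided:

* **wing-vein**: a single ligand (Delta) produced along an exponential
  gradient ``b_L(y) = L_max * exp(-|y - y0|)`` across rows, uniform receptor
  production.  Cells near the gradient peak are ligand-rich senders whose
  own receptors are cis-inhibited by dimers; their neighbours on either
  flank receive strong trans input, producing two parallel bands of
  activity that delimit the prospective vein.

* **dorsoventral boundary**: two ligand species with compartment-restricted
  production (Serrate dorsal, Delta ventral) and binary Fringe gating —
  Notch in dorsal cells can only be trans-activated by Delta, Notch in
  ventral cells only by Serrate.  Under dimer-mediated cis-inhibition,
  ligand and receptor coexist in every cell and activity concentrates in
  the cell rows flanking the compartment interface; under monomer-mediated
  mutual inactivation they cannot coexist and no boundary stripe forms.

The whole lattice is integrated as one coupled ODE system (no per-cell
relaxation sweeps, so results carry no cell-update order dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .models import ExternalSignal, ModelParameters, ValidationError
from .steady_state import SteadyStateError

__all__ = [
    "LigandSpecies",
    "Tissue",
    "neighbor_matrix",
    "neighbor_trans_input",
    "gradient_profile",
    "wing_vein_simulation",
    "dv_boundary_simulation",
]


def neighbor_matrix(rows: int, cols: int, topology: str = "von_neumann") -> sparse.csr_matrix:
    """Row-stochastic neighbour-averaging operator A: (A @ x)[i] = mean of x
    over the neighbours of cell i.

    Topologies: ``von_neumann`` (4-neighbour), ``moore`` (8-neighbour),
    ``hex`` (6-neighbour, odd rows offset right).  Cells are indexed
    row-major (``i = r * cols + c``).
    """
    if rows < 1 or cols < 1:
        raise ValidationError("grid must have at least one row and column")
    if rows * cols < 2:
        raise ValidationError("every cell needs at least one neighbour; grid too small")
    offsets = {
        "von_neumann": [(-1, 0), (1, 0), (0, -1), (0, 1)],
        "moore": [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)],
    }
    data, rows_i, cols_j = [], [], []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if topology in offsets:
                nbrs = [(r + dr, c + dc) for dr, dc in offsets[topology]]
            elif topology == "hex":
                shift = 0 if r % 2 == 0 else 1
                nbrs = [(r, c - 1), (r, c + 1),
                        (r - 1, c - 1 + shift), (r - 1, c + shift),
                        (r + 1, c - 1 + shift), (r + 1, c + shift)]
            else:
                raise ValidationError(f"unknown topology {topology!r}")
            nbrs = [(rr, cc) for rr, cc in nbrs if 0 <= rr < rows and 0 <= cc < cols]
            w = 1.0 / len(nbrs)
            for rr, cc in nbrs:
                rows_i.append(i)
                cols_j.append(rr * cols + cc)
                data.append(w)
    return sparse.csr_matrix((data, (rows_i, cols_j)), shape=(rows * cols, rows * cols))


@dataclass
class LigandSpecies:
    """One ligand species on a tissue.

    ``production`` is its per-cell production-rate field b_L (molecules/h,
    flat length rows*cols); ``permitted`` flags the cells whose Notch this
    species may trans-activate (the binary Fringe gate).  ``k_d`` may differ
    between species (e.g. a dimerization-deficient ectopic ligand).
    """

    name: str
    production: np.ndarray
    permitted: np.ndarray
    k_d: float = 1e-4
    k_t: float = ModelParameters.K_T
    k_ci: float = ModelParameters.K_CI

    def __post_init__(self):
        self.production = np.asarray(self.production, dtype=float).ravel()
        self.permitted = np.asarray(self.permitted, dtype=bool).ravel()
        if np.any(self.production < 0):
            raise ValidationError(f"species {self.name!r} production field must be >= 0")
        if self.k_d < 0 or self.k_t < 0 or self.k_ci < 0:
            raise ValidationError(f"species {self.name!r} rates must be >= 0")


@dataclass
class Tissue:
    """Lattice of cells with per-cell production fields and ligand species.

    ``model`` selects the per-cell kinetics: ``"T1"`` (dimer-mediated
    cis-inhibition; state per species is monomer+dimer) or ``"MI"``
    (monomer-mediated mutual inactivation, no dimer pool).  State layout of
    the flat vector: for each species its monomer field (and, under T1, its
    dimer field), then the receptor field N, then the signal field S.
    """

    rows: int
    cols: int
    species: list[LigandSpecies]
    b_N: np.ndarray
    model: str = "T1"
    topology: str = "von_neumann"
    compartment: np.ndarray | None = None  # labels per cell, e.g. 'dorsal'/'ventral'
    beta: float = 0.1
    beta_S: float = 0.5

    def __post_init__(self):
        self.n_cells = self.rows * self.cols
        self.b_N = np.broadcast_to(np.asarray(self.b_N, dtype=float), (self.n_cells,)).copy()
        if np.any(self.b_N < 0):
            raise ValidationError("b_N field must be >= 0")
        if self.model not in ("T1", "MI"):
            raise ValidationError(f"model must be 'T1' or 'MI', got {self.model!r}")
        for s in self.species:
            if s.production.size != self.n_cells or s.permitted.size != self.n_cells:
                raise ValidationError(f"species {s.name!r} field size mismatch")
        self.A = neighbor_matrix(self.rows, self.cols, self.topology)
        self._per_species = 2 if self.model == "T1" else 1
        self.n_vars = self._per_species * len(self.species) + 2

    # -- state vector layout ------------------------------------------------

    def _split(self, y: np.ndarray):
        n, k = self.n_cells, self._per_species
        parts = y.reshape(self.n_vars, n)
        L = [parts[k * s] for s in range(len(self.species))]
        Lstar = [parts[k * s + 1] for s in range(len(self.species))] if k == 2 else None
        N = parts[-2]
        S = parts[-1]
        return L, Lstar, N, S

    def zero_state(self) -> np.ndarray:
        return np.zeros(self.n_vars * self.n_cells)

    # -- dynamics -----------------------------------------------------------

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Coupled time derivative of the whole lattice (flat vector)."""
        y = np.maximum(y, 0.0)
        L, Lstar, N, S = self._split(y)
        out = np.empty_like(y).reshape(self.n_vars, self.n_cells)
        k = self._per_species
        dN = self.b_N - self.beta * N
        dS = -self.beta_S * S
        for si, sp in enumerate(self.species):
            Ls = L[si]
            # receptor level presented to this species by each cell's
            # neighbours: only cells whose Notch the species may bind count
            N_ext = self.A @ (N * sp.permitted)
            L_ext = self.A @ Ls
            trans = sp.k_t * L_ext * N * sp.permitted
            if self.model == "T1":
                D = Lstar[si]
                dL = sp.production - self.beta * Ls - 2.0 * sp.k_d * Ls * Ls - sp.k_t * N_ext * Ls
                dD = sp.k_d * Ls * Ls - self.beta * D - sp.k_ci * N * D
                dN -= sp.k_ci * D * N + trans
                out[k * si] = dL
                out[k * si + 1] = dD
            else:
                dL = sp.production - self.beta * Ls - sp.k_t * N_ext * Ls - sp.k_ci * N * Ls
                dN -= sp.k_ci * Ls * N + trans
                out[k * si] = dL
            dS += trans
        out[-2] = dN
        out[-1] = dS
        return out.ravel()

    def trans_flux(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Per-species contribution to dS in each cell (diagnostic)."""
        y = np.maximum(y, 0.0)
        L, _Lstar, N, _S = self._split(y)
        return {sp.name: sp.k_t * (self.A @ L[si]) * N * sp.permitted
                for si, sp in enumerate(self.species)}

    def steady_state(self, *, t_max: float = 5000.0, chunk: float = 250.0,
                     res_tol_factor: float = 1e-6, rtol: float = 1e-6) -> np.ndarray:
        """Integrate the lattice from the zero state until every cell's RHS
        is zero to within ``res_tol_factor * max(b_N)``."""
        y = self.zero_state()
        scale = max(float(self.b_N.max()), 1.0)
        res_tol = res_tol_factor * scale
        t = 0.0
        while t < t_max:
            t_end = min(t + chunk, t_max)
            sol = solve_ivp(lambda _t, yy: self.rhs(yy), (t, t_end), y,
                            method="RK45", rtol=rtol, atol=1e-8 * scale)
            if not sol.success:
                raise SteadyStateError(f"lattice integration failed: {sol.message}")
            y = np.maximum(sol.y[:, -1], 0.0)
            t = t_end
            residual = float(np.max(np.abs(self.rhs(y))))
            if residual < res_tol:
                return y
            if residual < 1e-4 * max(scale, *(s.production.max() for s in self.species)):
                # close enough for a matrix-free Newton polish to take over
                y_ref, res_ref = self._polish(y)
                if res_ref < res_tol:
                    return y_ref
        raise SteadyStateError(
            f"lattice did not reach steady state by t={t_max} h (residual {residual:.3e})",
            state=y, residual=residual)

    def _polish(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Drive the residual down by Jacobian-free Newton-Krylov."""
        from scipy.optimize import newton_krylov
        try:
            y_ref = newton_krylov(lambda z: self.rhs(z), y, f_tol=1e-10 * max(float(self.b_N.max()), 1.0),
                                  maxiter=50)
        except Exception:
            return y, float(np.max(np.abs(self.rhs(y))))
        y_ref = np.maximum(y_ref, 0.0)
        return y_ref, float(np.max(np.abs(self.rhs(y_ref))))

    def field(self, y: np.ndarray, what: str = "S") -> np.ndarray:
        """Extract a per-cell field from a flat state as a (rows, cols) array."""
        L, Lstar, N, S = self._split(np.asarray(y))
        if what == "S":
            arr = S
        elif what == "N":
            arr = N
        else:
            for si, sp in enumerate(self.species):
                if what == sp.name:
                    arr = L[si]
                    break
                if what == sp.name + "*":
                    if Lstar is None:
                        raise ValidationError("no dimer pool in the MI model")
                    arr = Lstar[si]
                    break
            else:
                raise ValidationError(f"unknown field {what!r}")
        return arr.reshape(self.rows, self.cols)


def neighbor_trans_input(tissue: Tissue, y: np.ndarray, cell: int | tuple[int, int]) -> dict[str, ExternalSignal]:
    """Trans inputs seen by one cell: per species, the neighbourhood mean of
    ligand monomer (and dimer under T1) and of receptor."""
    if isinstance(cell, tuple):
        r, c = cell
        cell = r * tissue.cols + c
    if not 0 <= cell < tissue.n_cells:
        raise ValidationError(f"cell index {cell} out of range")
    L, Lstar, N, _S = tissue._split(np.asarray(y, dtype=float))
    row = tissue.A.getrow(cell)
    out = {}
    for si, sp in enumerate(tissue.species):
        L_ext = (row @ L[si]).item()
        Ls_ext = (row @ Lstar[si]).item() if Lstar is not None else 0.0
        N_ext = (row @ N).item()
        out[sp.name] = ExternalSignal(L_ext, Ls_ext, N_ext)
    return out


def gradient_profile(L_max: float, y0: float, y_grid) -> np.ndarray:
    """Exponential production profile b_L(y) = L_max * exp(-|y - y0|)."""
    if L_max <= 0:
        raise ValidationError("L_max must be > 0")
    y = np.asarray(y_grid, dtype=float)
    return L_max * np.exp(-np.abs(y - y0))


def wing_vein_simulation(rows: int = 20, cols: int = 20, p: ModelParameters | None = None,
                         L_max: float = 15000.0, y0: float | None = None,
                         topology: str = "von_neumann",
                         return_tissue: bool = False):
    """Steady-state activity field for a ligand-production gradient.

    One ligand (Delta) with production decaying exponentially from row
    ``y0`` (grid centre by default), uniform receptor production
    b_N = 200 molecules/h, dimer-mediated cis-inhibition kinetics.
    Returns the per-cell S field (rows x cols).
    """
    if p is None:
        p = ModelParameters.t1()
    if y0 is None:
        y0 = (rows - 1) / 2.0
    prof = gradient_profile(L_max, y0, np.arange(rows, dtype=float))
    production = np.repeat(prof, cols)
    delta = LigandSpecies("Delta", production, np.ones(rows * cols, dtype=bool),
                          k_d=p.k_d, k_t=p.k1, k_ci=p.k4)
    tissue = Tissue(rows, cols, [delta], b_N=np.full(rows * cols, 200.0),
                    model="T1", topology=topology, beta=p.beta, beta_S=p.beta_S)
    y = tissue.steady_state()
    S = tissue.field(y, "S")
    return (S, tissue, y) if return_tissue else S


def dv_boundary_simulation(rows: int = 20, cols: int = 20, p: ModelParameters | None = None,
                           model: str = "T1", b_N: float = 1000.0, b_L: float = 200.0,
                           ectopic: dict | None = None,
                           topology: str = "von_neumann",
                           return_tissue: bool = False):
    """Steady-state activity field for dorsoventral boundary patterning.

    The top half of the grid is the dorsal compartment (produces Serrate),
    the bottom half ventral (produces Delta).  Fringe gating is binary:
    Delta may trans-activate only dorsal Notch, Serrate only ventral Notch.
    Receptor production is uniform (default 1000 molecules/h, 'in excess'
    of ligand production, default 200).

    ``ectopic`` adds a stripe of extra ligand production with the
    exponential gradient profile: a mapping with keys ``species`` ('Delta'
    or 'Serrate'), ``center`` (row), ``L_max`` (default 15000) and
    optionally ``k_d`` (e.g. a low value for a dimerization-deficient
    ligand; the ectopic pool is then an independent species with its own
    dimerization rate but the same Fringe identity).
    """
    if p is None:
        p = ModelParameters.t1() if model == "T1" else ModelParameters.mutual_inactivation()
    n = rows * cols
    row_of = np.repeat(np.arange(rows), cols)
    dorsal = row_of < rows // 2
    compartment = np.where(dorsal, "dorsal", "ventral")
    k_ci = p.k4 if model == "T1" else p.k3
    common = dict(k_d=p.k_d, k_t=p.k1, k_ci=k_ci)
    serrate = LigandSpecies("Serrate", np.where(dorsal, b_L, 0.0), ~dorsal, **common)
    delta = LigandSpecies("Delta", np.where(~dorsal, b_L, 0.0), dorsal, **common)
    species = [serrate, delta]
    if ectopic is not None:
        name = ectopic["species"]
        if name not in ("Delta", "Serrate"):
            raise ValidationError(f"ectopic species must be Delta or Serrate, got {name!r}")
        prof = gradient_profile(ectopic.get("L_max", 15000.0), float(ectopic["center"]),
                                row_of.astype(float))
        kw = dict(common)
        if "k_d" in ectopic and ectopic["k_d"] is not None:
            kw["k_d"] = float(ectopic["k_d"])
        mask = dorsal if name == "Delta" else ~dorsal
        species.append(LigandSpecies(f"ectopic-{name}", prof, mask, **kw))
    tissue = Tissue(rows, cols, species, b_N=np.full(n, float(b_N)), model=model,
                    topology=topology, compartment=compartment,
                    beta=p.beta, beta_S=p.beta_S)
    y = tissue.steady_state()
    S = tissue.field(y, "S")
    return (S, tissue, y) if return_tissue else S
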