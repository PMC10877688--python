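"""Enzymatically constrained FBA against local metabolite availability.

Per population and timestep the simulator solves

    maximize    ATP production
    subject to  S_int . f = 0           (internal steady state)
                sum_r f_r <= a          (enzymatic constraint)
                0 <= f,  F_in <= c / B_u   (environment-limited uptake)

with ``f`` in umol per timestep per population unit (1 unit = 1e10 cells)
and ``a`` the total-flux cap per unit.  After maximizing ATP a secondary LP
minimizes the summed flux at the fixed optimum, which makes the exchange
fluxes deterministic among degenerate optima (parsimonious FBA).

Uptake bounds follow the total-availability contract: the single population
at a site may take up at most the amount present, so the per-unit bound for
metabolite ``i`` is ``c(i) / B_u`` (metabolites flagged *unlimited*, such as
water, are unbounded).  Growth converts the ATP flux through the configured
cost of 1e-15 mol ATP per new cell.

Two interchangeable LP backends stand behind :func:`solve`: GLPK (via
swiglpk; the default, with a persistent warm-started problem per model) and
``scipy.optimize.linprog`` (HiGHS; used as an independent reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .gem_io import GemModel

__all__ = [
    "FbaProblem",
    "FbaSolution",
    "uptake_bounds",
    "solve",
    "growth_from_atp",
    "solver_for",
    "FbaSolver",
    "InternalConsistencyError",
    "POPULATION_UNIT_CELLS",
    "ATP_PER_CELL_MOL",
    "DEFAULT_ENZYMATIC_CONSTRAINT",
]

#: one population unit, cells (Table-2 convention: constraint per 1e10 bacteria)
POPULATION_UNIT_CELLS = 1e10
#: ATP needed to grow one cell, mol
ATP_PER_CELL_MOL = 1e-15
#: total flux cap, umol per timestep per population unit
DEFAULT_ENZYMATIC_CONSTRAINT = 2.0

#: LP feasibility tolerance
LP_TOL = 1e-9
#: post-hoc clipping threshold for solver round-off in fluxes
#: (1e-9 umol/step/unit = 1e-15 mol; GLPK's feasibility tolerance lets
#: phantom exchange fluxes of this order through on near-empty sites)
FLUX_CLIP = 1e-9


class InternalConsistencyError(RuntimeError):
    """The environment handed the solver an impossible state (negative amount)."""


@dataclass(frozen=True)
class FbaProblem:
    """One population's FBA instance at one site and timestep."""

    gem: GemModel
    env_amounts: Mapping[str, float]  # umol at the site
    population_units: float  # B / 1e10
    enzymatic_constraint: float = DEFAULT_ENZYMATIC_CONSTRAINT
    unlimited: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.population_units <= 0:
            raise ValueError("population_units must be positive")
        if self.enzymatic_constraint <= 0:
            raise ValueError("enzymatic_constraint must be positive")


@dataclass(frozen=True)
class FbaSolution:
    """Fluxes (umol/step/unit), uptake/secretion split, and growth rate."""

    status: str  # optimal | infeasible | zero
    objective: float  # ATP flux, umol/step/unit
    flux_values: np.ndarray
    reaction_order: tuple[str, ...]
    uptake: dict[str, float]  # F_in per metabolite
    secretion: dict[str, float]  # F_out per metabolite
    growth_rate: float  # cells per cell per timestep

    @property
    def fluxes(self) -> dict[str, float]:
        return dict(zip(self.reaction_order, self.flux_values))

    @property
    def total_flux(self) -> float:
        return float(self.flux_values.sum())


def uptake_bounds(
    c: Mapping[str, float],
    population_units: float,
    unlimited: frozenset[str] | set[str] = frozenset(),
) -> dict[str, float]:
    """Per-unit uptake bound for every metabolite present at the site.

    ``bound(i) = c(i) / B_u`` so total uptake ``F_in * B_u`` can never exceed
    the amount present.  Unlimited metabolites (water) get ``inf``.
    Metabolites absent from ``c`` are implicitly bounded at zero.
    """
    if population_units <= 0:
        raise ValueError("population_units must be positive")
    bounds: dict[str, float] = {}
    for met, amount in c.items():
        if met in unlimited:
            bounds[met] = math.inf
            continue
        if amount < -LP_TOL:
            raise InternalConsistencyError(
                f"negative environmental amount for {met!r}: {amount}"
            )
        bounds[met] = max(amount, 0.0) / population_units
    for met in unlimited:
        bounds[met] = math.inf
    return bounds


def growth_from_atp(
    atp_flux: float, B: float, atp_per_cell_mol: float = ATP_PER_CELL_MOL
) -> float:
    """Cells added in one forward-Euler timestep from the per-unit ATP flux.

    ``atp_flux`` is in umol per timestep per population unit; the population
    holds ``B / 1e10`` units, and each new cell costs ``atp_per_cell_mol``.
    """
    if atp_flux < 0:
        raise ValueError("atp_flux must be non-negative")
    total_atp_mol = atp_flux * 1e-6 * (B / POPULATION_UNIT_CELLS)
    return total_atp_mol / atp_per_cell_mol


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


class FbaSolver:
    """Reusable LP machinery for one GemModel.

    Builds the stoichiometric structure once; each call updates only the
    environment-dependent uptake bounds.  Solutions are cached on the
    effective bound vector (bounds are clamped at the enzymatic constraint
    first, since no single flux can exceed the total-flux cap, so all
    nutrient-saturated sites share one cache entry).
    """

    _MAX_CACHE = 100_000

    def __init__(self, gem: GemModel, backend: str = "glpk"):
        self.gem = gem
        self.backend = backend
        S, met_order = gem.stoichiometric_matrix()
        self.reaction_order = tuple(gem.reactions)
        n = len(self.reaction_order)
        balanced = [
            i for i, m in enumerate(met_order) if m not in gem.boundary_metabolites
        ]
        self.S_int = S[balanced, :].tocsc()
        self.met_order = met_order

        # objective vector
        obj = np.zeros(n)
        if gem.objective_reaction is not None:
            obj[self.reaction_order.index(gem.objective_reaction)] = 1.0
        else:
            row = S[[met_order.index(gem.objective_metabolite)], :].toarray().ravel()
            obj = row
        self.objective_vector = obj

        self.static_lb = np.array(
            [gem.reactions[r].lower_bound for r in self.reaction_order]
        )
        self.static_ub = np.array(
            [gem.reactions[r].upper_bound for r in self.reaction_order]
        )

        # environment coupling: column index of each uptake / secretion
        # exchange reaction, per metabolite
        pos = {r: i for i, r in enumerate(self.reaction_order)}
        self.uptake_cols: dict[str, int] = {}
        self.secretion_cols: dict[str, int] = {}
        for met, (up, sec) in gem.exchange_index.items():
            if up is not None and up in gem.environment_coupled:
                self.uptake_cols[met] = pos[up]
            if sec is not None and sec in gem.environment_coupled:
                self.secretion_cols[met] = pos[sec]
        self.uptake_mets = tuple(self.uptake_cols)
        self._uptake_col_arr = np.array(
            [self.uptake_cols[m] for m in self.uptake_mets], dtype=np.intp
        )

        self._cache: dict = {}
        self._zero = FbaSolution(
            status="zero",
            objective=0.0,
            flux_values=np.zeros(n),
            reaction_order=self.reaction_order,
            uptake={},
            secretion={},
            growth_rate=0.0,
        )
        self._glpk = None

    # -- public ------------------------------------------------------------

    def solve(self, problem: FbaProblem) -> FbaSolution:
        bounds = uptake_bounds(
            problem.env_amounts, problem.population_units, problem.unlimited
        )
        return self.solve_with_bounds(bounds, problem.enzymatic_constraint)

    def solve_with_bounds(
        self, bounds: Mapping[str, float], a: float
    ) -> FbaSolution:
        """Solve with explicit per-metabolite uptake bounds (umol/step/unit)."""
        ub = self.static_ub.copy()
        for met, col in self.uptake_cols.items():
            ub[col] = min(ub[col], bounds.get(met, 0.0))
        # no single flux can exceed the total-flux cap
        np.minimum(ub, a, out=ub)
        key = (a, ub[self._uptake_col_arr].tobytes())
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        sol = self._solve_lp(ub, a)
        if len(self._cache) < self._MAX_CACHE:
            self._cache[key] = sol
        return sol

    # -- LP ----------------------------------------------------------------

    def _solve_lp(self, ub: np.ndarray, a: float) -> FbaSolution:
        if self.backend == "glpk":
            flux, status, z = self._solve_glpk(ub, a)
        elif self.backend == "scipy":
            flux, status, z = self._solve_scipy(ub, a)
        else:
            raise ValueError(f"unknown LP backend {self.backend!r}")
        if status != "optimal":
            return FbaSolution(
                status="infeasible",
                objective=0.0,
                flux_values=np.zeros(len(self.reaction_order)),
                reaction_order=self.reaction_order,
                uptake={},
                secretion={},
                growth_rate=0.0,
            )
        flux[np.abs(flux) < FLUX_CLIP] = 0.0
        np.maximum(flux, 0.0, out=flux)
        # the stage-1 optimum is the ATP flux; the parsimonious stage-2 point
        # reproduces it only to within its own floor tolerance
        objective = float(z)
        if objective <= LP_TOL and not flux.any():
            return self._zero
        uptake = {}
        secretion = {}
        for met, col in self.uptake_cols.items():
            if flux[col] > 0.0:
                uptake[met] = float(flux[col])
        for met, col in self.secretion_cols.items():
            if flux[col] > 0.0:
                secretion[met] = float(flux[col])
        # growth rate per cell: objective umol/step/unit over the ATP cost
        g = objective * 1e-6 / (ATP_PER_CELL_MOL * POPULATION_UNIT_CELLS)
        return FbaSolution(
            status="optimal" if objective > LP_TOL else "zero",
            objective=max(objective, 0.0),
            flux_values=flux,
            reaction_order=self.reaction_order,
            uptake=uptake,
            secretion=secretion,
            growth_rate=g,
        )

    # GLPK backend: persistent problem object, warm-started simplex.
    def _build_glpk(self):
        import swiglpk as glp

        n = len(self.reaction_order)
        m = self.S_int.shape[0]
        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        glp.glp_add_rows(lp, m + 2)  # steady state + sum(f) + objective floor
        for i in range(1, m + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)
        glp.glp_set_row_bnds(lp, m + 1, glp.GLP_UP, 0.0, 0.0)  # set per solve
        glp.glp_set_row_bnds(lp, m + 2, glp.GLP_FR, 0.0, 0.0)
        glp.glp_add_cols(lp, n)

        coo = self.S_int.tocoo()
        nz = len(coo.data) + n + int(np.count_nonzero(self.objective_vector))
        ia = glp.intArray(nz + 1)
        ja = glp.intArray(nz + 1)
        ar = glp.doubleArray(nz + 1)
        k = 1
        for r, c, v in zip(coo.row, coo.col, coo.data):
            ia[k], ja[k], ar[k] = int(r) + 1, int(c) + 1, float(v)
            k += 1
        for j in range(n):  # sum(f) row
            ia[k], ja[k], ar[k] = m + 1, j + 1, 1.0
            k += 1
        for j in np.flatnonzero(self.objective_vector):  # objective floor row
            ia[k], ja[k], ar[k] = m + 2, int(j) + 1, float(self.objective_vector[j])
            k += 1
        glp.glp_load_matrix(lp, k - 1, ia, ja, ar)

        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        # guard against simplex stalling on degenerate bases; failures fall
        # back to a fresh standard basis and, at worst, an infeasible status
        parm.it_lim = 50_000
        parm.tm_lim = 10_000  # ms
        # the default primal tolerance (1e-7) lets steady-state leaks
        # manufacture phantom ATP on near-empty sites
        parm.tol_bnd = 1e-10
        self._glpk = (glp, lp, parm, m, n)

    def _glpk_set_col(self, glp, lp, j, lo, hi):
        if hi == math.inf:
            if lo == 0.0:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, 0.0, 0.0)
            else:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, lo, 0.0)
        elif hi <= lo:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, lo, lo)
        else:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_DB, lo, hi)

    def _solve_glpk(self, ub: np.ndarray, a: float):
        if self._glpk is None:
            self._build_glpk()
        glp, lp, parm, m, n = self._glpk

        for j in range(n):
            self._glpk_set_col(glp, lp, j, float(self.static_lb[j]), float(ub[j]))
        glp.glp_set_row_bnds(lp, m + 1, glp.GLP_UP, 0.0, float(a))
        glp.glp_set_row_bnds(lp, m + 2, glp.GLP_FR, 0.0, 0.0)
        for j in range(n):
            glp.glp_set_obj_coef(lp, j + 1, float(self.objective_vector[j]))
        ret = glp.glp_simplex(lp, parm)
        if ret != 0 or glp.glp_get_status(lp) != glp.GLP_OPT:
            return np.zeros(n), "infeasible", 0.0
        z = glp.glp_get_obj_val(lp)

        # parsimony stage: fix the ATP optimum, minimize total flux
        glp.glp_set_row_bnds(lp, m + 2, glp.GLP_LO, z - max(LP_TOL, abs(z) * 1e-9), 0.0)
        glp.glp_set_obj_dir(lp, glp.GLP_MIN)
        for j in range(n):
            glp.glp_set_obj_coef(lp, j + 1, 1.0)
        ret = glp.glp_simplex(lp, parm)
        if ret != 0 or glp.glp_get_status(lp) != glp.GLP_OPT:
            # warm-started basis occasionally stalls on the parsimony stage;
            # retry both stages from a fresh standard basis
            glp.glp_std_basis(lp)
            glp.glp_set_row_bnds(lp, m + 2, glp.GLP_FR, 0.0, 0.0)
            glp.glp_set_obj_dir(lp, glp.GLP_MAX)
            for j in range(n):
                glp.glp_set_obj_coef(lp, j + 1, float(self.objective_vector[j]))
            ret = glp.glp_simplex(lp, parm)
            if ret != 0 or glp.glp_get_status(lp) != glp.GLP_OPT:
                return np.zeros(n), "infeasible", 0.0
            z = glp.glp_get_obj_val(lp)
            glp.glp_set_row_bnds(
                lp, m + 2, glp.GLP_LO, z - max(LP_TOL, abs(z) * 1e-9), 0.0
            )
            glp.glp_set_obj_dir(lp, glp.GLP_MIN)
            for j in range(n):
                glp.glp_set_obj_coef(lp, j + 1, 1.0)
            ret = glp.glp_simplex(lp, parm)
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        if ret != 0 or glp.glp_get_status(lp) != glp.GLP_OPT:
            return np.zeros(n), "infeasible", 0.0
        flux = np.fromiter(
            (glp.glp_get_col_prim(lp, j + 1) for j in range(n)), float, n
        )
        return flux, "optimal", z

    def _solve_scipy(self, ub: np.ndarray, a: float):
        from scipy.optimize import linprog
        from scipy import sparse

        n = len(self.reaction_order)
        A_eq = self.S_int
        b_eq = np.zeros(A_eq.shape[0])
        A_ub = sparse.csr_matrix(np.ones((1, n)))
        res = linprog(
            -self.objective_vector,
            A_ub=A_ub,
            b_ub=[a],
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=list(zip(self.static_lb, [None if u == math.inf else u for u in ub])),
            method="highs",
        )
        if not res.success:
            return np.zeros(n), "infeasible", 0.0
        z = -res.fun
        # parsimony stage
        A_ub2 = sparse.vstack(
            [A_ub, sparse.csr_matrix(-self.objective_vector)]
        )
        res2 = linprog(
            np.ones(n),
            A_ub=A_ub2,
            b_ub=[a, -(z - max(LP_TOL, abs(z) * 1e-9))],
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=list(zip(self.static_lb, [None if u == math.inf else u for u in ub])),
            method="highs",
        )
        if not res2.success:
            return np.zeros(n), "infeasible", 0.0
        return np.asarray(res2.x, dtype=float), "optimal", z


def solver_for(gem: GemModel, backend: str = "glpk") -> FbaSolver:
    """Return (building on first use) the persistent solver for a model."""
    solver = gem._solver_cache.get(backend)
    if solver is None:
        solver = FbaSolver(gem, backend=backend)
        gem._solver_cache[backend] = solver
    return solver


def solve(problem: FbaProblem, backend: str = "glpk") -> FbaSolution:
    """Solve one enzymatically constrained FBA problem (module-level API)."""
    return solver_for(problem.gem, backend).solve(problem)
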