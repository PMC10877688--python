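"""Shared fixtures and the independent LP oracle.

The oracle solves the enzymatically constrained FBA polytope

    S f = 0,  sum(f) <= a,  0 <= f <= ub

by exhaustive enumeration of basic feasible solutions (vertices), entirely
independently of the package's LP backends.  It is only usable for tiny
models (<= ~8 reactions) and exists to pin the solver's optima.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from gutlattice.gem_io import GemModel, ReactionSpec
from gutlattice.synthetic_fixtures import make_crossfeeding_consortium

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# the oracle
# ---------------------------------------------------------------------------


def enumerate_lp_optimum(S_int, obj, a, ub, tol=1e-9):
    """Maximum of ``obj . f`` over the constrained-FBA polytope by vertex
    enumeration.  ``ub`` entries may be np.inf (the sum cap keeps the
    polytope bounded).  Returns the optimal objective value.
    """
    S_int = np.atleast_2d(np.asarray(S_int, dtype=float))
    obj = np.asarray(obj, dtype=float)
    n = len(obj)
    ub = np.asarray(ub, dtype=float)

    # candidate active constraints: rows (lhs, rhs) of equalities to pick
    candidates = []  # (row, rhs)
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        candidates.append((e, 0.0))  # f_i = 0
        if np.isfinite(ub[i]):
            candidates.append((e, ub[i]))  # f_i = ub_i
    candidates.append((np.ones(n), a))  # sum f = a

    m = S_int.shape[0] if S_int.size else 0
    best = None
    need = n - m
    if need < 0:
        need = 0
    for combo in itertools.combinations(range(len(candidates)), need):
        rows = [S_int[i] for i in range(m)] + [candidates[i][0] for i in combo]
        rhs = [0.0] * m + [candidates[i][1] for i in combo]
        A = np.vstack(rows) if rows else np.zeros((0, n))
        if A.shape[0] != n or np.linalg.matrix_rank(A) < n:
            continue
        try:
            f = np.linalg.solve(A, np.asarray(rhs))
        except np.linalg.LinAlgError:
            continue
        # feasibility
        if (f < -tol).any():
            continue
        if (f - ub > tol).any():
            continue
        if f.sum() > a + tol:
            continue
        if S_int.size and np.abs(S_int @ f).max() > tol:
            continue
        val = float(obj @ f)
        if best is None or val > best:
            best = val
    if best is None:
        raise AssertionError("oracle found no feasible vertex")
    return best


def oracle_optimum(gem: GemModel, env_bounds: dict, a: float) -> float:
    """Oracle optimum for a GemModel given per-metabolite uptake bounds."""
    from gutlattice.fba_core import solver_for

    solver = solver_for(gem)
    ub = solver.static_ub.copy()
    for met, col in solver.uptake_cols.items():
        ub[col] = min(ub[col], env_bounds.get(met, 0.0))
    ub = np.minimum(ub, a)
    return enumerate_lp_optimum(
        solver.S_int.toarray(), solver.objective_vector, a, ub
    )


# ---------------------------------------------------------------------------
# tiny hand-built models
# ---------------------------------------------------------------------------


def _gem(name, reactions, env_coupled=None, objective_metabolite="atp_c"):
    return GemModel(
        species_id=name,
        reactions={r.id: r for r in reactions},
        objective_metabolite=objective_metabolite,
        boundary_metabolites=frozenset({objective_metabolite}),
        environment_coupled=frozenset(
            env_coupled
            if env_coupled is not None
            else [r.id for r in reactions if r.is_exchange]
        ),
    )


@pytest.fixture(scope="session")
def chain_gem():
    """EX_S uptake + R1: S -> ATP (1:1); optimum a/2."""
    return _gem(
        "chain",
        [
            ReactionSpec("EX_s_e_rev", {"s_e": 1.0}, is_exchange=True),
            ReactionSpec("R1", {"s_e": -1.0, "atp_c": 1.0}),
        ],
    )


@pytest.fixture(scope="session")
def branched_gem():
    """Two routes from S: P1 (2 steps, 4 ATP) vs P2 (1 step, 2 ATP)."""
    return _gem(
        "branched",
        [
            ReactionSpec("EX_s_e_rev", {"s_e": 1.0}, is_exchange=True),
            ReactionSpec("P1a", {"s_e": -1.0, "i_c": 1.0}),
            ReactionSpec("P1b", {"i_c": -1.0, "atp_c": 4.0}),
            ReactionSpec("P2", {"s_e": -1.0, "atp_c": 2.0}),
        ],
    )


@pytest.fixture(scope="session")
def consortium():
    return make_crossfeeding_consortium()
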