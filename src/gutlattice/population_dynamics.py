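"""Metapopulation dynamics on the lattice.

Each lattice site holds at most one bacterial population (one species, size
``B`` in cells).  Per timestep, the canonical phase order is

    feed -> metabolize -> spread -> quiescence flags -> death ->
    colonization -> mixing (+ distal population removal) ->
    metabolite diffusion -> advection + distal removal -> record

Populations are seeded at probability 0.3 per site with 5e7 cells of a
uniformly random roster species (about 540 populations, 2.7e10 cells on the
default lattice).  A population of at least 1e10 cells spreads half its
size into a uniformly chosen empty Moore-neighbourhood site; populations at
the 2e10 cap are quiescent and skip metabolism; every population dies with
probability 0.0075 per step; empty sites are colonized at 5e-5 per step.

Mixing follows Kawasaki-style dynamics: in random order, every site swaps
its full contents with a uniformly random Moore neighbour, provided neither
partner has used its swap this pass.  An attempted swap is executed with
probability 0.76, which calibrates the population random walk to the
metabolite diffusion coefficient (see docs/methods.md); the slow/fast
sensitivity variants scale this acceptance or repeat the pass.

All per-step cell-count changes are ledgered (growth, deaths, washout,
colonization) so mass bookkeeping can be audited exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from numba import njit

from .fba_core import (
    DEFAULT_ENZYMATIC_CONSTRAINT,
    POPULATION_UNIT_CELLS,
    FbaSolver,
    solver_for,
)
from .gem_io import GemModel
from .lattice_env import LatticeGeometry, MetaboliteField

__all__ = [
    "Population",
    "CommunityState",
    "StepLedger",
    "initialize_community",
    "metabolize_all",
    "spread",
    "update_quiescence",
    "die",
    "colonize",
    "mix_populations",
    "well_mixed_relocate",
    "INITIAL_POPULATION_SIZE",
    "SPREAD_THRESHOLD",
    "MAX_POPULATION_SIZE",
    "DEATH_PROBABILITY",
    "COLONIZATION_PROBABILITY",
    "INITIAL_OCCUPANCY",
]

log = logging.getLogger(__name__)

INITIAL_POPULATION_SIZE = 5e7
SPREAD_THRESHOLD = 1e10
MAX_POPULATION_SIZE = 2e10
DEATH_PROBABILITY = 0.0075
COLONIZATION_PROBABILITY = 5e-5
INITIAL_OCCUPANCY = 0.3

_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass
class Population:
    species_id: str
    B: float  # cells
    col: int
    row: int
    quiescent: bool = False


@dataclass
class StepLedger:
    """Cell-count changes within one timestep, for exact bookkeeping."""

    growth: float = 0.0
    deaths: float = 0.0
    washout: float = 0.0
    colonized: float = 0.0
    quiescent_count: int = 0
    infeasible_count: int = 0


class CommunityState:
    """All populations plus the occupancy grid and the seeded RNG."""

    def __init__(
        self,
        geometry: LatticeGeometry,
        roster: Mapping[str, GemModel],
        rng: np.random.Generator,
    ):
        self.geometry = geometry
        self.roster = dict(roster)
        self.roster_names = list(self.roster)
        self.rng = rng
        self.populations: list[Population] = []
        self.grid = np.full((geometry.height, geometry.width), -1, dtype=np.int64)
        self.t = 0

    # -- structure maintenance --------------------------------------------

    def add_population(self, pop: Population) -> None:
        if self.grid[pop.row, pop.col] != -1:
            raise ValueError(f"site ({pop.row},{pop.col}) already occupied")
        self.grid[pop.row, pop.col] = len(self.populations)
        self.populations.append(pop)

    def _reindex(self, keep: np.ndarray) -> None:
        """Drop populations where ``keep`` is False and rebuild the grid."""
        self.populations = [p for p, k in zip(self.populations, keep) if k]
        self.grid.fill(-1)
        for i, p in enumerate(self.populations):
            self.grid[p.row, p.col] = i

    def total_cells(self) -> float:
        return float(sum(p.B for p in self.populations))

    def totals_by_species(self) -> dict[str, float]:
        out = {name: 0.0 for name in self.roster_names}
        for p in self.populations:
            out[p.species_id] = out.get(p.species_id, 0.0) + p.B
        return out

    def check_invariants(self) -> None:
        """One population per site; locations in bounds; grid consistent."""
        h, w = self.grid.shape
        seen = set()
        for i, p in enumerate(self.populations):
            assert 0 <= p.row < h and 0 <= p.col < w, "location out of bounds"
            assert (p.row, p.col) not in seen, "two populations on one site"
            assert self.grid[p.row, p.col] == i, "grid out of sync"
            assert p.B > 0, "non-positive population size"
            seen.add((p.row, p.col))
        assert int((self.grid >= 0).sum()) == len(self.populations)


def initialize_community(
    roster: Mapping[str, GemModel],
    geometry: LatticeGeometry,
    rng: np.random.Generator,
    occupancy: float = INITIAL_OCCUPANCY,
    initial_size: float = INITIAL_POPULATION_SIZE,
) -> CommunityState:
    """Seed each site with probability ``occupancy`` by 5e7 cells of a
    uniformly random roster species."""
    if not roster:
        raise ValueError("roster must not be empty")
    state = CommunityState(geometry, roster, rng)
    h, w = geometry.height, geometry.width
    mask = rng.random((h, w)) < occupancy
    species = rng.integers(0, len(state.roster_names), size=(h, w))
    for row, col in np.argwhere(mask):
        state.add_population(
            Population(
                species_id=state.roster_names[species[row, col]],
                B=initial_size,
                col=int(col),
                row=int(row),
            )
        )
    return state


# ---------------------------------------------------------------------------
# metabolism
# ---------------------------------------------------------------------------


def metabolize_all(
    state: CommunityState,
    field_: MetaboliteField,
    a: float = DEFAULT_ENZYMATIC_CONSTRAINT,
    energy_ledger=None,
    flux_recorder=None,
    backend: str = "glpk",
) -> StepLedger:
    """Solve every non-quiescent population's FBA and apply the outcome.

    Uptake is subtracted from and secretion added to the site pools; growth
    is applied forward-Euler and capped at the maximum population size.
    Solutions are audited into ``energy_ledger`` and recorded into
    ``flux_recorder`` when given (both observers; neither touches the RNG or
    the trajectory).
    """
    ledger = StepLedger()
    order = state.rng.permutation(len(state.populations))
    for idx in order:
        pop = state.populations[idx]
        if pop.quiescent:
            ledger.quiescent_count += 1
            continue
        gem = state.roster[pop.species_id]
        solver = solver_for(gem, backend)
        B_u = pop.B / POPULATION_UNIT_CELLS
        c = field_.site_amounts(solver.uptake_mets, pop.row, pop.col)
        bounds = {}
        for met, amount in c.items():
            if met in field_.unlimited:
                bounds[met] = np.inf
            else:
                bounds[met] = amount / B_u
        sol = solver.solve_with_bounds(bounds, a)
        if sol.status == "infeasible":
            ledger.infeasible_count += 1
            log.warning(
                "infeasible FBA for %s at (%d,%d), t=%d",
                pop.species_id, pop.row, pop.col, state.t,
            )
            continue
        for met, f_in in sol.uptake.items():
            field_.take_at(met, pop.row, pop.col, f_in * B_u)
        for met, f_out in sol.secretion.items():
            field_.add_at(met, pop.row, pop.col, f_out * B_u)
        delta = sol.growth_rate * pop.B
        applied = min(delta, MAX_POPULATION_SIZE - pop.B)
        pop.B += applied
        ledger.growth += applied
        if energy_ledger is not None:
            energy_ledger.record_solution(sol, growth_cells=applied)
        if flux_recorder is not None:
            flux_recorder.record(state.t, pop.species_id, sol, B_u)
    return ledger


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------


def _empty_moore_neighbours(state: CommunityState, row: int, col: int):
    h, w = state.grid.shape
    out = []
    for dr, dc in _MOORE:
        r, c = row + dr, col + dc
        if 0 <= r < h and 0 <= c < w and state.grid[r, c] == -1:
            out.append((int(r), int(c)))
    return out

def spread(
    state: CommunityState,
    threshold: float = SPREAD_THRESHOLD,
) -> None:
    """Populations above the spreading threshold split half their size into
    a uniformly chosen empty adjacent (Moore) site; total cells conserved."""
    rng = state.rng
    snapshot = rng.permutation(len(state.populations))
    for idx in snapshot:
        pop = state.populations[idx]
        if pop.B < threshold:
            continue
        empties = _empty_moore_neighbours(state, pop.row, pop.col)
        if not empties:
            continue
        r, c = empties[rng.integers(len(empties))]
        half = pop.B / 2.0
        pop.B = half
        state.add_population(
            Population(species_id=pop.species_id, B=half, col=c, row=r)
        )


def update_quiescence(state: CommunityState, enabled: bool = True) -> None:
    """Re-evaluate the quiescence flag: populations at the cap stop
    metabolizing (they still die, swap, and may resume if they shrink)."""
    for pop in state.populations:
        pop.quiescent = enabled and pop.B >= MAX_POPULATION_SIZE


def die(state: CommunityState, p: float = DEATH_PROBABILITY) -> float:
    """Remove each population independently with probability ``p``.

    Biomass is not returned to the metabolite pools.  Returns the cells
    removed.
    """
    n = len(state.populations)
    if n == 0 or p == 0.0:
        # no RNG draw: a disabled process must not perturb the stream shape
        return 0.0
    draws = state.rng.random(n)
    keep = draws >= p
    died = float(sum(p_.B for p_, k in zip(state.populations, keep) if not k))
    if not keep.all():
        state._reindex(keep)
    return died


def colonize(
    state: CommunityState,
    p: float = COLONIZATION_PROBABILITY,
    initial_size: float = INITIAL_POPULATION_SIZE,
    enabled: bool = True,
) -> float:
    """Seed each empty site with probability ``p`` by a random species."""
    if not enabled or p == 0.0:
        return 0.0
    h, w = state.grid.shape
    draws = state.rng.random((h, w))
    hits = np.argwhere((draws < p) & (state.grid == -1))
    added = 0.0
    for row, col in hits:
        species = state.roster_names[state.rng.integers(len(state.roster_names))]
        state.add_population(
            Population(species_id=species, B=initial_size, col=int(col), row=int(row))
        )
        added += initial_size
    return added


# ---------------------------------------------------------------------------
# Kawasaki-style mixing
# ---------------------------------------------------------------------------


@njit(cache=False)
def _kawasaki_pass(grid, order, nbr_pick, accept_draw, accept_p):  # pragma: no cover
    h, w = grid.shape
    used = np.zeros((h, w), dtype=np.bool_)
    moore_dr = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
    moore_dc = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
    for k in range(order.shape[0]):
        site = order[k]
        r = site // w
        c = site % w
        # only occupied sites initiate a swap of their bacterial content;
        # an empty site can still be chosen as the destination
        if grid[r, c] < 0 or used[r, c]:
            continue
        nr = r + moore_dr[nbr_pick[k]]
        nc = c + moore_dc[nbr_pick[k]]
        if nr < 0 or nr >= h or nc < 0 or nc >= w:
            used[r, c] = True
            continue
        if used[nr, nc]:
            used[r, c] = True
            continue
        # the attempt consumes both partners' swap regardless of acceptance
        used[r, c] = True
        used[nr, nc] = True
        if accept_draw[k] < accept_p:
            tmp = grid[r, c]
            grid[r, c] = grid[nr, nc]
            grid[nr, nc] = tmp


def mix_populations(
    state: CommunityState,
    repeats: Optional[int] = None,
    accept: Optional[float] = None,
) -> float:
    """Swap site contents along Kawasaki-style dynamics, then wash out the
    most distal column.  Returns the cells removed distally.

    Each pass visits the occupied sites in random order; an unused pair
    (site, random Moore neighbour) is swapped with the calibrated acceptance
    probability and both partners are marked as having used their attempt.
    An isolated population therefore draws exactly one Moore hop per pass
    (variance 0.76 x 0.75 L^2 = 0.57 L^2 per axis, the metabolite value).
    """
    g = state.geometry
    repeats = g.mixing_repeats if repeats is None else repeats
    accept = g.mixing_accept if accept is None else accept
    rng = state.rng
    n = g.n_sites
    for _ in range(repeats):
        order = rng.permutation(n)
        nbr_pick = rng.integers(0, 8, size=n)
        accept_draw = rng.random(n)
        _kawasaki_pass(state.grid, order, nbr_pick, accept_draw, accept)
    # grid indices moved; update population coordinates
    for (row, col) in np.argwhere(state.grid >= 0):
        pop = state.populations[state.grid[row, col]]
        pop.row, pop.col = int(row), int(col)
    return _remove_distal(state)


def _remove_distal(state: CommunityState) -> float:
    """Populations at the most distal column leave the system."""
    w = state.geometry.width
    keep = np.array([p.col < w - 1 for p in state.populations], dtype=bool)
    removed = float(sum(p.B for p, k in zip(state.populations, keep) if not k))
    if not keep.all():
        state._reindex(keep)
    return removed


def well_mixed_relocate(state: CommunityState) -> float:
    """Assign all populations to random non-overlapping sites (well-mixed
    variant), then wash out the distal column."""
    n = len(state.populations)
    if n == 0:
        return 0.0
    sites = state.rng.choice(state.geometry.n_sites, size=n, replace=False)
    w = state.geometry.width
    state.grid.fill(-1)
    for i, (pop, site) in enumerate(zip(state.populations, sites)):
        pop.row, pop.col = int(site // w), int(site % w)
        state.grid[pop.row, pop.col] = i
    return _remove_distal(state)
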