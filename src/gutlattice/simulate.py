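"""The canonical simulation loop and the run output bundle.

Each timestep executes the documented phase order:

    1. feed (on the 60-step schedule)
    2. metabolism: per-population enzymatically constrained FBA, applied to
       the site pools and the population sizes (random population order)
    3. spreading of large populations
    4. quiescence re-evaluation
    5. stochastic death
    6. colonization of empty sites
    7. Kawasaki mixing (or well-mixed relocation) + distal washout
    8. metabolite diffusion
    9. advection + distal removal (well-mixed: equal redistribution after)
    10. recording (abundances, population table, cell ledger, audit)

Runs are reproducible: the same config and seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, RunConfig
from .gem_io import GemModel, block_uptake_patch, apply_patch, load_gem
from .lattice_env import FeedSchedule, MetaboliteField
from .observables import AbundanceRecorder, FluxRecorder
from .population_dynamics import (
    CommunityState,
    colonize,
    die,
    initialize_community,
    metabolize_all,
    mix_populations,
    spread,
    update_quiescence,
    well_mixed_relocate,
)
from .thermo_audit import EnergyLedger

__all__ = ["SimulationResult", "run_simulation", "resolve_roster"]

log = logging.getLogger(__name__)


def resolve_roster(config: RunConfig) -> dict[str, GemModel]:
    """Materialize the species roster: bundled fixtures or SBML files."""
    from . import synthetic_fixtures as fx

    bundled = {
        spec.name: spec
        for spec in (fx.BIFIDO_SPEC, fx.PRODUCER_SPEC, fx.COMPETITOR_SPEC)
    }
    roster: dict[str, GemModel] = {}
    for name, source in config.roster.items():
        if source == "fixture":
            if name not in bundled:
                raise ConfigError(f"no bundled fixture model named {name!r}")
            roster[name] = fx.make_toy_gem(bundled[name])
        else:
            if not os.path.exists(source):
                raise ConfigError(f"SBML file for {name!r} not found: {source!r}")
            roster[name] = load_gem(source, species_id=name)
    for species, mets in config.knockouts.items():
        roster[species] = apply_patch(
            roster[species], block_uptake_patch(species, mets)
        )
    return roster


@dataclass
class SimulationResult:
    """In-memory output bundle of one run."""

    config: RunConfig
    abundances: pd.DataFrame
    populations: pd.DataFrame
    fluxes: pd.DataFrame
    cell_ledger: pd.DataFrame
    audit: Optional[dict]
    manifest: dict
    final_state: CommunityState
    final_field: MetaboliteField

    def final_totals(self) -> dict[str, float]:
        return self.final_state.totals_by_species()

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.abundances.to_csv(os.path.join(outdir, "abundances.csv"), index=False)
        self.populations.to_csv(os.path.join(outdir, "populations.csv"), index=False)
        self.fluxes.to_csv(os.path.join(outdir, "fluxes.csv"), index=False)
        self.cell_ledger.to_csv(os.path.join(outdir, "cell_ledger.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        if self.audit is not None:
            with open(os.path.join(outdir, "audit.json"), "w") as fh:
                json.dump(self.audit, fh, indent=2)
        self.config.to_yaml(os.path.join(outdir, "config.yaml"))


def run_simulation(
    config: RunConfig, seed: Optional[int] = None
) -> SimulationResult:
    """Run the full model for ``config.duration`` timesteps."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    roster = resolve_roster(config)
    geometry = config.geometry()
    schedule = FeedSchedule(
        config.feed_composition(),
        period=config.feed_period,
        columns=config.feed_columns,
    )
    field_ = MetaboliteField(geometry)
    field_.init_oxygen(config.initial_oxygen)
    state = initialize_community(
        roster,
        geometry,
        rng,
        occupancy=config.initial_occupancy,
        initial_size=config.initial_population_size,
    )

    energy_ledger = EnergyLedger() if config.audit else None
    flux_recorder = FluxRecorder() if config.record_fluxes else None
    abundance = AbundanceRecorder(list(roster))
    pop_rows: list[dict] = []
    ledger_rows: list[dict] = []

    def record_populations(t: int) -> None:
        for p in state.populations:
            pop_rows.append(
                {
                    "t": t,
                    "col": p.col,
                    "row": p.row,
                    "species": p.species_id,
                    "B": p.B,
                    "quiescent": p.quiescent,
                }
            )

    abundance.record(0, state.totals_by_species())
    record_populations(0)

    for t in range(config.duration):
        state.t = t
        total_before = state.total_cells()
        field_.feed(schedule, t)
        step = metabolize_all(
            state,
            field_,
            a=config.enzymatic_constraint,
            energy_ledger=energy_ledger,
            flux_recorder=flux_recorder,
            backend=config.backend,
        )
        spread(state)
        update_quiescence(state, enabled=config.quiescence)
        step.deaths = die(state, config.death_probability)
        step.colonized = colonize(
            state,
            config.colonization_probability,
            config.initial_population_size,
            enabled=config.colonization,
        )
        if config.well_mixed:
            step.washout = well_mixed_relocate(state)
        else:
            step.washout = mix_populations(
                state, repeats=config.mixing_repeats, accept=config.mixing_accept
            )
        field_.diffuse()
        field_.advect(t)
        if config.well_mixed:
            field_.well_mixed_redistribute()

        ledger_rows.append(
            {
                "t": t,
                "total_before": total_before,
                "growth": step.growth,
                "deaths": step.deaths,
                "washout": step.washout,
                "colonized": step.colonized,
                "total_after": state.total_cells(),
                "quiescent": step.quiescent_count,
                "infeasible": step.infeasible_count,
            }
        )
        done = t + 1 == config.duration
        if (t + 1) % config.record_interval == 0 or done:
            abundance.record(t + 1, state.totals_by_species())
        if (t + 1) % config.population_table_interval == 0 or done:
            record_populations(t + 1)
        if done or (t + 1) % 1000 == 0:
            log.info("step %d/%d: %d populations", t + 1, config.duration,
                     len(state.populations))

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
    }
    return SimulationResult(
        config=config,
        abundances=abundance.frame(),
        populations=pd.DataFrame(
            pop_rows, columns=["t", "col", "row", "species", "B", "quiescent"]
        ),
        fluxes=(
            flux_recorder.frame()
            if flux_recorder is not None
            else pd.DataFrame(
                columns=["t", "species", "metabolite", "uptake_umol", "secretion_umol"]
            )
        ),
        cell_ledger=pd.DataFrame(ledger_rows),
        audit=energy_ledger.summary() if energy_ledger is not None
        and energy_ledger.total_solutions else None,
        manifest=manifest,
        final_state=state,
        final_field=field_,
    )
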