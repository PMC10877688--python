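"""Run configuration: defaults, validation, YAML round-trip.

The defaults are the model's standard parameter set: a 225x8 lattice of
2x2 mm sites (3-minute timesteps, 90 mL total volume), 211 umol of each
scheduled nutrient every 60 timesteps into the first six columns, 0.1 umol
initial oxygen per site, initial occupancy 0.3 at 5e7 cells, spreading at
1e10 cells, quiescence/cap at 2e10 cells, death probability 0.0075 and
colonization probability 5e-5 per step, an enzymatic constraint of 2 umol
flux per timestep per 1e10 cells, and 1e-15 mol ATP per new cell.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import yaml

from .lattice_env import (
    LatticeGeometry,
    default_geometry,
    fixture_geometry,
    gos_composition,
    large_geometry,
    small_geometry,
)

__all__ = ["RunConfig", "table2_parameters", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any compute)."""


_VARIANTS = {
    "default": default_geometry,
    "small": small_geometry,
    "large": large_geometry,
}


def table2_parameters() -> dict[str, float]:
    """The standard parameter set, in the printed units."""
    return {
        "lattice_side_length_mm": 2.0,
        "lattice_width": 225,
        "lattice_height": 8,
        "timestep_s": 180.0,
        "average_initial_populations": 540.0,
        "placement_probability_per_empty_site": 0.00005,
        "death_probability_per_population": 0.0075,
        "initial_population_size_cells": 5e7,
        "spreading_size_cells": 1e10,
        "maximum_population_size_cells": 2e10,
        "atp_to_grow_one_cell_mol": 1e-15,
        "enzymatic_constraint_umol_per_step_per_unit": 2.0,
        "nutrient_input_umol_per_feeding": 211.0,
        "initial_oxygen_umol_per_site": 0.1,
        "advection_mm_per_timestep": 2.0,
        "diffusion_cm2_per_s": 6.3e-5,
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    # lattice & duration
    lattice: str = "default"  # default | small | large | fixture
    lattice_width: Optional[int] = None  # override (fixture lattices)
    lattice_height: Optional[int] = None
    duration: int = 10080  # timesteps (21 days)
    seed: int = 0

    # roster: species name -> "fixture" (bundled toy) or an SBML path
    roster: dict[str, str] = field(
        default_factory=lambda: {
            "bifido": "fixture",
            "producer": "fixture",
            "competitor": "fixture",
        }
    )
    #: per-species uptake knockouts: species -> [metabolite ids]
    knockouts: dict[str, list[str]] = field(default_factory=dict)

    # feeding: nutrient -> umol per feeding; "gos" expands to DP3/4/5
    feed: dict[str, float] = field(default_factory=lambda: {"lactose": 211.0})
    feed_period: int = 60
    feed_columns: int = 6
    #: scale feed amounts by lattice-site count relative to the 1800-site
    #: reference, keeping the per-site nutrient density fixed
    scale_feed_to_lattice: bool = True

    # population dynamics (Table-2 values)
    initial_occupancy: float = 0.3
    initial_population_size: float = 5e7
    death_probability: float = 0.0075
    colonization_probability: float = 0.00005
    enzymatic_constraint: float = 2.0
    initial_oxygen: float = 0.1

    # mode flags (sensitivity variants)
    well_mixed: bool = False
    colonization: bool = True
    quiescence: bool = True
    mixing_repeats: Optional[int] = None
    mixing_accept: Optional[float] = None

    # observability
    audit: bool = True
    record_fluxes: bool = True
    record_interval: int = 10
    population_table_interval: int = 100
    backend: str = "glpk"

    # ------------------------------------------------------------------

    @classmethod
    def consortium_fixture(
        cls, with_2fl: bool = False, duration: int = 1500, seed: int = 0, **overrides
    ) -> "RunConfig":
        """Desk-scale competition run: toy consortium on the 20x4 lattice.

        Uses the fixture feeding regime (one transit-time pulse every 20
        steps at the full model's time-averaged per-site inflow), with or
        without the 2'-FL supplement.
        """
        from .synthetic_fixtures import consortium_feeds

        feeds = consortium_feeds()
        sched = feeds["lactose+2fl" if with_2fl else "lactose"]
        return cls(
            lattice="fixture",
            duration=duration,
            seed=seed,
            feed=dict(sched.composition),
            feed_period=sched.period,
            scale_feed_to_lattice=False,
            **overrides,
        )

    def validate(self) -> None:
        for name in (
            "initial_occupancy",
            "death_probability",
            "colonization_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.duration < 0:
            raise ConfigError("duration must be non-negative")
        if self.enzymatic_constraint <= 0:
            raise ConfigError("enzymatic_constraint must be positive")
        if self.initial_oxygen < 0:
            raise ConfigError("initial_oxygen must be non-negative")
        if self.lattice not in (*_VARIANTS, "fixture"):
            raise ConfigError(f"unknown lattice variant {self.lattice!r}")
        if not self.roster:
            raise ConfigError("roster must not be empty")
        for nutrient, amount in self.feed.items():
            if amount < 0:
                raise ConfigError(f"negative feed amount for {nutrient!r}")
        for species in self.knockouts:
            if species not in self.roster:
                raise ConfigError(f"knockout target {species!r} not in roster")

    def geometry(self) -> LatticeGeometry:
        if self.lattice == "fixture":
            return fixture_geometry(
                width=self.lattice_width or 20, height=self.lattice_height or 4
            )
        g = _VARIANTS[self.lattice]()
        if self.lattice_width or self.lattice_height:
            raise ConfigError("lattice dims can only be overridden for 'fixture'")
        return g

    def feed_composition(self) -> dict[str, float]:
        """Expand nutrient names to metabolite amounts (umol per feeding)."""
        g = self.geometry()
        scale = g.n_sites / 1800.0 if self.scale_feed_to_lattice else 1.0
        comp: dict[str, float] = {}
        for nutrient, amount in self.feed.items():
            amount = amount * scale
            if nutrient == "lactose":
                comp["lcts_e"] = comp.get("lcts_e", 0.0) + amount
            elif nutrient in ("2fl", "2'-FL", "2FL"):
                comp["2fl_e"] = comp.get("2fl_e", 0.0) + amount
            elif nutrient == "gos":
                for met, v in gos_composition(amount).items():
                    comp[met] = comp.get(met, 0.0) + v
            else:  # raw metabolite id
                comp[nutrient] = comp.get(nutrient, 0.0) + amount
        return comp

    # YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        cfg = cls(**dict(doc))
        cfg.validate()
        return cfg

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        try:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        except (FileNotFoundError, OSError):
            doc = yaml.safe_load(source)
        if not isinstance(doc, dict):
            raise ConfigError("config YAML must be a mapping")
        return cls.from_dict(doc)
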