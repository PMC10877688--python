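"""Thermodynamic plausibility audit of FBA solutions.

Every solution's Gibbs free-energy balance is

    l = sum_i (F_in(i) - F_out(i)) * E(i)      [J / timestep / population unit]

with ``F`` the exchange fluxes (converted from umol to mol) and ``E`` the
per-metabolite Gibbs free energy (kJ/mol, pH 7 / ionic strength 0.1 M
convention).  ``l >= 0`` means free energy was dissipated — the solution is
thermodynamically plausible; ``l < 0`` (output carries more free energy than
the input) flags a violation.  A run-level ledger accumulates the fraction
of plausible solutions and the share of total growth produced by violators.

The audit is purely observational: enabling it never changes a simulation
trajectory.

The bundled default energy table is *synthetic*: self-consistent toy values
for the fixture metabolites, not literature measurements.  Values for 2'-FL
and the GOS fractions are derived compositely from lactose, fucose and
galactose (condensation water is ignored by convention, which makes the
patch-added hydrolysis reactions energy-neutral by construction).  A real
table can be supplied as a two-column CSV (metabolite id, kJ/mol).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .fba_core import FbaSolution

__all__ = [
    "EnergyTable",
    "EnergyLedger",
    "AuditError",
    "energy_balance",
    "audit_summary",
    "SYNTHETIC_ENERGIES",
    "VIOLATION_TOLERANCE_J",
]

#: LP round-off absorbed before a solution is called a violation (J)
VIOLATION_TOLERANCE_J = 1e-9


class AuditError(KeyError):
    """A metabolite in an audited exchange has no energy entry."""


#: synthetic per-metabolite Gibbs free energies, kJ/mol (fixture scale)
SYNTHETIC_ENERGIES: dict[str, float] = {
    "lcts_e": -1440.0,
    "glc_D_e": -720.0,
    "gal_e": -720.0,
    "fuc_L_e": -720.0,
    "lac_L_e": -380.0,
    "ac_e": -260.0,
    "ppd12_e": -327.0,
    "but_e": -353.0,
    "co2_e": -394.0,
    "for_e": -351.0,
    "h2o_e": -238.0,
    "o2_e": 0.0,
    "h2_e": 0.0,
}

#: composite rules: id -> list of (source id, multiplicity)
COMPOSITE_RULES: dict[str, tuple[tuple[str, float], ...]] = {
    "2fl_e": (("lcts_e", 1.0), ("fuc_L_e", 1.0)),
    "gosdp3_e": (("lcts_e", 1.0), ("gal_e", 1.0)),
    "gosdp4_e": (("lcts_e", 1.0), ("gal_e", 2.0)),
    "gosdp5_e": (("lcts_e", 1.0), ("gal_e", 3.0)),
}


@dataclass(frozen=True)
class EnergyTable:
    """Metabolite -> Gibbs free energy (kJ/mol), with composite derivation."""

    energies: Mapping[str, float]

    @classmethod
    def with_composites(
        cls,
        base: Optional[Mapping[str, float]] = None,
        rules: Mapping[str, tuple] = COMPOSITE_RULES,
    ) -> "EnergyTable":
        energies = dict(SYNTHETIC_ENERGIES if base is None else base)
        for target, parts in rules.items():
            if target not in energies:
                try:
                    energies[target] = sum(energies[src] * k for src, k in parts)
                except KeyError as exc:
                    raise AuditError(
                        f"composite rule for {target!r} needs {exc.args[0]!r}"
                    ) from exc
        return cls(energies)

    @classmethod
    def from_csv(cls, path: str, composites: bool = True) -> "EnergyTable":
        base: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                base[row[0].strip()] = float(row[1])
        return cls.with_composites(base) if composites else cls(base)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for met, e in self.energies.items():
                writer.writerow([met, e])

    def __getitem__(self, met: str) -> float:
        try:
            return self.energies[met]
        except KeyError:
            raise AuditError(f"no Gibbs energy entry for metabolite {met!r}")

    def __contains__(self, met: str) -> bool:
        return met in self.energies


def energy_balance(solution: FbaSolution, table: EnergyTable) -> float:
    """Energy loss ``l`` of one solution, J per timestep per population unit.

    Positive ``l``: the inputs carried more free energy than the outputs
    (dissipation — plausible).  Negative ``l``: flagged as a violation.
    """
    l = 0.0
    for met, f_in in solution.uptake.items():
        l += f_in * table[met]  # umol * kJ/mol = mJ -> * 1e-3 J below
    for met, f_out in solution.secretion.items():
        l -= f_out * table[met]
    return l * 1e-3


@dataclass
class EnergyLedger:
    """Run-level audit counters (monotone non-decreasing over a run)."""

    table: EnergyTable = field(default_factory=EnergyTable.with_composites)
    tolerance_j: float = VIOLATION_TOLERANCE_J
    total_solutions: int = 0
    violating_solutions: int = 0
    total_growth: float = 0.0
    violator_growth: float = 0.0
    total_energy_loss_j: float = 0.0

    def record_solution(self, solution: FbaSolution, growth_cells: float) -> None:
        l = energy_balance(solution, self.table)
        self.record(l, growth_cells)

    def record(self, l: float, growth_cells: float = 0.0) -> None:
        self.total_solutions += 1
        self.total_growth += growth_cells
        self.total_energy_loss_j += l
        if l < -self.tolerance_j:
            self.violating_solutions += 1
            self.violator_growth += growth_cells

    def summary(self) -> dict[str, float]:
        return audit_summary(self)


def audit_summary(ledger: EnergyLedger) -> dict[str, float]:
    """Percentage of plausible solutions and the violators' growth share."""
    if ledger.total_solutions == 0:
        raise ValueError("audit summary undefined: no solutions recorded")
    plausible = ledger.total_solutions - ledger.violating_solutions
    growth_share = (
        100.0 * ledger.violator_growth / ledger.total_growth
        if ledger.total_growth > 0
        else 0.0
    )
    return {
        "fraction_plausible": 100.0 * plausible / ledger.total_solutions,
        "violator_growth_share": growth_share,
        "solutions_audited": ledger.total_solutions,
    }
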