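"""The spatial environment: per-site metabolite pools and transport.

The colon is discretized as a regular ``width x height`` lattice (default
225 x 8 sites of 2 x 2 mm, 0.05 mL each, 90 mL total) with a 180 s timestep.
Metabolites move by

* **diffusion** — per timestep, N substeps in which a fraction ``p`` of each
  site's amount moves to each of the four nearest neighbours (defaults
  N = 2, p = 0.1425; walls are reflecting: mass that would cross stays put);
  the resulting effective diffusion coefficient is
  ``D = 2 N p L^2 / (2 dt) = 6.3e-5 cm^2/s`` and is held constant across the
  lattice-size variants by adjusting N, p and the advection stride;
* **advection** — bulk distal transport by one column per timestep (two on
  the fine lattice, one every second step on the coarse lattice); oxygen is
  exempt; the most distal column is removed from the system;
* **feeding** — every 60 timesteps (3 h) the scheduled nutrient amounts are
  divided equally over the first six columns;
* an optional **well-mixed** variant that divides every metabolite's lattice
  total equally over all sites each timestep.

Amounts are in umol per site.  Unlimited metabolites (water) are represented
symbolically rather than as large numbers so conservation checks stay exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "LatticeGeometry",
    "MetaboliteField",
    "FeedSchedule",
    "default_geometry",
    "small_geometry",
    "large_geometry",
    "fixture_geometry",
    "gos_composition",
    "diffuse",
    "advect",
    "feed",
    "init_oxygen",
    "well_mixed_redistribute",
    "tracer_transit_hours",
    "kernel_displacement_variance",
    "effective_diffusion_cm2_s",
    "TOTAL_COLON_VOLUME_ML",
    "GOS_FRACTIONS",
]

TOTAL_COLON_VOLUME_ML = 90.0
#: DP3 / DP4 / DP5 mass split of the GOS dose
GOS_FRACTIONS = {"gosdp3_e": 0.64, "gosdp4_e": 0.28, "gosdp5_e": 0.08}


@dataclass(frozen=True)
class LatticeGeometry:
    """Lattice dimensions, transport constants and their variant scalings."""

    width: int = 225
    height: int = 8
    site_side_mm: float = 2.0
    timestep_s: float = 180.0
    site_volume_ml: float = 0.05
    diffusion_substeps: int = 2
    diffusion_fraction: float = 0.1425
    advection_columns: int = 1
    advection_period: int = 1  # advect every k-th timestep
    n_feed_columns: int = 6
    mixing_repeats: int = 1
    mixing_accept: float = 0.76

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def site_side_cm(self) -> float:
        return self.site_side_mm / 10.0


def default_geometry() -> LatticeGeometry:
    return LatticeGeometry()


def small_geometry() -> LatticeGeometry:
    """112x4 sites of 4x4 mm: one 7.125% substep, advection every 2nd step."""
    return LatticeGeometry(
        width=112,
        height=4,
        site_side_mm=4.0,
        site_volume_ml=TOTAL_COLON_VOLUME_ML / (112 * 4),
        diffusion_substeps=1,
        diffusion_fraction=0.07125,
        advection_columns=1,
        advection_period=2,
        mixing_accept=0.19,
    )


def large_geometry() -> LatticeGeometry:
    """450x16 sites of 1x1 mm: eight substeps, two columns per step."""
    return LatticeGeometry(
        width=450,
        height=16,
        site_side_mm=1.0,
        site_volume_ml=TOTAL_COLON_VOLUME_ML / (450 * 16),
        diffusion_substeps=8,
        diffusion_fraction=0.1425,
        advection_columns=2,
        advection_period=1,
        mixing_repeats=4,
        mixing_accept=0.76,
    )


def fixture_geometry(width: int = 20, height: int = 4) -> LatticeGeometry:
    """Desk-scale lattice with default-style sites and transport constants."""
    return LatticeGeometry(
        width=width,
        height=height,
        site_volume_ml=0.05,
    )


@dataclass
class FeedSchedule:
    """Pulsed nutrient inflow: amounts (umol) per feeding event."""

    composition: dict[str, float]
    period: int = 60
    columns: int = 6

    def __post_init__(self) -> None:
        for met, amount in self.composition.items():
            if amount < 0:
                raise ValueError(f"negative feed amount for {met!r}")

    def with_gos(self, total: float) -> "FeedSchedule":
        comp = dict(self.composition)
        comp.update(gos_composition(total))
        return FeedSchedule(comp, self.period, self.columns)


def gos_composition(total: float) -> dict[str, float]:
    """Split a GOS dose into its DP3/DP4/DP5 fractions (64/28/8 %)."""
    return {met: frac * total for met, frac in GOS_FRACTIONS.items()}


class MetaboliteField:
    """Per-site amounts of every extracellular metabolite.

    Arrays are ``(height, width)``; column 0 is the proximal end.  Metabolites
    in ``unlimited`` are symbolic (infinite supply, no array); metabolites in
    ``non_advected`` (oxygen) are exempt from advection but still diffuse.
    """

    def __init__(
        self,
        geometry: LatticeGeometry,
        unlimited: Iterable[str] = ("h2o_e",),
        non_advected: Iterable[str] = ("o2_e",),
    ):
        self.geometry = geometry
        self.amounts: dict[str, np.ndarray] = {}
        self.unlimited = frozenset(unlimited)
        self.non_advected = frozenset(non_advected)

    # -- bookkeeping -------------------------------------------------------

    def _array(self, met: str) -> np.ndarray:
        arr = self.amounts.get(met)
        if arr is None:
            g = self.geometry
            arr = np.zeros((g.height, g.width))
            self.amounts[met] = arr
        return arr

    def amount(self, met: str) -> np.ndarray:
        if met in self.unlimited:
            raise ValueError(f"{met!r} is unlimited; it has no finite field")
        return self._array(met)

    def total(self, met: str) -> float:
        if met in self.unlimited:
            return math.inf
        arr = self.amounts.get(met)
        return float(arr.sum()) if arr is not None else 0.0

    def site_amounts(self, mets: Sequence[str], row: int, col: int) -> dict[str, float]:
        out: dict[str, float] = {}
        for met in mets:
            if met in self.unlimited:
                out[met] = math.inf
            else:
                arr = self.amounts.get(met)
                out[met] = float(arr[row, col]) if arr is not None else 0.0
        return out

    def add_at(self, met: str, row: int, col: int, amount: float) -> None:
        if met in self.unlimited:
            return
        self._array(met)[row, col] += amount

    def take_at(self, met: str, row: int, col: int, amount: float) -> None:
        """Remove ``amount`` from a site, clipping round-off at zero."""
        if met in self.unlimited:
            return
        arr = self._array(met)
        new = arr[row, col] - amount
        if new < -1e-6:
            raise ValueError(
                f"overdraw of {met!r} at ({row},{col}): {arr[row, col]} - {amount}"
            )
        arr[row, col] = max(new, 0.0)

    # -- transport ---------------------------------------------------------

    def diffuse(self) -> None:
        """N substeps of the 4-neighbour fraction kernel; walls reflect."""
        g = self.geometry
        p = g.diffusion_fraction
        for _ in range(g.diffusion_substeps):
            for met, arr in self.amounts.items():
                self.amounts[met] = _diffusion_substep(arr, p)

    def advect(self, t: int) -> dict[str, float]:
        """Shift metabolites distally; return the removed (excreted) amounts.

        ``t`` is the current timestep (the coarse lattice advects only every
        second step).  Metabolites in ``non_advected`` stay put; the contents
        of the most distal column(s) leave the system.
        """
        g = self.geometry
        removed: dict[str, float] = {}
        if g.advection_period > 1 and t % g.advection_period != 0:
            return removed
        k = g.advection_columns
        for met, arr in self.amounts.items():
            if met in self.non_advected:
                continue
            removed[met] = float(arr[:, -k:].sum())
            arr[:, k:] = arr[:, :-k]
            arr[:, :k] = 0.0
        return removed

    def feed(self, schedule: FeedSchedule, t: int) -> None:
        """Insert the scheduled nutrients when ``t`` is on the feed period."""
        if t % schedule.period != 0:
            return
        g = self.geometry
        ncols = min(schedule.columns, g.width)
        per_site = 1.0 / (ncols * g.height)
        for met, amount in schedule.composition.items():
            if met in self.unlimited or amount == 0:
                continue
            self._array(met)[:, :ncols] += amount * per_site

    def init_oxygen(self, amount: float, met: str = "o2_e") -> None:
        """Place the initial oxygen bolus uniformly (once, at t = 0)."""
        if amount < 0:
            raise ValueError("initial oxygen amount must be non-negative")
        if amount > 0:
            self._array(met)[:] = amount

    def well_mixed_redistribute(self) -> None:
        """Divide every metabolite's lattice total equally over all sites."""
        n = self.geometry.n_sites
        for met, arr in self.amounts.items():
            arr[:] = arr.sum() / n

    def copy(self) -> "MetaboliteField":
        new = MetaboliteField(self.geometry, self.unlimited, self.non_advected)
        new.amounts = {m: a.copy() for m, a in self.amounts.items()}
        return new

    def to_frame(self, nonzero_only: bool = True):
        """Tidy snapshot: one row per (row, col, metabolite) with µmol."""
        import pandas as pd

        rows = []
        for met in sorted(self.amounts):
            arr = self.amounts[met]
            idx = np.argwhere(arr != 0.0) if nonzero_only else np.argwhere(
                np.ones_like(arr, dtype=bool)
            )
            for r, c in idx:
                rows.append(
                    {"row": int(r), "col": int(c), "metabolite": met,
                     "umol": float(arr[r, c])}
                )
        return pd.DataFrame(rows, columns=["row", "col", "metabolite", "umol"])

    def to_csv(self, path: str, nonzero_only: bool = True) -> None:
        self.to_frame(nonzero_only).to_csv(path, index=False)


def _diffusion_substep(arr: np.ndarray, p: float) -> np.ndarray:
    """One substep: each site sends fraction p to each existing neighbour."""
    out = arr.copy()
    # vertical
    out[:-1, :] -= p * arr[:-1, :]
    out[1:, :] += p * arr[:-1, :]
    out[1:, :] -= p * arr[1:, :]
    out[:-1, :] += p * arr[1:, :]
    # horizontal
    out[:, :-1] -= p * arr[:, :-1]
    out[:, 1:] += p * arr[:, :-1]
    out[:, 1:] -= p * arr[:, 1:]
    out[:, :-1] += p * arr[:, 1:]
    return out


# spec-surface wrappers ------------------------------------------------------


def diffuse(field: MetaboliteField) -> MetaboliteField:
    field.diffuse()
    return field


def advect(field: MetaboliteField, t: int = 0) -> dict[str, float]:
    return field.advect(t)


def feed(field: MetaboliteField, schedule: FeedSchedule, t: int) -> MetaboliteField:
    field.feed(schedule, t)
    return field


def init_oxygen(field: MetaboliteField, amount: float) -> MetaboliteField:
    field.init_oxygen(amount)
    return field


def well_mixed_redistribute(field: MetaboliteField) -> MetaboliteField:
    field.well_mixed_redistribute()
    return field


# ---------------------------------------------------------------------------
# transport observables
# ---------------------------------------------------------------------------


def tracer_transit_hours(
    geometry: Optional[LatticeGeometry] = None,
    max_steps: int = 20_000,
    mass_tolerance: float = 1e-9,
) -> float:
    """Removal-weighted mean exit time of a proximally fed tracer pulse.

    A unit pulse of an inert tracer is fed into the first six columns of a
    metabolite-only lattice; default diffusion and advection (with distal
    removal) then run until the pulse has left the system.  The mean exit
    timestep, weighted by the removed mass, is converted to hours.
    """
    g = geometry or default_geometry()
    field = MetaboliteField(g, unlimited=(), non_advected=())
    field.feed(FeedSchedule({"tracer": 1.0}, period=max_steps + 1, columns=g.n_feed_columns), 0)
    total = field.total("tracer")
    weighted = 0.0
    removed_total = 0.0
    for t in range(max_steps):
        field.diffuse()
        removed = field.advect(t).get("tracer", 0.0)
        weighted += removed * (t + 1)
        removed_total += removed
        if field.total("tracer") < mass_tolerance * total:
            break
    mean_steps = weighted / removed_total
    return mean_steps * g.timestep_s / 3600.0


def kernel_displacement_variance(geometry: Optional[LatticeGeometry] = None) -> float:
    """Per-timestep single-axis displacement variance of the diffusion kernel,
    in cm^2, measured by applying the actual kernel to a point mass.

    With N substeps of fraction p and site side L the analytic value is
    ``2 N p L^2``; this routine computes it from the implemented kernel so
    the number reflects the code, not the formula.
    """
    g = geometry or default_geometry()
    # a point mass in the middle of a patch large enough that no mass
    # reaches the walls within one timestep
    span = 2 * g.diffusion_substeps + 3
    arr = np.zeros((2 * span + 1, 2 * span + 1))
    arr[span, span] = 1.0
    for _ in range(g.diffusion_substeps):
        arr = _diffusion_substep(arr, g.diffusion_fraction)
    x = (np.arange(arr.shape[1]) - span) * g.site_side_cm
    w = arr.sum(axis=0)  # marginal over the transverse axis
    mean = float((w * x).sum())
    return float((w * (x - mean) ** 2).sum())


def effective_diffusion_cm2_s(geometry: Optional[LatticeGeometry] = None) -> float:
    """Effective diffusion coefficient D = var / (2 dt) of the mixing kernel."""
    g = geometry or default_geometry()
    return kernel_displacement_variance(g) / (2.0 * g.timestep_s)
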