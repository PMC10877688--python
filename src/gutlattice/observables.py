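"""Simulation output: abundance records, cross-feeding flux networks,
persistence counts, and single-timestep growth assays.

The flux network mirrors the figure convention of the underlying model:
nodes are species and (lattice-summed) metabolite pools; a directed edge
species -> pool carries the secretion flux of that metabolite summed over a
trailing window (60 timesteps by default), multiplied by the metabolite's
carbon content, in umol atomic carbon; pool -> species edges carry uptake
likewise.  Edges below the 100 umol-C threshold are dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .fba_core import FbaProblem, FbaSolution, solve
from .gem_io import GemModel
from .synthetic_fixtures import FIXTURE_CARBON

__all__ = [
    "AbundanceRecorder",
    "FluxRecorder",
    "flux_network",
    "network_edge_table",
    "butyrate_persistence",
    "growth_assay",
    "load_composition_csv",
    "DEFAULT_WINDOW",
    "DEFAULT_CARBON_THRESHOLD",
]

DEFAULT_WINDOW = 60
DEFAULT_CARBON_THRESHOLD = 100.0  # umol atomic carbon


def load_composition_csv(path: str) -> dict[str, int]:
    """Element-composition table: two-column CSV (metabolite id, C atoms)."""
    out: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            out[row[0].strip()] = int(row[1])
    return out


class AbundanceRecorder:
    """Per-timestep total cells per species, plus relative abundances."""

    def __init__(self, species: Sequence[str]):
        self.species = list(species)
        self._rows: list[dict] = []

    def record(self, t: int, totals: Mapping[str, float]) -> None:
        row = {"t": t}
        row.update({s: float(totals.get(s, 0.0)) for s in self.species})
        self._rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=["t", *self.species])

    def relative(self) -> pd.DataFrame:
        df = self.frame().set_index("t")
        total = df.sum(axis=1)
        rel = df.div(total.replace(0.0, np.nan), axis=0).fillna(0.0)
        return rel.reset_index()

    def final_totals(self) -> dict[str, float]:
        if not self._rows:
            return {s: 0.0 for s in self.species}
        last = self._rows[-1]
        return {s: last[s] for s in self.species}


class FluxRecorder:
    """Lattice-total exchange fluxes per species, metabolite and timestep.

    Stores umol (per-unit fluxes scaled by the population units that
    produced them), so window sums are directly comparable with the
    environment's bookkeeping.
    """

    def __init__(self) -> None:
        self._uptake: dict[tuple[int, str, str], float] = {}
        self._secretion: dict[tuple[int, str, str], float] = {}

    def record(self, t: int, species: str, sol: FbaSolution, B_u: float) -> None:
        for met, f in sol.uptake.items():
            key = (t, species, met)
            self._uptake[key] = self._uptake.get(key, 0.0) + f * B_u
        for met, f in sol.secretion.items():
            key = (t, species, met)
            self._secretion[key] = self._secretion.get(key, 0.0) + f * B_u

    def frame(self) -> pd.DataFrame:
        rows = []
        keys = sorted(set(self._uptake) | set(self._secretion))
        for t, species, met in keys:
            rows.append(
                {
                    "t": t,
                    "species": species,
                    "metabolite": met,
                    "uptake_umol": self._uptake.get((t, species, met), 0.0),
                    "secretion_umol": self._secretion.get((t, species, met), 0.0),
                }
            )
        return pd.DataFrame(
            rows, columns=["t", "species", "metabolite", "uptake_umol", "secretion_umol"]
        )


def flux_network(
    records: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_CARBON_THRESHOLD,
    carbon: Optional[Mapping[str, int]] = None,
    t_end: Optional[int] = None,
    combine_lactate: bool = False,
) -> nx.DiGraph:
    """Carbon-weighted cross-feeding network over the trailing window.

    ``records`` is a FluxRecorder frame.  Edge weights are umol atomic
    carbon (flux x carbon content summed over the last ``window`` steps);
    edges below ``threshold`` are dropped.  With ``combine_lactate`` the L-
    and D-lactate pools merge into one node.
    """
    carbon = dict(FIXTURE_CARBON if carbon is None else carbon)
    if records.empty:
        return nx.DiGraph()
    t_end = int(records["t"].max()) if t_end is None else t_end
    sel = records[(records["t"] > t_end - window) & (records["t"] <= t_end)]
    graph = nx.DiGraph()
    grouped = sel.groupby(["species", "metabolite"])[
        ["uptake_umol", "secretion_umol"]
    ].sum()
    for (species, met), row in grouped.iterrows():
        if met not in carbon:
            raise KeyError(f"metabolite {met!r} missing from composition table")
        pool = met
        if combine_lactate and met in ("lac_L_e", "lac_D_e"):
            pool = "lac_e"
        c = carbon[met]
        up_c = row["uptake_umol"] * c
        sec_c = row["secretion_umol"] * c
        if sec_c >= threshold:
            w = graph.get_edge_data(species, pool, {"weight": 0.0})["weight"]
            graph.add_edge(species, pool, weight=w + sec_c)
        if up_c >= threshold:
            w = graph.get_edge_data(pool, species, {"weight": 0.0})["weight"]
            graph.add_edge(pool, species, weight=w + up_c)
    return graph


def network_edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "umol_carbon": d["weight"]}
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "umol_carbon"])


def write_graphml(graph: nx.DiGraph, path: str) -> None:
    """Export the cross-feeding network as GraphML."""
    nx.write_graphml(graph, path)


def butyrate_persistence(
    final_abundances: Iterable[Mapping[str, float]],
    producer_species: Iterable[str],
    cutoff: float = 1e10,
) -> int:
    """Count runs whose combined butyrate-producer abundance exceeds the
    cutoff at the end of the run."""
    producers = set(producer_species)
    count = 0
    for totals in final_abundances:
        unknown = producers - set(totals)
        if unknown:
            raise KeyError(f"unknown species in producer group: {sorted(unknown)}")
        combined = sum(totals[s] for s in producers)
        if combined > cutoff:
            count += 1
    return count


def growth_assay(
    gem: GemModel,
    substrate_spec: Mapping[str, object],
    B: float = 5e9,
    site_volume_ml: float = 0.05,
    a: float = 2.0,
    unlimited_water: str = "h2o_e",
) -> float:
    """Per-timestep growth on a defined substrate mix (single FBA solve).

    ``substrate_spec`` maps metabolite ids to a concentration in umol/mL or
    the string ``"unlimited"``.  A population of ``B`` cells has access to
    one lattice site's volume; the returned value is the relative growth
    ``dB / B`` over one timestep.
    """
    env: dict[str, float] = {}
    unlimited = {unlimited_water}
    for met, conc in substrate_spec.items():
        if conc == "unlimited":
            unlimited.add(met)
            env[met] = np.inf
        else:
            env[met] = float(conc) * site_volume_ml
    problem = FbaProblem(
        gem,
        env_amounts=env,
        population_units=B / 1e10,
        enzymatic_constraint=a,
        unlimited=frozenset(unlimited),
    )
    sol = solve(problem)
    return sol.growth_rate
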