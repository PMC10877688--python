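"""Synthetic toy GEMs with analytically known optima.

These generators stand in for full-size gut-bacterium reconstructions so the
whole stack — SBML reading, normalization, constrained FBA, the spatial
simulation — is testable at desk scale.  Every toy model follows the same
dialect as the real inputs (``EX_`` exchange prefixes, ``_e``/``_c``
compartment suffixes, reversible exchanges) and is serialized through SBML
so the real reader is exercised.

A toy model is a set of *pathways*.  Each pathway turns substrate(s) into
extracellular products plus ATP through a chain of irreversible internal
reactions.  ATP is a virtual boundary metabolite (``atp_c``): its net
production rate is the FBA objective and it carries no mass.  For a single
pathway consuming one substrate unit the LP optimum under the enzymatic
constraint ``a`` has the closed form

    ATP* = a * yield / (uptake + internal + secretion fluxes per substrate)

i.e. ``a`` times the pathway's ATP yield per unit of summed flux; with
several pathways the optimum is the best achievable ratio, which the flux
cap then scales (models whose pathways can chain — one pathway consuming
another's product — may beat any single ratio; the LP finds this).

:func:`make_crossfeeding_consortium` builds the three-species community used
by the competition experiments: a *bifido*-like primary degrader (lactose
and 2'-FL fermenter whose 2'-FL pathway yields propane-1,2-diol), a
*producer* (butyrate producer cross-feeding on lactate and on 1,2-PD +
acetate), and a *competitor* that consumes lactose and lactate faster than
the producer but cannot touch 1,2-PD.  The yields are fixed constants of the
generator, chosen so that (i) the competitor's ATP-per-flux on lactate
exceeds the producer's, and (ii) the producer's ATP-per-flux on
1,2-PD/acetate exceeds every competitor option, mirroring the niche
structure that lets 2'-FL rescue butyrate producers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .gem_io import GemModel, GemParseError, load_gem
from .lattice_env import FeedSchedule

__all__ = [
    "PathwaySpec",
    "ToyGemSpec",
    "make_toy_gem",
    "make_cobra_model",
    "write_sbml",
    "make_crossfeeding_consortium",
    "consortium_feeds",
    "pathway_yield_per_flux",
    "optimal_atp_single_pathway",
    "FIXTURE_CARBON",
]

ATP = "atp_c"

#: carbon content (atoms per molecule) of every metabolite the fixtures use
FIXTURE_CARBON: dict[str, int] = {
    "lcts_e": 12,
    "2fl_e": 18,
    "gosdp3_e": 18,
    "gosdp4_e": 24,
    "gosdp5_e": 30,
    "glc_D_e": 6,
    "gal_e": 6,
    "fuc_L_e": 6,
    "lac_L_e": 3,
    "ac_e": 2,
    "ppd12_e": 3,
    "but_e": 4,
    "co2_e": 1,
    "for_e": 1,
    "h2o_e": 0,
    "o2_e": 0,
    "h2_e": 0,
    ATP: 0,  # virtual energy bookkeeping species
}


@dataclass(frozen=True)
class PathwaySpec:
    """One catabolic route: substrates -> products + ATP.

    ``substrates`` and ``products`` map extracellular metabolite ids to
    positive stoichiometric coefficients.  ``n_internal`` chains the
    conversion over that many internal reactions (intermediates carry the
    whole carbon skeleton).  ``atp_yield`` is credited on the final step.
    """

    name: str
    substrates: Mapping[str, float]
    products: Mapping[str, float]
    atp_yield: float
    n_internal: int = 1

    def __post_init__(self) -> None:
        if self.n_internal < 1:
            raise ValueError("pathways need at least one internal reaction")
        if not self.substrates:
            raise ValueError("pathways need at least one substrate")
        carbon_in = sum(
            FIXTURE_CARBON.get(m, 0) * s for m, s in self.substrates.items()
        )
        carbon_out = sum(
            FIXTURE_CARBON.get(m, 0) * s for m, s in self.products.items()
        )
        if carbon_in != carbon_out:
            raise GemParseError(
                f"pathway {self.name!r} does not conserve carbon: "
                f"{carbon_in} in vs {carbon_out} out"
            )

    @property
    def flux_per_turn(self) -> float:
        """Summed flux per unit pathway flux when all products are secreted:
        substrate uptakes + internal chain + product secretions."""
        return (
            sum(self.substrates.values())
            + self.n_internal
            + sum(self.products.values())
        )


@dataclass(frozen=True)
class ToyGemSpec:
    name: str
    pathways: tuple[PathwaySpec, ...]

    @property
    def exchange_metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pathways:
            for m in (*p.substrates, *p.products):
                seen.setdefault(m)
        return list(seen)


def pathway_yield_per_flux(p: PathwaySpec) -> float:
    """ATP per unit of summed flux for one pathway in isolation."""
    return p.atp_yield / p.flux_per_turn


def optimal_atp_single_pathway(p: PathwaySpec, a: float) -> float:
    """Closed-form LP optimum when only this pathway runs: a * yield/flux."""
    return a * pathway_yield_per_flux(p)


def make_cobra_model(spec: ToyGemSpec):
    """Build the toy model as a cobra.Model in the AGORA-style dialect."""
    import cobra

    model = cobra.Model(spec.name)
    mets: dict[str, "cobra.Metabolite"] = {}

    def met(mid: str) -> "cobra.Metabolite":
        if mid not in mets:
            comp = mid.rsplit("_", 1)[-1]
            mets[mid] = cobra.Metabolite(mid, compartment=comp)
        return mets[mid]

    # reversible exchange for every extracellular metabolite
    for mid in spec.exchange_metabolites:
        ex = cobra.Reaction(f"EX_{mid}", lower_bound=-1000.0, upper_bound=1000.0)
        ex.add_metabolites({met(mid): -1.0})
        model.add_reactions([ex])

    for p in spec.pathways:
        carbon = sum(FIXTURE_CARBON.get(m, 0) * s for m, s in p.substrates.items())
        prev: Optional[str] = None
        for k in range(p.n_internal):
            rxn = cobra.Reaction(
                f"{p.name}_r{k + 1}", lower_bound=0.0, upper_bound=1000.0
            )
            stoich: dict = {}
            if k == 0:
                for m, s in p.substrates.items():
                    stoich[met(m)] = -s
            else:
                stoich[met(prev)] = -1.0
            if k == p.n_internal - 1:
                for m, s in p.products.items():
                    stoich[met(m)] = stoich.get(met(m), 0.0) + s
                stoich[met(ATP)] = p.atp_yield
            else:
                inter = f"{p.name}_i{k + 1}_c"
                FIXTURE_CARBON.setdefault(inter, carbon)
                stoich[met(inter)] = 1.0
                prev = inter
            rxn.add_metabolites(stoich)
            model.add_reactions([rxn])
    return model


def make_toy_gem(spec: ToyGemSpec) -> GemModel:
    """Generate the toy model and normalize it through the real reader."""
    return load_gem(
        make_cobra_model(spec),
        species_id=spec.name,
        objective_metabolite=ATP,
        boundary_metabolites={ATP},
    )


def write_sbml(spec: ToyGemSpec, path: str) -> None:
    """Serialize a toy model as SBML Level 3 (fbc)."""
    from cobra.io import write_sbml_model

    write_sbml_model(make_cobra_model(spec), path)


# ---------------------------------------------------------------------------
# the cross-feeding consortium
# ---------------------------------------------------------------------------

BIFIDO_SPEC = ToyGemSpec(
    "bifido",
    (
        # bifid-shunt stoichiometry: lactose (2 hexoses) -> 3 acetate + 2 lactate
        PathwaySpec(
            "bif_lcts", {"lcts_e": 1}, {"ac_e": 3, "lac_L_e": 2}, atp_yield=5.0
        ),
        # 2'-FL: the lactose moiety follows the shunt; the fucose moiety is
        # reduced to propane-1,2-diol.  The high ATP yield makes 2'-FL the
        # degrader's preferred, exclusive substrate, so the 1,2-PD flux
        # appears as soon as 2'-FL is fed.
        PathwaySpec(
            "bif_2fl",
            {"2fl_e": 1},
            {"ac_e": 3, "lac_L_e": 2, "ppd12_e": 2},
            atp_yield=9.0,
        ),
    ),
)

PRODUCER_SPEC = ToyGemSpec(
    "producer",
    (
        # lactate route: slightly *worse* ATP-per-flux than the competitor's
        # lactate oxidation, so the producer loses the shared lactate niche
        PathwaySpec(
            "but_lac", {"lac_L_e": 2}, {"but_e": 1, "co2_e": 2}, atp_yield=2.2
        ),
        # 1,2-PD + acetate route: the best yield-per-flux in the consortium,
        # and exclusive to the producer — the 2'-FL rescue channel
        PathwaySpec(
            "but_ppd",
            {"ppd12_e": 1, "ac_e": 1},
            {"but_e": 1, "co2_e": 1},
            atp_yield=6.0,
        ),
    ),
)

COMPETITOR_SPEC = ToyGemSpec(
    "competitor",
    (
        # homofermentative lactose use plus lactate oxidation; the LP may
        # chain the two (consume its own lactate) for extra yield
        PathwaySpec("cmp_lcts", {"lcts_e": 1}, {"lac_L_e": 4}, atp_yield=4.0),
        PathwaySpec(
            "cmp_lac", {"lac_L_e": 1}, {"ac_e": 1, "co2_e": 1}, atp_yield=1.5
        ),
    ),
)


def make_crossfeeding_consortium() -> dict[str, GemModel]:
    """Toy degrader / butyrate producer / competitor trio.

    Yield-per-flux ratios at generation time (fixed constants of the
    generator, documented here rather than tuned per test):

    =========== ============ =====================
    species      substrate    ATP per summed flux
    =========== ============ =====================
    bifido       lactose      5/7   = 0.714
    bifido       2'-FL        9/9   = 1.000 (exclusive)
    competitor   lactose      4/6   = 0.667 (0.714 when chaining lactate)
    competitor   lactate      1.5/4 = 0.375
    producer     lactate      2.2/6 = 0.367
    producer     1,2-PD+ac    6/5   = 1.200 (exclusive)
    =========== ============ =====================

    The orderings that carry the competition motif: the competitor beats the
    producer on lactate (0.375 > 0.367) and matches the degrader on lactose,
    while the producer's 1,2-PD route is the best ratio in the system but
    exists only when the degrader ferments 2'-FL.
    """
    return {
        spec.name: make_toy_gem(spec)
        for spec in (BIFIDO_SPEC, PRODUCER_SPEC, COMPETITOR_SPEC)
    }


def consortium_feeds(
    n_sites: int = 80,
    reference_sites: int = 1800,
    amount: float = 211.0,
    period: int = 20,
    reference_period: int = 60,
) -> dict[str, FeedSchedule]:
    """The two feeding regimes of the competition fixture.

    The full-scale regime feeds 211 umol per nutrient every 60 timesteps
    into a 1800-site lattice whose transit time (~220 steps) spans several
    feeding intervals, so nutrients are present continuously.  On a short
    fixture lattice the transit takes only ~20 steps; feeding every 60 would
    leave the system in famine two-thirds of the time, an artifact of the
    truncated geometry rather than a feature of the model.  The fixture
    feeds therefore pulse once per transit time (every 20 steps) at a
    proportionally smaller dose, preserving both the per-site time-averaged
    inflow of the full model and its always-fed character.
    """
    scaled = amount * (n_sites / reference_sites) * (period / reference_period)
    return {
        "lactose": FeedSchedule({"lcts_e": scaled}, period=period),
        "lactose+2fl": FeedSchedule(
            {"lcts_e": scaled, "2fl_e": scaled}, period=period
        ),
    }
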