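"""Reading and normalizing genome-scale metabolic models (GEMs).

SBML documents (AGORA dialect) are read through cobrapy and converted to the
internal :class:`GemModel` representation used by the simulator:

* every reversible reaction is split into two irreversible reactions, so all
  fluxes are non-negative;
* reactions flagged as ``exchange``, ``sink`` or ``demand`` (by id prefix, by
  SBML boundary structure, or by an explicit override list) are recorded as
  exchange reactions; the split direction that *produces* the exchanged
  metabolite is the uptake reaction, the direction that consumes it is the
  secretion reaction;
* a stoichiometric matrix ``S`` (metabolites x reactions) is assembled, with
  designated *boundary* metabolites excluded from the steady-state rows.

A declarative :class:`ModelPatch` mechanism applies ordered curation actions
(add/remove reactions, set bounds, block uptake of a metabolite), and
:func:`add_prebiotic_pathways` adds the GOS / 2'-FL digestion machinery
(extracellular stepwise cleavage of GOS chains, ABC transport, intracellular
hydrolysis) to a designated consumer model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "ReactionSpec",
    "GemModel",
    "ModelPatch",
    "PatchAction",
    "GemParseError",
    "PatchError",
    "ConfigurationError",
    "load_gem",
    "apply_patch",
    "add_prebiotic_pathways",
    "validate_gem",
    "PrebioticIds",
]


class GemParseError(ValueError):
    """Malformed or empty SBML input."""


class PatchError(ValueError):
    """A patch action refers to a missing element or would create a duplicate."""


class ConfigurationError(ValueError):
    """The model lacks required configuration (e.g. no objective)."""


#: AGORA/BiGG id prefixes that mark a reaction as environment-facing.
EXCHANGE_PREFIXES = ("EX_", "DM_", "sink_", "SINK_", "Sink_", "SK_")

#: suffix appended to the reverse half of a split reversible reaction
REVERSE_SUFFIX = "_rev"

_COMPARTMENT_RE = re.compile(r"[\[(]([a-zA-Z0-9]+)[\])]$")


def canonical_met_id(met_id: str, compartment: Optional[str] = None) -> str:
    """Normalize a metabolite id to BiGG-style ``name_compartment``.

    AGORA releases encode the compartment as ``lcts[e]`` or ``lcts(e)``;
    both are rewritten to ``lcts_e``.  Ids already in suffix form pass
    through unchanged.  (The SBML ``M_``/``R_`` sid prefixes are already
    removed by the cobra reader.)
    """
    m = _COMPARTMENT_RE.search(met_id)
    if m:
        return f"{met_id[: m.start()]}_{m.group(1)}"
    if compartment and not met_id.endswith(f"_{compartment}"):
        return f"{met_id}_{compartment}"
    return met_id


def canonical_rxn_id(rxn_id: str) -> str:
    m = _COMPARTMENT_RE.search(rxn_id)
    if m:
        return f"{rxn_id[: m.start()]}_{m.group(1)}"
    return rxn_id


@dataclass(frozen=True)
class ReactionSpec:
    """One irreversible reaction of a normalized model.

    Stoichiometry maps metabolite ids to signed coefficients (negative =
    consumed).  Bounds are fluxes in umol per timestep per population unit
    and are non-negative after normalization.  ``source`` records whether
    the reaction came from the GEM itself or from a patch.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = float("inf")
    is_exchange: bool = False
    source: str = "gem"

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise GemParseError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound < 0:
            raise GemParseError(
                f"reaction {self.id!r} has negative lower bound after normalization"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise GemParseError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def exchanged_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"{self.id!r} is not an exchange reaction")
        return next(iter(self.stoichiometry))


@dataclass
class GemModel:
    """Normalized, irreversible stoichiometric model of one (sub)species.

    ``exchange_index`` maps each exchanged metabolite to its
    ``(uptake_reaction_id, secretion_reaction_id)`` pair (either may be
    ``None`` when the model can only move the metabolite one way).

    The FBA objective is either a single ATP-producing/demand reaction
    (``objective_reaction``) or the net production rate of a designated
    *boundary* metabolite (``objective_metabolite``), which is excluded from
    the steady-state constraint.  Exactly one of the two must be set.
    """

    species_id: str
    reactions: dict[str, ReactionSpec]
    objective_reaction: Optional[str] = None
    objective_metabolite: Optional[str] = None
    boundary_metabolites: frozenset[str] = frozenset()
    #: exchange reactions that couple to the environment pools (EX_ class);
    #: demand/sink classes stay in the LP but do not touch the site pools.
    environment_coupled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._matrix_cache: Optional[tuple] = None
        self._solver_cache: dict = {}

    # -- derived structure -------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                seen.setdefault(met)
        return list(seen)

    @property
    def exchange_index(self) -> dict[str, tuple[Optional[str], Optional[str]]]:
        """metabolite -> (uptake reaction id, secretion reaction id)."""
        index: dict[str, tuple[Optional[str], Optional[str]]] = {}
        for rxn in self.reactions.values():
            if not rxn.is_exchange:
                continue
            met = rxn.exchanged_metabolite
            coeff = rxn.stoichiometry[met]
            up, sec = index.get(met, (None, None))
            if coeff > 0:
                up = rxn.id
            else:
                sec = rxn.id
            index[met] = (up, sec)
        return index

    def stoichiometric_matrix(self):
        """Sparse S (metabolites x reactions) and the metabolite row order.

        Boundary metabolites are included as rows so that column counts and
        elemental audits see the full stoichiometry; the FBA layer drops the
        boundary rows from the steady-state constraint.
        """
        if self._matrix_cache is None:
            mets = self.metabolite_ids
            met_pos = {m: i for i, m in enumerate(mets)}
            rows, cols, vals = [], [], []
            for j, rxn in enumerate(self.reactions.values()):
                for met, coeff in rxn.stoichiometry.items():
                    rows.append(met_pos[met])
                    cols.append(j)
                    vals.append(float(coeff))
            S = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(len(mets), len(self.reactions))
            )
            self._matrix_cache = (S, mets)
        return self._matrix_cache

    def copy(self) -> "GemModel":
        return GemModel(
            species_id=self.species_id,
            reactions=dict(self.reactions),
            objective_reaction=self.objective_reaction,
            objective_metabolite=self.objective_metabolite,
            boundary_metabolites=self.boundary_metabolites,
            environment_coupled=self.environment_coupled,
        )


def _is_exchange_like(rxn_id: str, override: Iterable[str] = ()) -> bool:
    return rxn_id in set(override) or any(
        rxn_id.startswith(p) for p in EXCHANGE_PREFIXES
    )


def _is_environment_coupled(rxn_id: str) -> bool:
    # only the EX_ class exchanges mass with the lumen pools by default
    return rxn_id.startswith("EX_")


def _split_reaction(
    rxn_id: str,
    stoich: dict[str, float],
    lb: float,
    ub: float,
    is_exchange: bool,
    source: str = "gem",
) -> list[ReactionSpec]:
    """Split a (possibly reversible) reaction into irreversible specs."""
    specs: list[ReactionSpec] = []
    fwd_ub = max(ub, 0.0)
    if fwd_ub > 0 or lb >= 0:
        specs.append(
            ReactionSpec(
                id=rxn_id,
                stoichiometry=dict(stoich),
                lower_bound=max(lb, 0.0),
                upper_bound=fwd_ub,
                is_exchange=is_exchange,
                source=source,
            )
        )
    if lb < 0:
        specs.append(
            ReactionSpec(
                id=rxn_id + REVERSE_SUFFIX,
                stoichiometry={m: -c for m, c in stoich.items()},
                lower_bound=0.0,
                upper_bound=-lb,
                is_exchange=is_exchange,
                source=source,
            )
        )
    return specs


def load_gem(
    model,
    species_id: str,
    objective_reaction: Optional[str] = None,
    objective_metabolite: Optional[str] = None,
    boundary_metabolites: Iterable[str] = (),
    exchange_override: Iterable[str] = (),
) -> GemModel:
    """Read an SBML document (path or cobra.Model) into a :class:`GemModel`.

    Parameters
    ----------
    model:
        Path to an SBML Level 3 file, or an in-memory ``cobra.Model``.
    species_id:
        Identifier for the (sub)species this model represents.
    objective_reaction, objective_metabolite:
        ATP objective.  When neither is given, the cobra model's own
        objective reaction is used; if that is absent too, a
        :class:`ConfigurationError` is raised.
    boundary_metabolites:
        Metabolites exempted from the steady-state constraint (virtual
        species such as a boundary ATP pool in toy models).
    exchange_override:
        Extra reaction ids to classify as exchange regardless of prefix.
    """
    import cobra
    from cobra.io import read_sbml_model

    if isinstance(model, (str, bytes)) or hasattr(model, "__fspath__"):
        try:
            cobra_model = read_sbml_model(str(model))
        except Exception as exc:  # cobra wraps libsbml errors
            raise GemParseError(f"cannot parse SBML document {model!r}: {exc}") from exc
    elif isinstance(model, cobra.Model):
        cobra_model = model
    else:
        raise TypeError(f"expected SBML path or cobra.Model, got {type(model)!r}")

    if len(cobra_model.reactions) == 0:
        raise GemParseError(f"SBML document for {species_id!r} contains no reactions")

    cobra_objective_ids = [
        canonical_rxn_id(r.id)
        for r in cobra_model.reactions
        if r.objective_coefficient
    ]

    reactions: dict[str, ReactionSpec] = {}
    env_coupled: set[str] = set()
    for rxn in cobra_model.reactions:
        rid = canonical_rxn_id(rxn.id)
        stoich = {
            canonical_met_id(met.id, met.compartment): float(coeff)
            for met, coeff in rxn.metabolites.items()
        }
        if not stoich:
            raise GemParseError(f"reaction {rxn.id!r} has empty stoichiometry")
        is_ex = _is_exchange_like(rid, exchange_override) or (
            rxn.boundary and len(stoich) == 1
        )
        for spec in _split_reaction(
            rid, stoich, float(rxn.lower_bound), float(rxn.upper_bound), is_ex
        ):
            if spec.id in reactions:
                raise GemParseError(f"duplicate reaction id {spec.id!r} in SBML")
            reactions[spec.id] = spec
            if is_ex and _is_environment_coupled(rid):
                env_coupled.add(spec.id)

    if objective_reaction is None and objective_metabolite is None:
        if len(cobra_objective_ids) == 1:
            objective_reaction = cobra_objective_ids[0]
        else:
            raise ConfigurationError(
                f"no identifiable ATP objective for {species_id!r}: pass "
                "objective_reaction or objective_metabolite"
            )
    gem = GemModel(
        species_id=species_id,
        reactions=reactions,
        objective_reaction=objective_reaction,
        objective_metabolite=objective_metabolite,
        boundary_metabolites=frozenset(boundary_metabolites),
        environment_coupled=frozenset(env_coupled),
    )
    validate_gem(gem)
    return gem


def validate_gem(gem: GemModel) -> None:
    """Check the GemModel invariants; raise on violation."""
    if not gem.reactions:
        raise GemParseError(f"model {gem.species_id!r} has no reactions")
    if (gem.objective_reaction is None) == (gem.objective_metabolite is None):
        raise ConfigurationError(
            f"model {gem.species_id!r} must set exactly one of "
            "objective_reaction / objective_metabolite"
        )
    if gem.objective_reaction is not None and gem.objective_reaction not in gem.reactions:
        raise ConfigurationError(
            f"objective reaction {gem.objective_reaction!r} not in model "
            f"{gem.species_id!r}"
        )
    mets = set(gem.metabolite_ids)
    if gem.objective_metabolite is not None:
        if gem.objective_metabolite not in mets:
            raise ConfigurationError(
                f"objective metabolite {gem.objective_metabolite!r} not in model"
            )
        if gem.objective_metabolite not in gem.boundary_metabolites:
            raise ConfigurationError(
                "an objective metabolite must be declared boundary "
                "(its steady-state row would otherwise force zero production)"
            )
    S, met_order = gem.stoichiometric_matrix()
    assert S.shape[1] == len(gem.reactions)
    for met, (up, sec) in gem.exchange_index.items():
        for rid in (up, sec):
            if rid is not None and rid not in gem.reactions:
                raise GemParseError(f"exchange index refers to missing reaction {rid!r}")


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

_VERBS = ("add_reaction", "remove_reaction", "set_bound", "block_uptake")


@dataclass(frozen=True)
class PatchAction:
    verb: str
    payload: object

    def __post_init__(self) -> None:
        if self.verb not in _VERBS:
            raise PatchError(f"unknown patch verb {self.verb!r}")


@dataclass(frozen=True)
class ModelPatch:
    """Ordered curation actions targeting one species' model."""

    target_species: str
    actions: tuple[PatchAction, ...] = ()

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelPatch":
        """Parse the YAML/JSON patch document form.

        ``{"target_species": "x", "actions": [{"block_uptake": "lcts_e"},
        {"set_bound": {"id": "R1", "lower": 0, "upper": 5}}, ...]}``
        """
        actions = []
        for entry in doc.get("actions", ()):
            if len(entry) != 1:
                raise PatchError(f"patch action must have one verb: {entry!r}")
            verb, payload = next(iter(entry.items()))
            if verb == "add_reaction":
                payload = ReactionSpec(
                    id=payload["id"],
                    stoichiometry=dict(payload["stoichiometry"]),
                    lower_bound=float(payload.get("lower_bound", 0.0)),
                    upper_bound=float(payload.get("upper_bound", float("inf"))),
                    is_exchange=bool(payload.get("is_exchange", False)),
                    source="patch",
                )
            actions.append(PatchAction(verb, payload))
        return cls(target_species=doc["target_species"], actions=tuple(actions))


def apply_patch(gem: GemModel, patch: ModelPatch) -> GemModel:
    """Apply a patch, returning a new model; the input model is unchanged."""
    if patch.target_species != gem.species_id:
        raise PatchError(
            f"patch targets {patch.target_species!r}, model is {gem.species_id!r}"
        )
    new = gem.copy()
    for action in patch.actions:
        if action.verb == "add_reaction":
            spec: ReactionSpec = action.payload  # type: ignore[assignment]
            if spec.id in new.reactions:
                raise PatchError(f"add_reaction: duplicate reaction id {spec.id!r}")
            spec = replace(spec, source="patch")
            new.reactions[spec.id] = spec
            if spec.is_exchange and _is_environment_coupled(spec.id):
                new.environment_coupled = new.environment_coupled | {spec.id}
        elif action.verb == "remove_reaction":
            rid = str(action.payload)
            if rid not in new.reactions:
                raise PatchError(f"remove_reaction: unknown reaction id {rid!r}")
            del new.reactions[rid]
            new.environment_coupled = new.environment_coupled - {rid}
        elif action.verb == "set_bound":
            payload = action.payload
            rid, lo, hi = payload["id"], payload["lower"], payload["upper"]  # type: ignore[index]
            if rid not in new.reactions:
                raise PatchError(f"set_bound: unknown reaction id {rid!r}")
            if lo < 0:
                raise PatchError("set_bound: bounds are non-negative after splitting")
            new.reactions[rid] = replace(
                new.reactions[rid], lower_bound=float(lo), upper_bound=float(hi),
                source="patch",
            )
        elif action.verb == "block_uptake":
            met = str(action.payload)
            up, _sec = new.exchange_index.get(met, (None, None))
            # blocking uptake of a metabolite the model cannot take up anyway
            # is vacuously satisfied
            if up is not None:
                new.reactions[up] = replace(
                    new.reactions[up], lower_bound=0.0, upper_bound=0.0,
                    source="patch",
                )
    validate_gem(new)
    return new


def block_uptake_patch(species_id: str, metabolites: Sequence[str]) -> ModelPatch:
    """Convenience: the knockout patch used by the competition experiments."""
    return ModelPatch(
        target_species=species_id,
        actions=tuple(PatchAction("block_uptake", m) for m in metabolites),
    )


# ---------------------------------------------------------------------------
# prebiotic digestion pathways
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrebioticIds:
    """Configured metabolite ids used by the prebiotic pathway additions."""

    lactose_c: str = "lcts_c"
    fucose_c: str = "fuc_L_c"
    galactose_c: str = "gal_c"
    galactose_e: str = "gal_e"
    fl2_e: str = "2fl_e"
    fl2_c: str = "2fl_c"
    gos_dp3_e: str = "gosdp3_e"
    gos_dp3_c: str = "gosdp3_c"
    gos_dp4_e: str = "gosdp4_e"
    gos_dp5_e: str = "gosdp5_e"
    #: ATP bookkeeping of the ABC transport step; AGORA-style models should
    #: override with a balanced hydrolysis stoichiometry (adp, pi, h).
    atp_cost_stoichiometry: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.atp_cost_stoichiometry is None:
            object.__setattr__(self, "atp_cost_stoichiometry", {"atp_c": -1.0})


def add_prebiotic_pathways(
    gem: GemModel, which: str, ids: PrebioticIds = PrebioticIds()
) -> GemModel:
    """Add 2'-FL or GOS digestion to a consumer model.

    2'-FL: extracellular 2'-FL species, an ABC transporter (one ATP per
    molecule by default) and an intracellular fucosidase releasing lactose
    and fucose.  GOS: DP3/DP4/DP5 chains; DP5 and DP4 are cleaved
    extracellularly, each step releasing one galactose; DP3 is taken up by an
    ABC transporter and hydrolyzed internally to lactose plus galactose.

    The patch is intended for the designated prebiotic consumer only;
    applying it requires the prerequisite metabolites (lactose, fucose or
    galactose) to already occur in the model.
    """
    mets = set(gem.metabolite_ids)
    atp_cost = dict(ids.atp_cost_stoichiometry)
    if which.upper() in ("2FL", "2'-FL", "FL"):
        for required in (ids.lactose_c, ids.fucose_c):
            if required not in mets:
                raise PatchError(
                    f"2FL pathway requires metabolite {required!r} in "
                    f"{gem.species_id!r}"
                )
        actions = [
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id=f"EX_{ids.fl2_e}{REVERSE_SUFFIX}",
                    stoichiometry={ids.fl2_e: 1.0},
                    is_exchange=True,
                    source="patch",
                ),
            ),
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id="ABC_2fl",
                    stoichiometry={ids.fl2_e: -1.0, ids.fl2_c: 1.0, **atp_cost},
                    source="patch",
                ),
            ),
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id="FUCASE_2fl",
                    stoichiometry={
                        ids.fl2_c: -1.0,
                        ids.lactose_c: 1.0,
                        ids.fucose_c: 1.0,
                    },
                    source="patch",
                ),
            ),
        ]
    elif which.upper() == "GOS":
        for required in (ids.lactose_c, ids.galactose_c):
            if required not in mets:
                raise PatchError(
                    f"GOS pathway requires metabolite {required!r} in "
                    f"{gem.species_id!r}"
                )
        actions = [
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id=f"EX_{dp}{REVERSE_SUFFIX}",
                    stoichiometry={dp: 1.0},
                    is_exchange=True,
                    source="patch",
                ),
            )
            for dp in (ids.gos_dp5_e, ids.gos_dp4_e, ids.gos_dp3_e)
        ]
        # extracellular stepwise cleavage; the released products stay in the
        # consumer's FBA problem (they cannot diffuse mid-digestion) and reach
        # the site pool only through the model's exchange fluxes
        actions += [
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id="GOSDEG_dp5",
                    stoichiometry={
                        ids.gos_dp5_e: -1.0,
                        ids.gos_dp4_e: 1.0,
                        ids.galactose_e: 1.0,
                    },
                    source="patch",
                ),
            ),
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id="GOSDEG_dp4",
                    stoichiometry={
                        ids.gos_dp4_e: -1.0,
                        ids.gos_dp3_e: 1.0,
                        ids.galactose_e: 1.0,
                    },
                    source="patch",
                ),
            ),
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id="ABC_gosdp3",
                    stoichiometry={ids.gos_dp3_e: -1.0, ids.gos_dp3_c: 1.0, **atp_cost},
                    source="patch",
                ),
            ),
            PatchAction(
                "add_reaction",
                ReactionSpec(
                    id="GOSHYD_dp3",
                    stoichiometry={
                        ids.gos_dp3_c: -1.0,
                        ids.lactose_c: 1.0,
                        ids.galactose_c: 1.0,
                    },
                    source="patch",
                ),
            ),
        ]
        if ids.galactose_e not in gem.exchange_index:
            # allow surplus extracellular galactose to return to the pool
            actions.append(
                PatchAction(
                    "add_reaction",
                    ReactionSpec(
                        id=f"EX_{ids.galactose_e}",
                        stoichiometry={ids.galactose_e: -1.0},
                        is_exchange=True,
                        source="patch",
                    ),
                )
            )
    else:
        raise ValueError(f"unknown prebiotic pathway {which!r}")

    return apply_patch(gem, ModelPatch(gem.species_id, tuple(actions)))
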