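"""SBML loading, normalization, patches and prebiotic pathway additions."""

import math

import pytest

from gutlattice.fba_core import FbaProblem, solve, uptake_bounds
from gutlattice.gem_io import (
    ConfigurationError,
    GemParseError,
    ModelPatch,
    PatchAction,
    PatchError,
    PrebioticIds,
    ReactionSpec,
    add_prebiotic_pathways,
    apply_patch,
    block_uptake_patch,
    canonical_met_id,
    load_gem,
    validate_gem,
)
from gutlattice.synthetic_fixtures import (
    BIFIDO_SPEC,
    PathwaySpec,
    ToyGemSpec,
    make_cobra_model,
    make_toy_gem,
    write_sbml,
)


def _cobra_toy(reversible=True):
    """One reversible reaction A <-> B plus exchanges, as a cobra model."""
    import cobra

    m = cobra.Model("toy")
    a = cobra.Metabolite("a_e", compartment="e")
    b = cobra.Metabolite("b_e", compartment="e")
    ex_a = cobra.Reaction("EX_a_e", lower_bound=-10, upper_bound=10)
    ex_a.add_metabolites({a: -1})
    ex_b = cobra.Reaction("EX_b_e", lower_bound=-10, upper_bound=10)
    ex_b.add_metabolites({b: -1})
    r = cobra.Reaction("R_ab", lower_bound=-5 if reversible else 0, upper_bound=5)
    r.add_metabolites({a: -1, b: 1})
    m.add_reactions([ex_a, ex_b, r])
    m.objective = "R_ab"
    return m


class TestLoad:
    def test_reversible_reaction_is_split(self):
        gem = load_gem(_cobra_toy(), "toy", objective_reaction="R_ab")
        assert "R_ab" in gem.reactions and "R_ab_rev" in gem.reactions
        fwd, rev = gem.reactions["R_ab"], gem.reactions["R_ab_rev"]
        assert fwd.stoichiometry == {"a_e": -1, "b_e": 1}
        assert rev.stoichiometry == {"a_e": 1, "b_e": -1}
        assert fwd.upper_bound == 5 and rev.upper_bound == 5
        assert all(r.lower_bound >= 0 for r in gem.reactions.values())

    def test_exchange_reactions_are_indexed_by_metabolite(self):
        gem = load_gem(_cobra_toy(), "toy", objective_reaction="R_ab")
        up, sec = gem.exchange_index["a_e"]
        assert up == "EX_a_e_rev" and sec == "EX_a_e"

    def test_sbml_roundtrip_through_file(self, tmp_path):
        path = str(tmp_path / "bifido.xml")
        write_sbml(BIFIDO_SPEC, path)
        gem = load_gem(
            path, "bifido", objective_metabolite="atp_c",
            boundary_metabolites={"atp_c"},
        )
        sol = solve(FbaProblem(gem, {"lcts_e": 100.0}, 1.0, 2.0))
        assert sol.objective == pytest.approx(2 * 5 / 7, rel=1e-9)

    def test_empty_model_is_a_parse_error(self):
        import cobra

        with pytest.raises(GemParseError):
            load_gem(cobra.Model("empty"), "empty", objective_reaction="x")

    def test_missing_objective_is_a_configuration_error(self):
        import cobra

        m = _cobra_toy()
        m.objective = {}
        with pytest.raises(ConfigurationError):
            load_gem(m, "toy")

    @pytest.mark.parametrize("raw,expected", [
        ("lcts[e]", "lcts_e"),
        ("lcts(e)", "lcts_e"),
        ("lcts_e", "lcts_e"),
    ])
    def test_agora_id_dialects_normalize(self, raw, expected):
        assert canonical_met_id(raw) == expected

    def test_split_polytope_matches_original_reversible_encoding(self):
        """Splitting is lossless: our LP on the split model equals cobra's
        FBA on the original reversible model when the flux cap is slack."""
        m = _cobra_toy()
        m.objective = "EX_b_e"  # maximize export of B
        expected = m.optimize().objective_value
        gem = load_gem(m, "toy", objective_reaction="EX_b_e")
        sol = solve(FbaProblem(gem, {"a_e": 1e6}, 1.0, 1e6))
        assert sol.objective == pytest.approx(expected, rel=1e-9)


class TestPatch:
    def test_block_uptake_zeroes_only_the_uptake_direction(self, consortium):
        gem = consortium["producer"]
        patched = apply_patch(gem, block_uptake_patch("producer", ["lac_L_e"]))
        up, sec = patched.exchange_index["lac_L_e"]
        assert patched.reactions[up].upper_bound == 0
        assert patched.reactions[sec].upper_bound > 0
        # original untouched
        assert gem.reactions[up].upper_bound > 0
        # lactate no longer supports growth; 1,2-PD still does
        s = solve(FbaProblem(patched, {"lac_L_e": 100.0}, 1.0, 2.0))
        assert s.objective == 0.0
        s = solve(FbaProblem(patched, {"ppd12_e": 100.0, "ac_e": 100.0}, 1.0, 2.0))
        assert s.objective > 0

    def test_empty_patch_is_identity(self, consortium):
        gem = consortium["bifido"]
        patched = apply_patch(gem, ModelPatch("bifido"))
        assert patched.reactions == gem.reactions

    def test_patch_is_idempotent(self, consortium):
        gem = consortium["producer"]
        p = block_uptake_patch("producer", ["lac_L_e"])
        once = apply_patch(gem, p)
        twice = apply_patch(once, p)
        assert once.reactions == twice.reactions

    def test_duplicate_add_is_an_error(self, consortium):
        gem = consortium["bifido"]
        dup = next(iter(gem.reactions))
        patch = ModelPatch(
            "bifido",
            (PatchAction("add_reaction", gem.reactions[dup]),),
        )
        with pytest.raises(PatchError, match=dup):
            apply_patch(gem, patch)

    def test_unknown_reaction_reference_is_an_error(self, consortium):
        patch = ModelPatch("bifido", (PatchAction("remove_reaction", "nope"),))
        with pytest.raises(PatchError, match="nope"):
            apply_patch(consortium["bifido"], patch)

    def test_wrong_target_species_is_an_error(self, consortium):
        with pytest.raises(PatchError):
            apply_patch(consortium["bifido"], ModelPatch("producer"))

    def test_patch_document_roundtrip(self, consortium):
        doc = {
            "target_species": "producer",
            "actions": [
                {"block_uptake": "lac_L_e"},
                {"set_bound": {"id": "but_ppd_r1", "lower": 0.0, "upper": 3.0}},
            ],
        }
        patched = apply_patch(consortium["producer"], ModelPatch.from_dict(doc))
        assert patched.reactions["but_ppd_r1"].upper_bound == 3.0
        assert patched.reactions["but_ppd_r1"].source == "patch"


# a compartmentalized consumer with intracellular lactose / fucose /
# galactose handling, to host the prebiotic pathway additions
_HOST_SPEC = ToyGemSpec(
    "host",
    (
        PathwaySpec("h_lcts", {"lcts_e": 1}, {"ac_e": 3, "lac_L_e": 2}, 5.0),
    ),
)


def _host_gem():
    """Host model with cytosolic lactose/fucose/galactose metabolism."""
    import cobra

    m = make_cobra_model(_HOST_SPEC)
    mets = {x.id: x for x in m.metabolites}
    for mid in ("lcts_c", "fuc_L_c", "gal_c", "gal_e", "ppd12_e", "atp_c"):
        if mid not in mets:
            mets[mid] = cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])
    # cytosolic lactose enters the bifid shunt
    t = cobra.Reaction("LCTSt", lower_bound=0, upper_bound=1000)
    t.add_metabolites({mets["lcts_c"]: -1, mets["lcts_e"]: 1})
    # fucose -> 1,2-PD (+ implicit redox, toy scale)
    fuc = cobra.Reaction("FUC_cat", lower_bound=0, upper_bound=1000)
    fuc.add_metabolites(
        {mets["fuc_L_c"]: -1, mets["ppd12_e"]: 1, mets["atp_c"]: 1}
    )
    ex_ppd = cobra.Reaction("EX_ppd12_e", lower_bound=-1000, upper_bound=1000)
    ex_ppd.add_metabolites({mets["ppd12_e"]: -1})
    # galactose joins glycolysis, toy-style
    gal = cobra.Reaction("GAL_cat", lower_bound=0, upper_bound=1000)
    gal.add_metabolites({mets["gal_c"]: -1, mets["ac_e"]: 3, mets["atp_c"]: 2})
    m.add_reactions([t, fuc, ex_ppd, gal])
    return load_gem(
        m, "host", objective_metabolite="atp_c", boundary_metabolites={"atp_c"}
    )


class TestPrebioticPathways:
    def test_2fl_pathway_enables_growth_on_2fl(self):
        gem = _host_gem()
        base = solve(FbaProblem(gem, {"2fl_e": 100.0}, 1.0, 2.0))
        assert base.objective == 0.0
        patched = add_prebiotic_pathways(gem, "2FL")
        sol = solve(FbaProblem(patched, {"2fl_e": 100.0}, 1.0, 2.0))
        assert sol.objective > 0
        assert "ppd12_e" in sol.secretion  # the fucose moiety leaves as 1,2-PD

    def test_gos_dp5_reaches_lactose_via_two_cleavages(self):
        gem = add_prebiotic_pathways(_host_gem(), "GOS")
        sol = solve(FbaProblem(gem, {"gosdp5_e": 100.0}, 1.0, 2.0))
        assert sol.objective > 0
        assert sol.uptake == {"gosdp5_e": pytest.approx(sol.uptake["gosdp5_e"])}

    def test_added_reactions_conserve_carbon(self):
        from gutlattice.synthetic_fixtures import FIXTURE_CARBON

        carbon = dict(
            FIXTURE_CARBON,
            lcts_c=12, fuc_L_c=6, gal_c=6, **{"2fl_c": 18, "gosdp3_c": 18},
        )
        gem = add_prebiotic_pathways(
            add_prebiotic_pathways(_host_gem(), "GOS"), "2FL"
        )
        for rxn in gem.reactions.values():
            if rxn.source != "patch" or rxn.is_exchange:
                continue
            net = sum(
                coeff * carbon[met]
                for met, coeff in rxn.stoichiometry.items()
                if met in carbon and met != "atp_c"
            )
            assert net == 0, rxn.id

    def test_missing_prerequisite_metabolite_is_a_patch_error(self, consortium):
        # the producer has no cytosolic lactose/fucose at all
        with pytest.raises(PatchError):
            add_prebiotic_pathways(consortium["producer"], "2FL")

    def test_patch_applies_only_to_designated_consumer(self, consortium):
        # the simulation-level contract: the patch is applied per-species by
        # configuration, not broadcast; other models remain untouched
        before = dict(consortium["competitor"].reactions)
        try:
            add_prebiotic_pathways(consortium["competitor"], "2FL")
        except PatchError:
            pass
        assert consortium["competitor"].reactions == before


def test_validate_rejects_inconsistent_objective(chain_gem):
    broken = chain_gem.copy()
    broken.objective_metabolite = None
    with pytest.raises(ConfigurationError):
        validate_gem(broken)
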