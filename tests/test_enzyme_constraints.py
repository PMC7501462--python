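"""GECKO transformation, proteome integration, condition models, ecFVA."""

import numpy as np
import pytest

from ecswitch.enzyme_constraints import (
    ConditionError,
    ConditionSpec,
    KcatEntry,
    PoolParams,
    ProteinInfo,
    ProteomeSample,
    add_enzyme_constraints,
    apply_condition,
    apply_proteome,
    build_condition_model,
    ecfva_compare,
    split_reversible,
)
from ecswitch.gem_core import MetabolicModel, Metabolite, Reaction, fba, fva

from conftest import build_chain_model


@pytest.fixture(scope="module")
def toy_ec(cfg0, toy_m145, toy_tables):
    _, kcats, proteins = toy_tables
    return add_enzyme_constraints(
        split_reversible(toy_m145), kcats, proteins, cfg0.pool)


@pytest.fixture(scope="module")
def m145_bundle(cfg0, toy_m145, toy_tables, toy_ec):
    from ecswitch.synthetic_data import make_conditions, make_proteome, make_timeseries

    _, kcats, proteins = toy_tables
    ts = make_timeseries(cfg0, "M145")
    proteomes = make_proteome(toy_m145, ts, cfg0, kcats, proteins)
    conditions = make_conditions(ts, proteomes, cfg0)
    return ts, proteomes, conditions


class TestSplitReversible:
    def test_reversible_bounds_split(self):
        m = build_chain_model()
        m.reactions["AB"].lower_bound = -5.0
        out = split_reversible(m)
        assert out.reactions["AB"].lower_bound == 0.0
        assert out.reactions["AB"].upper_bound == 10.0
        assert out.reactions["AB_REV"].upper_bound == 5.0
        assert out.reactions["AB_REV"].stoichiometry == {"A": 1.0, "B": -1.0}

    def test_irreversible_untouched(self, chain_model):
        out = split_reversible(chain_model)
        assert "AB_REV" not in out.reactions
        assert out.reactions["AB"].lower_bound == 0.0

    def test_optimum_preserved(self, toy_m145):
        split = split_reversible(toy_m145)
        assert fba(split).objective_value == pytest.approx(
            fba(toy_m145).objective_value, abs=1e-9)


def single_enzyme_model():
    m = build_chain_model()
    m.reactions["AB"].gene_rule = "gE"
    split = split_reversible(m)
    return add_enzyme_constraints(
        split,
        [KcatEntry("E", "AB", "forward", 3600.0)],
        [ProteinInfo("E", 30.0, "gE")],
        PoolParams(),
    )


class TestAddEnzymeConstraints:
    def test_kcat_caps_flux(self):
        ec = single_enzyme_model()
        out = apply_proteome(ec, ProteomeSample("s", 0.0, {"E": 0.001}))
        sol = fba(out.model)
        # v <= kcat * e = 3600 * 0.001 = 3.6
        assert sol.objective_value == pytest.approx(3.6, abs=1e-8)

    def test_huge_pool_recovers_unconstrained_optimum(self, toy_ec, toy_m145):
        relaxed = toy_ec.copy()
        relaxed.model.reactions["prot_pool_exchange"].upper_bound = 1e6
        assert fba(relaxed.model).objective_value == pytest.approx(
            fba(toy_m145).objective_value, abs=1e-6)

    def test_isozymes_get_one_copy_each(self, toy_ec):
        # PFK carries "g_pfkA or g_pfkB": two copies, each with one enzyme
        assert "PFK_No1" in toy_ec.model.reactions
        assert "PFK_No2" in toy_ec.model.reactions
        assert sorted(toy_ec.forward_copies["PFK"]) == ["PFK_No1", "PFK_No2"]
        for cid in ("PFK_No1", "PFK_No2"):
            enz = [mid for mid in toy_ec.model.reactions[cid].stoichiometry
                   if mid.startswith("prot_")]
            assert len(enz) == 1

    def test_complex_couples_all_subunits(self, toy_ec):
        # NADHOX requires "g_nuoA and g_nuoB": both subunits at -1/kcat
        stoich = toy_ec.model.reactions["NADHOX"].stoichiometry
        subunits = [mid for mid in stoich if mid.startswith("prot_")]
        assert sorted(subunits) == ["prot_P_nuoA", "prot_P_nuoB"]
        assert all(stoich[s] < 0 for s in subunits)

    def test_gene_rule_free_reactions_uncoupled(self, toy_ec):
        stoich = toy_ec.model.reactions["ATPM"].stoichiometry
        assert not any(mid.startswith("prot_") for mid in stoich)

    def test_unknown_kcat_reaction_rejected(self, toy_m145, toy_tables):
        _, _, proteins = toy_tables
        with pytest.raises(Exception, match="GHOST"):
            add_enzyme_constraints(
                split_reversible(toy_m145),
                [KcatEntry("P_glk", "GHOST", "forward", 100.0)],
                proteins, PoolParams())

    def test_flux_space_containment(self, cfg0, toy_ec, toy_m145):
        """Projected ec samples are feasible states of the parent GEM."""
        from ecswitch.flux_sampling import sample_vertices

        samples = sample_vertices(toy_ec, 100, seed=5)
        S, _, rxn_ids = toy_m145.stoichiometric_matrix()
        for row in samples.matrix:
            net = toy_ec.net_fluxes(dict(zip(samples.reaction_ids, row)))
            v = np.array([net[r] for r in rxn_ids])
            assert np.abs(S @ v).max() < 1e-6
            for j, rid in enumerate(rxn_ids):
                rxn = toy_m145.reactions[rid]
                assert rxn.lower_bound - 1e-6 <= v[j] <= rxn.upper_bound + 1e-6

    def test_enzyme_usage_never_exceeds_kcat_capacity(self, toy_ec):
        """v <= kcat·e in every returned solution, by mass balance of the
        enzyme species: usage flux equals sum of v/kcat over consumers."""
        out = apply_proteome(
            toy_ec, ProteomeSample("s", 0.0, {p: 1e-4 for p in toy_ec.proteins}))
        sol = fba(out.model)
        for pid in out.measured:
            assert sol.values[out.usage_reactions[pid]] <= 1e-4 + 1e-9


class TestApplyProteome:
    def test_huge_abundances_recover_optimum(self, toy_ec, toy_m145):
        sample = ProteomeSample("s", 0.0, {p: 10.0 for p in toy_ec.proteins})
        out = apply_proteome(toy_ec, sample)
        # measured mass blows past the pool budget; cap goes to zero but
        # every enzyme is individually unconstrained in practice
        assert fba(out.model).objective_value == pytest.approx(
            fba(toy_m145).objective_value, abs=1e-6)

    def test_halving_limiting_enzyme_halves_flux(self):
        ec = single_enzyme_model()
        full = fba(apply_proteome(ec, ProteomeSample("s", 0, {"E": 0.001})).model)
        half = fba(apply_proteome(ec, ProteomeSample("s", 0, {"E": 0.0005})).model)
        assert half.objective_value == pytest.approx(full.objective_value / 2, abs=1e-9)

    def test_empty_sample_is_pure_pool(self, toy_ec):
        out = apply_proteome(toy_ec, ProteomeSample("s", 0.0, {}))
        assert out.measured == set()
        cap = out.model.reactions["prot_pool_exchange"].upper_bound
        assert cap == pytest.approx(out.pool_params.cap)

    def test_flexibilize_raises_limiting_bound(self):
        ec = single_enzyme_model()
        sample = ProteomeSample("s", 0.0, {"E": 0.0005})  # supports only 1.8
        out = apply_proteome(ec, sample, flexibilize=True, required_growth=3.0)
        assert fba(out.model).objective_value >= 3.0 - 1e-9
        assert out.model.reactions["usage_prot_E"].upper_bound > 0.0005

    def test_flexibilize_budget_exhaustion_raises(self):
        ec = single_enzyme_model()
        sample = ProteomeSample("s", 0.0, {"E": 1e-6})
        with pytest.raises(ConditionError):
            apply_proteome(ec, sample, flexibilize=True,
                           required_growth=11.0, relaxation_budget=3)


class TestApplyCondition:
    def test_self_consistent_rates_feasible(self, toy_ec):
        sol = fba(toy_ec.model)
        spec = ConditionSpec(
            "M145", 0.0,
            {"EX_glc": (sol.values["EX_glc"],) * 2,
             "EX_glut": (sol.values["EX_glut"],) * 2},
            growth_rate=sol.objective_value)
        out = apply_condition(toy_ec, spec, tolerance_fraction=0.0)
        assert fba(out.model).objective_value == pytest.approx(
            sol.objective_value, abs=1e-7)

    def test_inconsistent_rates_diagnosed(self, toy_ec):
        # no glucose allowed, but growth demanded at the glucose optimum
        spec = ConditionSpec("M145", 0.0, {"EX_glc": (0.0, 0.0),
                                           "EX_glut": (0.0, 0.0)},
                             growth_rate=0.3)
        with pytest.raises(ConditionError) as err:
            apply_condition(toy_ec, spec, tolerance_fraction=0.0)
        assert "BIOMASS" in err.value.violations or err.value.violations

    def test_strain_contrast_in_glycolytic_flux(self, cfg0, toy_ec, m145_bundle, toy_tables):
        """Condition models plant the glucose-uptake contrast: the
        wild-type-like strain runs more glycolytic flux than the
        slower-growing deletion mutant at the second sampling point."""
        from ecswitch.synthetic_data import (
            build_toy_gem, make_conditions, make_proteome, make_timeseries)

        _, kcats, proteins = toy_tables
        _, _, conds_145 = m145_bundle
        m1152 = build_toy_gem(cfg0, "M1152")
        kcats_1152 = [k for k in kcats if k.reaction_id in m1152.reactions]
        ec_1152 = add_enzyme_constraints(
            split_reversible(m1152), kcats_1152, proteins, cfg0.pool)
        ts_1152 = make_timeseries(cfg0, "M1152")
        prot_1152 = make_proteome(m1152, ts_1152, cfg0, kcats_1152, proteins)
        conds_1152 = make_conditions(ts_1152, prot_1152, cfg0)

        cm_145 = build_condition_model(toy_ec, conds_145[1], cfg0.condition_tolerance)
        cm_1152 = build_condition_model(ec_1152, conds_1152[1], cfg0.condition_tolerance)
        hex_145 = cm_145.net_fluxes(fba(cm_145.model).values)["HEX1"]
        hex_1152 = cm_1152.net_fluxes(fba(cm_1152.model).values)["HEX1"]
        assert hex_145 > hex_1152


class TestEcFva:
    def test_unconstrained_ec_matches_gem_widths(self, toy_m145, toy_tables, cfg0):
        _, kcats, proteins = toy_tables
        ec = add_enzyme_constraints(
            split_reversible(toy_m145), kcats, proteins, cfg0.pool)
        relaxed = ec.copy()
        relaxed.model.reactions["prot_pool_exchange"].upper_bound = 1e7
        cmp = ecfva_compare(toy_m145, relaxed, ["PFK", "PGI", "EX_ac", "GLUDH"])
        for rid in cmp.gem_ranges:
            gw = cmp.gem_ranges[rid][1] - cmp.gem_ranges[rid][0]
            ew = cmp.ec_ranges[rid][1] - cmp.ec_ranges[rid][0]
            assert ew == pytest.approx(gw, abs=1e-5)

    def test_kcat_cap_strictly_shrinks_width(self):
        ec = single_enzyme_model()
        out = apply_proteome(ec, ProteomeSample("s", 0, {"E": 0.001}))
        gem = build_chain_model()
        cmp = ecfva_compare(gem, out, ["AB"])
        gw = cmp.gem_ranges["AB"][1] - cmp.gem_ranges["AB"][0]
        ew = cmp.ec_ranges["AB"][1] - cmp.ec_ranges["AB"][0]
        assert ew == pytest.approx(3.6) and ew < gw

    def test_widths_never_exceed_gem(self, toy_m145, toy_ec):
        cmp = ecfva_compare(toy_m145, toy_ec)
        df = cmp.widths()
        assert (df["ec_width"] <= df["gem_width"] + 1e-6).all()
        # the headline qualitative effect: variability drastically reduced
        assert df["ec_width"].median() < df["gem_width"].median()
        gem_sorted, ec_sorted = cmp.cumulative()
        assert len(gem_sorted) == len(ec_sorted) == len(df)
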