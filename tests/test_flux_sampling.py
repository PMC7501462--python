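"""Vertex sampling, pathway activity aggregation, metabolite budgets."""

import numpy as np
import pytest

from ecswitch.flux_sampling import (
    metabolite_budget,
    pathway_activity,
    sample_vertices,
)
from ecswitch.gem_core import MetabolicModel, Metabolite, Reaction, fba, fva

from conftest import build_chain_model


def one_free_dimension_model(cap=10.0):
    """in -> A -> out, both capacities equal: one free flux in [0, cap]."""
    m = MetabolicModel("box")
    m.add_metabolite(Metabolite("A"))
    m.add_reaction(Reaction("in", {"A": 1}, 0, cap))
    m.add_reaction(Reaction("out", {"A": -1}, 0, cap))
    m.objective = "out"
    return m


class TestSampleVertices:
    def test_singleton_polytope(self):
        m = build_chain_model()
        m.reactions["EX_B"].lower_bound = 10.0  # pins every flux to 10
        samples = sample_vertices(m, 20, seed=3)
        assert np.allclose(samples.matrix, 10.0 * np.ones_like(samples.matrix) *
                           np.sign(np.array([-1, 1, 1]))[None, :], atol=1e-9)

    def test_box_mean_by_sign_symmetry(self):
        """The free flux hits 0 or 10 with probability 1/2 each, so the
        sample mean approaches 5."""
        samples = sample_vertices(one_free_dimension_model(), 4000, seed=11)
        mean = samples.means().values["out"]
        assert abs(mean - 5.0) < 0.2
        # every sample is a vertex: exactly 0 or 10
        assert np.all(np.isclose(samples.matrix, 0.0, atol=1e-9)
                      | np.isclose(samples.matrix, 10.0, atol=1e-9))

    def test_means_inside_fva_ranges(self, toy_m145):
        samples = sample_vertices(toy_m145, 300, seed=17)
        ranges = fva(toy_m145).ranges
        for rid, mean in samples.means().values.items():
            lo, hi = ranges[rid]
            assert lo - 1e-7 <= mean <= hi + 1e-7

    def test_rows_satisfy_steady_state_and_bounds(self, toy_m145):
        samples = sample_vertices(toy_m145, 50, seed=23)
        S, _, rxn_ids = toy_m145.stoichiometric_matrix()
        assert np.abs(S @ samples.matrix.T).max() < 1e-6
        lb = np.array([toy_m145.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([toy_m145.reactions[r].upper_bound for r in rxn_ids])
        assert (samples.matrix >= lb - 1e-9).all()
        assert (samples.matrix <= ub + 1e-9).all()

    def test_deterministic_under_seed(self, toy_m145):
        a = sample_vertices(toy_m145, 25, seed=99)
        b = sample_vertices(toy_m145, 25, seed=99)
        assert np.array_equal(a.matrix, b.matrix)
        c = sample_vertices(toy_m145, 25, seed=100)
        assert not np.array_equal(a.matrix, c.matrix)

    def test_infeasible_model_rejected(self):
        m = build_chain_model()
        m.reactions["EX_B"].lower_bound = 11.0
        with pytest.raises(Exception, match="infeasible"):
            sample_vertices(m, 5, seed=1)


class TestPathwayActivity:
    @staticmethod
    def _means(**fluxes):
        return dict(fluxes)

    def test_identical_conditions_flagged_zero(self):
        means = self._means(r1=2.0, r2=-1.0)
        pa = pathway_activity(
            {"a": means, "b": dict(means)},
            {"r1": "P1", "r2": "P2"},
            {"a": 1.0, "b": 1.0}, top_k=2)
        assert (pa.zscores.to_numpy() == 0).all()
        assert pa.zero_variance == {"P1", "P2"}

    def test_rows_standardized(self):
        conditions = {f"c{i}": self._means(r1=float(i), r2=2.0 * i + 1) for i in range(5)}
        pa = pathway_activity(conditions, {"r1": "P1", "r2": "P2"},
                              {f"c{i}": 1.0 for i in range(5)}, top_k=2)
        for _, row in pa.zscores.iterrows():
            assert row.mean() == pytest.approx(0.0, abs=1e-9)
            assert row.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_absolute_value_aggregation_and_co2_normalization(self):
        pa = pathway_activity(
            {"a": self._means(r1=-3.0, r2=1.0)},
            {"r1": "P", "r2": "P"},
            {"a": 2.0}, top_k=1)
        assert pa.raw.loc["P", "a"] == pytest.approx(4.0)
        assert pa.normalized.loc["P", "a"] == pytest.approx(2.0)

    def test_non_positive_co2_rejected(self):
        with pytest.raises(ValueError):
            pathway_activity({"a": {"r": 1.0}}, {"r": "P"}, {"a": 0.0})

    def test_planted_switch_directions(self, cfg0, toy_m145, toy_tables):
        """Across the depletion boundary the fatty-acid pathway activity
        falls and oxidative phosphorylation rises (CO2-normalized)."""
        from ecswitch.enzyme_constraints import (
            add_enzyme_constraints, build_condition_model, split_reversible)
        from ecswitch.synthetic_data import (
            make_conditions, make_proteome, make_timeseries)

        _, kcats, proteins = toy_tables
        ec = add_enzyme_constraints(
            split_reversible(toy_m145), kcats, proteins, cfg0.pool)
        ts = make_timeseries(cfg0, "M145")
        proteomes = make_proteome(toy_m145, ts, cfg0, kcats, proteins)
        conds = make_conditions(ts, proteomes, cfg0)
        subsystems = {r.id: r.pathway for r in toy_m145.reactions.values()}
        samples, co2 = {}, {}
        for i in (1, 2, 4, 5):  # two pre- and two post-switch conditions
            cm = build_condition_model(ec, conds[i], cfg0.condition_tolerance)
            samples[f"t{i}"] = sample_vertices(cm, 150, seed=300 + i)
            co2[f"t{i}"] = float(ts.co2[i] / ts.cdw[i])
        pa = pathway_activity(
            samples, subsystems, co2, top_k=10,
            force_include=("Fatty acid biosynthesis", "Oxidative phosphorylation"))
        fatty = pa.normalized.loc["Fatty acid biosynthesis"]
        oxphos = pa.normalized.loc["Oxidative phosphorylation"]
        assert fatty[["t4", "t5"]].mean() < fatty[["t1", "t2"]].mean()
        assert oxphos[["t4", "t5"]].mean() > oxphos[["t1", "t2"]].mean()


class TestMetaboliteBudget:
    def test_single_producer_consumer(self):
        m = build_chain_model()
        budget = metabolite_budget({"EX_A": -2.0, "AB": 2.0, "EX_B": 2.0}, m, "A")
        assert budget.producing == pytest.approx({"EX_A": 2.0})
        assert budget.consuming == pytest.approx({"AB": 2.0})

    def test_budget_balances_for_every_sampled_vector(self, toy_m145):
        samples = sample_vertices(toy_m145, 40, seed=31)
        for row in samples.matrix:
            values = dict(zip(samples.reaction_ids, row))
            budget = metabolite_budget(values, toy_m145, "malcoa")
            assert budget.total_production == pytest.approx(
                budget.total_consumption, abs=1e-6)

    def test_mutant_has_no_bgc_drains(self, cfg0, toy_m1152):
        samples = sample_vertices(toy_m1152, 60, seed=37)
        budget = metabolite_budget(samples.net_means(), toy_m1152, "malcoa")
        assert not {"ACTS", "REDS", "CDAS", "CPKS"} & set(budget.consuming)

    def test_fatty_acid_to_bgc_drain_ratio(self, cfg0, toy_m145, toy_tables):
        """On the wild-type pre-switch condition, the fatty-acid drain of
        malonyl-CoA is 3-6x the summed BGC drains (calibrated contrast)."""
        from ecswitch.enzyme_constraints import (
            add_enzyme_constraints, build_condition_model, split_reversible)
        from ecswitch.synthetic_data import (
            make_conditions, make_proteome, make_timeseries)

        _, kcats, proteins = toy_tables
        ec = add_enzyme_constraints(
            split_reversible(toy_m145), kcats, proteins, cfg0.pool)
        ts = make_timeseries(cfg0, "M145")
        proteomes = make_proteome(toy_m145, ts, cfg0, kcats, proteins)
        conds = make_conditions(ts, proteomes, cfg0)
        cm = build_condition_model(ec, conds[1], cfg0.condition_tolerance)
        samples = sample_vertices(cm, 300, seed=7)
        budget = metabolite_budget(samples.net_means(), toy_m145, "malcoa")
        fatty = budget.consuming.get("FAS", 0.0)
        bgc = sum(budget.consuming.get(r, 0.0)
                  for r in ("ACTS", "REDS", "CDAS", "CPKS"))
        assert 3.0 <= fatty / bgc <= 6.0
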