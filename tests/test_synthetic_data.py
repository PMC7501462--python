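"""Generator determinism, planted phenomenology, recovery properties."""

import numpy as np
import pytest

from ecswitch.gem_core import fba
from ecswitch.synthetic_data import (
    ATP_RULE_ONLY,
    M145_REACTION_COUNT,
    MUTANT_REACTION_COUNT,
    UNCURATED_OPEN,
    ToyConfig,
    build_toy_gem,
    make_phenotype_tests,
    make_proteome,
    make_thermo_kcats,
    make_timeseries,
    planted_max_growth,
)
from ecswitch.thermo_curation import evaluate_phenotypes, propose_directionality


class TestToyGem:
    def test_reaction_counts(self, toy_m145, toy_m1152):
        assert len(toy_m145.reactions) == M145_REACTION_COUNT
        assert len(toy_m1152.reactions) == MUTANT_REACTION_COUNT

    def test_deleted_clusters_absent(self, toy_m1152):
        for rid in ("ACTS", "REDS", "CDAS", "CPKS", "EX_act", "EX_red"):
            assert rid not in toy_m1152.reactions

    def test_planted_max_growth_is_hand_computable(self, cfg0, toy_m145):
        assert fba(toy_m145).objective_value == pytest.approx(
            planted_max_growth(cfg0), abs=1e-9)

    def test_growth_requires_phosphate(self, toy_m145):
        m = toy_m145.copy()
        m.reactions["EX_pi"].lower_bound = 0.0
        assert fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_determinism(self, cfg0):
        a = build_toy_gem(cfg0, "M145")
        b = build_toy_gem(cfg0, "M145")
        assert [
            (r.id, sorted(r.stoichiometry.items()), r.lower_bound, r.upper_bound)
            for r in a.reactions.values()
        ] == [
            (r.id, sorted(r.stoichiometry.items()), r.lower_bound, r.upper_bound)
            for r in b.reactions.values()
        ]

    def test_mutant_feasible_set_is_subset(self, cfg0, toy_m145, toy_m1152):
        """Deletions only remove reactions, so the mutant optimum cannot
        exceed the wild type's under identical bounds."""
        assert set(toy_m1152.reactions) <= set(toy_m145.reactions)
        assert fba(toy_m1152).objective_value <= fba(toy_m145).objective_value + 1e-9


class TestThermoKcats:
    def test_noise_free_recovery_is_complete(self, cfg0):
        import dataclasses

        cfg = dataclasses.replace(cfg0, dg_sigma=0.0)
        model = build_toy_gem(cfg, "M145", curated=False)
        thermo, _, _ = make_thermo_kcats(model, cfg)
        proposals = propose_directionality(model, thermo)
        planted = set(UNCURATED_OPEN) - set(ATP_RULE_ONLY)
        recovered = {p.reaction_id for p in proposals
                     if p.reaction_id in planted and p.new_bounds[0] == 0.0}
        assert recovered == planted

    def test_recovery_rate_under_noise(self, cfg0):
        """With sigma = 5 kJ/mol, >= 90% of planted irreversibilities are
        recovered (Monte Carlo over 20 seeds)."""
        import dataclasses

        planted = set(UNCURATED_OPEN) - set(ATP_RULE_ONLY)
        hits = total = 0
        for seed in range(20):
            cfg = dataclasses.replace(cfg0, seed=seed, dg_sigma=5.0)
            model = build_toy_gem(cfg, "M145", curated=False)
            thermo, _, _ = make_thermo_kcats(model, cfg)
            proposals = propose_directionality(model, thermo)
            recovered = {p.reaction_id for p in proposals
                         if p.reaction_id in planted and p.new_bounds[0] == 0.0}
            hits += len(recovered)
            total += len(planted)
        assert hits / total >= 0.9

    def test_kcats_positive_and_reproducible(self, cfg0, toy_m145):
        _, kcats_a, proteins_a = make_thermo_kcats(toy_m145, cfg0)
        _, kcats_b, proteins_b = make_thermo_kcats(toy_m145, cfg0)
        assert all(k.kcat > 0 for k in kcats_a)
        assert [(k.protein_id, k.reaction_id, k.direction, k.kcat) for k in kcats_a] == [
            (k.protein_id, k.reaction_id, k.direction, k.kcat) for k in kcats_b]
        assert all(p.molecular_weight > 0 for p in proteins_a)
        assert proteins_a == proteins_b


class TestTimeseries:
    def test_bitwise_reproducible_with_noise(self):
        cfg = ToyConfig(noise_sd=0.02)
        a = make_timeseries(cfg, "M145")
        b = make_timeseries(cfg, "M145")
        assert np.array_equal(a.cdw, b.cdw)
        for key in a.concentrations:
            assert np.array_equal(a.concentrations[key], b.concentrations[key])

    def test_mass_plausibility_noise_free(self, cfg0):
        """Biomass gain never exceeds yield-weighted substrate use."""
        for strain in ("M145", "M1146", "M1152"):
            ts = make_timeseries(cfg0, strain)
            dx = np.diff(ts.cdw)
            supplied = sum(
                -np.diff(ts.concentrations[sub]) * cfg0.yields[sub]
                for sub in ("glucose", "glutamate"))
            assert (dx <= supplied + 1e-9).all()

    def test_bgc_products_only_in_wild_type(self, cfg0):
        wt = make_timeseries(cfg0, "M145")
        mut = make_timeseries(cfg0, "M1152")
        assert wt.concentrations["act_analog"].max() > 0
        assert mut.concentrations["act_analog"].max() == 0.0

    def test_germicidin_in_all_strains_scaled(self, cfg0):
        # biomass-normalized titers order by the preset scale factors
        # (absolute titers do not: strains reach different biomass)
        series = {s: make_timeseries(cfg0, s) for s in ("M145", "M1146", "M1152")}
        finals = {s: ts.concentrations["germicidin_A"][-1] / ts.cdw[-1]
                  for s, ts in series.items()}
        assert finals["M145"] > finals["M1146"] > finals["M1152"] > 0


@pytest.fixture(scope="module")
def proteomes(cfg0, toy_m145, toy_tables):
    _, kcats, proteins = toy_tables
    ts = make_timeseries(cfg0, "M145")
    return make_proteome(toy_m145, ts, cfg0, kcats, proteins), proteins


class TestProteome:
    def test_switch_shift_directions(self, cfg0, toy_m145, proteomes):
        samples, _ = proteomes
        t_dep = cfg0.preset("M145").t_depletion
        pre = [s for s in samples if s.time <= t_dep]
        post = [s for s in samples if s.time > t_dep]

        def mean_abundance(sample_list, genes):
            pids = ["P_" + g[2:] for g in genes]
            return np.mean([
                s.abundances.get(p, 0.0) for s in sample_list for p in pids])

        oxphos = {"g_nuoA", "g_nuoB", "g_cydA"}
        fatty = {"g_accA", "g_accB", "g_fabF"}
        assert mean_abundance(post, oxphos) > mean_abundance(pre, oxphos)
        assert mean_abundance(post, fatty) < mean_abundance(pre, fatty)

    def test_measured_mass_within_pool_budget(self, cfg0, proteomes):
        samples, proteins = proteomes
        mw = {p.protein_id: p.molecular_weight for p in proteins}
        limit = cfg0.pool.f * cfg0.pool.p_total
        for s in samples:
            mass = sum(a * mw.get(p, 25.0) for p, a in s.abundances.items())
            assert mass <= limit + 1e-9

    def test_some_proteins_withheld(self, cfg0, toy_m145, proteomes):
        samples, _ = proteomes
        model_proteins = {"P_" + g[2:] for g in toy_m145.genes}
        measured = set(samples[0].abundances)
        assert model_proteins - measured  # a withheld fraction exists


class TestPhenotypeTests:
    def test_zero_flips_give_perfect_mcc(self, cfg0, toy_m145):
        import dataclasses

        cfg = dataclasses.replace(
            cfg0, n_phenotype_tests=60, target_confusion=(40, 0, 20, 0))
        tests = make_phenotype_tests(toy_m145, cfg)
        assert evaluate_phenotypes(toy_m145, tests).mcc == pytest.approx(1.0)

    def test_planted_confusion_structure(self, cfg0, toy_m145):
        tests = make_phenotype_tests(toy_m145, cfg0)
        assert len(tests) == 241
        m = evaluate_phenotypes(toy_m145, tests)
        assert (m.tp, m.fp, m.tn, m.fn) == (155, 42, 38, 6)
        assert m.accuracy == pytest.approx(0.80, abs=0.03)
        assert m.sensitivity == pytest.approx(0.96, abs=0.03)
        assert m.specificity == pytest.approx(0.48, abs=0.03)

    def test_deterministic_under_seed(self, cfg0, toy_m145):
        a = make_phenotype_tests(toy_m145, cfg0)
        b = make_phenotype_tests(toy_m145, cfg0)
        assert [(t.test_id, t.observed) for t in a] == [(t.test_id, t.observed) for t in b]
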