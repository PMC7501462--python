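"""Seeded generators for every input of the analysis pipeline.

The toy network emulates central carbon metabolism of a polyketide-
producing actinomycete: glycolysis, pentose phosphate pathway, TCA
cycle, oxidative phosphorylation, anaplerosis, glutamate assimilation,
fatty-acid biosynthesis from malonyl-CoA, a germicidin-analog pathway
present in every strain, and four deletable BGC-analog pathways
(actinorhodin-, undecylprodigiosin-, CDA- and coelimycin-like) that
drain malonyl-CoA.  Growth strictly requires phosphate; its uptake
bound makes the maximal growth rate hand-computable
(μ_max = phosphate uptake / biomass phosphate coefficient).

Strain presets plant the study's contrasts: the wild-type-like strain
(M145 preset) grows at 0.21 h⁻¹ and depletes phosphate at 35 h; the
BGC-deletion strains grow at 0.21 h⁻¹ (M1146 preset, depletion 38 h)
and 0.15 h⁻¹ (M1152 preset, depletion 47 h).  Germicidin-analog
titers are scaled by 0.73/0.75 (M1146, A/B) and 0.08/0.18 (M1152),
i.e. the scale factors back-calculated from the planted 27/25 % and
92/82 % production reductions.  All generators are pure functions of
(config, seed): identical inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .cultivation_rates import TimeSeries
from .enzyme_constraints import (
    ConditionSpec,
    KcatEntry,
    PoolParams,
    ProteinInfo,
    ProteomeSample,
    condition_bounds,
)
from .gem_core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .thermo_curation import GROWTH_CUTOFF, PhenotypeTest, ThermoRecord, _simulate_test

__all__ = [
    "StrainPreset",
    "ToyConfig",
    "build_toy_gem",
    "make_thermo_kcats",
    "make_timeseries",
    "make_proteome",
    "make_phenotype_tests",
    "make_conditions",
    "M145_REACTION_COUNT",
    "MUTANT_REACTION_COUNT",
    "PHO_REGULON",
]

#: declared reaction counts of the generated models
M145_REACTION_COUNT = 51
MUTANT_REACTION_COUNT = 43

#: pseudo-proteins of the phosphate-starvation regulon (alignment marker)
PHO_REGULON = ("P_pho1", "P_pho2", "P_pho3", "P_pho4", "P_pho5", "P_pstS")


@dataclass
class StrainPreset:
    name: str
    mu: float  # exponential-phase growth rate, h^-1
    t_depletion: float  # phosphate depletion time, h
    glucose_share: float  # fraction of biomass formed from glucose carbon
    germicidin_scale: Dict[str, float] = field(default_factory=lambda: {"A": 1.0, "B": 1.0})
    has_bgc: bool = True
    acetate_per_biomass: float = 1.5  # mmol acetate per g CDW formed


def _default_strains() -> Dict[str, StrainPreset]:
    return {
        "M145": StrainPreset("M145", 0.21, 35.0, 0.60, {"A": 1.0, "B": 1.0}, True, 1.5),
        "M1146": StrainPreset("M1146", 0.21, 38.0, 0.55, {"A": 0.73, "B": 0.75}, False, 1.2),
        "M1152": StrainPreset("M1152", 0.15, 47.0, 0.45, {"A": 0.08, "B": 0.18}, False, 0.5),
    }


@dataclass
class ToyConfig:
    """Study conditions for the synthetic system (defaults ARE the study)."""

    seed: int = 42
    noise_sd: float = 0.02  # multiplicative measurement noise on time series
    strains: Dict[str, StrainPreset] = field(default_factory=_default_strains)
    # cultivation
    initial_cdw: float = 0.001  # g/L inoculum
    glucose_0: float = 60.0  # mmol/L
    glutamate_0: float = 60.0
    phosphate_0: float = 2.5
    yields: Dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.09, "glutamate": 0.075}
    )  # g biomass per mmol substrate
    maintenance_rate: float = 0.05  # h^-1-equivalent substrate drain after arrest
    germicidin_rate: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.8, "B": 0.5}
    )  # mg/L/h per g/L biomass at depletion
    co2_per_growth: float = 20.0  # mmol CO2 per g biomass formed
    co2_per_biomass: float = 1.5  # mmol/(g·h) maintenance respiration
    pre_fractions: Tuple[float, ...] = (0.3, 0.6, 0.85)
    post_offsets: Tuple[float, ...] = (5.0, 13.0, 21.0, 29.0)
    # thermodynamics / enzymes
    dg_magnitude: float = 45.0  # planted |ΔG| for irreversible reactions, kJ/mol
    dg_sigma: float = 5.0  # kJ/mol noise on ΔG estimates
    kcat_median: float = 3600.0  # h^-1
    kcat_sigma: float = 0.5  # lognormal sigma (natural log)
    mw_range: Tuple[float, float] = (15.0, 35.0)  # g/mmol
    pool: PoolParams = field(default_factory=lambda: PoolParams(p_total=0.45, f=0.8, sigma=0.5))
    proteome_noise: float = 0.1  # lognormal sigma on abundances
    proteome_budget_fraction: float = 0.92  # of f·p_total, mass cap for measured proteins
    allocation_margin: float = 1.15  # abundance over minimal requirement
    bgc_drain_target: float = 0.0055  # calibrated per-BGC malonyl-CoA drain capacity
    # phenotype tests
    n_phenotype_tests: int = 241
    target_confusion: Tuple[int, int, int, int] = (155, 42, 38, 6)  # tp, fp, tn, fn
    # condition building
    condition_tolerance: float = 0.25

    def preset(self, strain: str) -> StrainPreset:
        if strain not in self.strains:
            raise KeyError(f"no preset for strain {strain!r}")
        return self.strains[strain]


# ---------------------------------------------------------------------
# toy genome-scale model
# ---------------------------------------------------------------------

#: reactions opened to reversible in the pre-curation model; their
#: planted truth is forward-irreversible.
UNCURATED_OPEN = (
    "HEX1", "PFK", "PYK", "PDH", "PTA", "POX", "G6PDH", "TKT", "CS", "ICDH",
    "AKGDH", "PPC", "PCK", "GLUDH", "ASPTA", "GLNS", "ACC", "FAS",
    "GERMA", "GERMB", "NADHOX", "CYTBD",
)

#: ATP-driven reactions deliberately left without a ΔG estimate so the
#: ATP curation rule (not the thermodynamic classifier) covers them.
ATP_RULE_ONLY = ("HEX1", "GLNS")

BGC_PATHWAYS = {
    "ACTS": "Actinorhodin biosynthesis (BGC)",
    "REDS": "Undecylprodigiosin biosynthesis (BGC)",
    "CDAS": "CDA biosynthesis (BGC)",
    "CPKS": "Coelimycin biosynthesis (BGC)",
}

#: malonyl-CoA stoichiometry of each BGC-analog synthesis
BGC_MALONYL = {"ACTS": 8.0, "REDS": 4.0, "CDAS": 3.0, "CPKS": 5.0}

#: biomass composition (consumed per 1/h of growth; 30 ATP is growth-
#: associated maintenance, 0.5 phosphate makes P the limiting nutrient)
BIOMASS = {
    "pyr": -1.0, "accoa": -1.0, "akg": -0.5, "fa": -0.2, "asp": -0.2,
    "gln": -0.1, "pi": -0.5, "nh4": -1.0, "nadph": -2.0, "atp": -30.0,
    "adp": 30.0,
}

REFERENCE_MEDIUM = {"EX_glc": -10.0, "EX_glut": -6.0, "EX_pi": -0.15}

#: fixed enzyme capacities (mmol·gDW⁻¹·h⁻¹) for the malonyl-CoA gate:
#: acetyl-CoA carboxylase supplies at most ~0.085, fatty-acid synthase
#: drains at most ~0.06, so the fatty-acid drain dominates the small
#: calibrated BGC drains by the planted 3–6×.
CALIBRATED_CAPS = {"ACC": 0.085, "FAS": 0.06}

#: reactions whose enzymes get calibrated (not flux-derived) abundances
_CALIBRATED_PATHWAYS = ("Germicidin biosynthesis", "Fatty acid biosynthesis")

#: post-switch abundance multipliers per pathway (the planted proteome
#: reallocation: oxidative phosphorylation up, fatty acids down, BGCs on)
POST_SWITCH_SHIFT = {
    "Oxidative phosphorylation": 1.6,
    "Fatty acid biosynthesis": 0.2,
    "Glycolysis": 0.8,
    "Germicidin biosynthesis": 2.0,
}
POST_SWITCH_BGC_SHIFT = 4.0
POST_SWITCH_PHO_SHIFT = 6.0


def _met(model: MetabolicModel, mid: str, name: str = "", comp: str = "c") -> None:
    model.add_metabolite(Metabolite(mid, name or mid, comp))


def _rxn(model, rid, stoich, lb, ub, gene="", subsystem="", pathway=""):
    model.add_reaction(
        Reaction(rid, stoich, lower_bound=lb, upper_bound=ub, gene_rule=gene,
                 subsystem=subsystem, pathway=pathway or subsystem)
    )


def build_toy_gem(
    config: ToyConfig,
    variant: str = "M145",
    curated: bool = True,
) -> MetabolicModel:
    """Deterministic toy GEM for one strain variant.

    The M145 variant has 50 reactions; M1146/M1152 lack the four
    BGC-analog pathways and their product exchanges (42 reactions).
    With ``curated=False`` the reactions in :data:`UNCURATED_OPEN` are
    opened to reversibility, emulating the state before thermodynamic
    curation.  On the reference medium the maximal growth rate is
    phosphate-limited: μ_max = 0.15 / 0.5 = 0.3 h⁻¹.
    """
    preset = config.preset(variant)
    m = MetabolicModel(f"toy_{variant}")
    for mid in ("glc", "glut", "pi", "nh4", "o2", "co2", "ac", "g6p", "f6p",
                "g3p", "pep", "pyr", "accoa", "malcoa", "cit", "akg", "oaa",
                "ru5p", "fa", "asp", "gln", "atp", "adp", "nadh", "nadph"):
        _met(m, mid)
    for mid in ("glc_e", "glut_e", "pi_e", "nh4_e", "o2_e", "co2_e", "ac_e",
                "germA_e", "germB_e"):
        _met(m, mid, comp="e")
    if preset.has_bgc:
        for mid in ("act_e", "red_e", "cda_e", "cpk_e"):
            _met(m, mid, comp="e")

    EX = "Exchange"
    _rxn(m, "EX_glc", {"glc_e": -1}, REFERENCE_MEDIUM["EX_glc"], 0, subsystem=EX)
    _rxn(m, "EX_glut", {"glut_e": -1}, REFERENCE_MEDIUM["EX_glut"], 0, subsystem=EX)
    _rxn(m, "EX_pi", {"pi_e": -1}, REFERENCE_MEDIUM["EX_pi"], 0, subsystem=EX)
    _rxn(m, "EX_nh4", {"nh4_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND, subsystem=EX)
    _rxn(m, "EX_o2", {"o2_e": -1}, -DEFAULT_BOUND, 0, subsystem=EX)
    _rxn(m, "EX_co2", {"co2_e": -1}, 0, DEFAULT_BOUND, subsystem=EX)
    _rxn(m, "EX_ac", {"ac_e": -1}, 0, DEFAULT_BOUND, subsystem=EX)
    _rxn(m, "EX_germA", {"germA_e": -1}, 0, DEFAULT_BOUND, subsystem=EX)
    _rxn(m, "EX_germB", {"germB_e": -1}, 0, DEFAULT_BOUND, subsystem=EX)
    if preset.has_bgc:
        for prod in ("act", "red", "cda", "cpk"):
            _rxn(m, f"EX_{prod}", {f"{prod}_e": -1}, 0, DEFAULT_BOUND, subsystem=EX)

    TR = "Transport"
    _rxn(m, "GLCt", {"glc_e": -1, "glc": 1}, 0, DEFAULT_BOUND, "g_glcP", TR)
    _rxn(m, "GLUTt", {"glut_e": -1, "glut": 1}, 0, DEFAULT_BOUND, "g_gluA", TR)
    _rxn(m, "PIt", {"pi_e": -1, "pi": 1}, 0, DEFAULT_BOUND, "g_pstS", TR)
    _rxn(m, "NH4t", {"nh4_e": -1, "nh4": 1}, -DEFAULT_BOUND, DEFAULT_BOUND, "g_amtB", TR)
    _rxn(m, "O2t", {"o2_e": -1, "o2": 1}, 0, DEFAULT_BOUND, "", TR)
    _rxn(m, "CO2t", {"co2": -1, "co2_e": 1}, 0, DEFAULT_BOUND, "", TR)
    _rxn(m, "ACt", {"ac": -1, "ac_e": 1}, 0, DEFAULT_BOUND, "", TR)

    CC = "Central carbon metabolism"
    _rxn(m, "HEX1", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, 0, DEFAULT_BOUND,
         "g_glk", CC, "Glycolysis")
    _rxn(m, "PGI", {"g6p": -1, "f6p": 1}, -DEFAULT_BOUND, DEFAULT_BOUND,
         "g_pgi", CC, "Glycolysis")
    _rxn(m, "PFK", {"f6p": -1, "atp": -1, "g3p": 2, "adp": 1}, 0, DEFAULT_BOUND,
         "g_pfkA or g_pfkB", CC, "Glycolysis")
    _rxn(m, "PGK", {"g3p": -1, "adp": -1, "pep": 1, "atp": 1, "nadh": 1}, 0,
         DEFAULT_BOUND, "g_pgk", CC, "Glycolysis")
    _rxn(m, "PYK", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, 0, DEFAULT_BOUND,
         "g_pyk", CC, "Glycolysis")
    _rxn(m, "PDH", {"pyr": -1, "accoa": 1, "co2": 1, "nadh": 1}, 0, DEFAULT_BOUND,
         "g_aceE and g_aceF", CC, "Pyruvate metabolism")
    _rxn(m, "PTA", {"accoa": -1, "adp": -1, "ac": 1, "atp": 1}, 0, DEFAULT_BOUND,
         "g_pta", CC, "Pyruvate metabolism")
    _rxn(m, "POX", {"pyr": -1, "o2": -0.5, "ac": 1, "co2": 1}, 0, DEFAULT_BOUND,
         "g_poxB", CC, "Pyruvate metabolism")
    _rxn(m, "G6PDH", {"g6p": -1, "ru5p": 1, "co2": 1, "nadph": 2}, 0, DEFAULT_BOUND,
         "g_zwf", CC, "Pentose phosphate pathway")
    _rxn(m, "TKT", {"ru5p": -3, "f6p": 2, "g3p": 1}, 0, DEFAULT_BOUND,
         "g_tkt", CC, "Pentose phosphate pathway")
    _rxn(m, "CS", {"accoa": -1, "oaa": -1, "cit": 1}, 0, DEFAULT_BOUND,
         "g_gltA", CC, "Citric acid cycle")
    _rxn(m, "ICDH", {"cit": -1, "akg": 1, "co2": 1, "nadph": 1}, 0, DEFAULT_BOUND,
         "g_icd", CC, "Citric acid cycle")
    _rxn(m, "AKGDH", {"akg": -1, "oaa": 1, "co2": 2, "nadh": 2, "atp": 1,
                      "adp": -1}, 0, DEFAULT_BOUND, "g_sucA", CC, "Citric acid cycle")
    _rxn(m, "PPC", {"pep": -1, "co2": -1, "oaa": 1}, 0, DEFAULT_BOUND,
         "g_ppc", CC, "Anaplerosis")
    _rxn(m, "PCK", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1}, 0,
         DEFAULT_BOUND, "g_pck", CC, "Anaplerosis")

    AA = "Amino acid metabolism"
    _rxn(m, "GLUDH", {"glut": -1, "akg": 1, "nh4": 1, "nadh": 1}, 0, DEFAULT_BOUND,
         "g_gdhA", AA, "Glutamate metabolism")
    _rxn(m, "ASPTA", {"oaa": -1, "glut": -1, "asp": 1, "akg": 1}, 0, DEFAULT_BOUND,
         "g_aspC", AA, "Alanine, aspartate and glutamate metabolism")
    _rxn(m, "GLNS", {"glut": -1, "nh4": -1, "atp": -1, "gln": 1, "adp": 1}, 0,
         DEFAULT_BOUND, "g_glnA", AA, "Alanine, aspartate and glutamate metabolism")

    EN = "Energy metabolism"
    _rxn(m, "NADHOX", {"nadh": -1, "o2": -0.5, "adp": -2, "atp": 2}, 0,
         DEFAULT_BOUND, "g_nuoA and g_nuoB", EN, "Oxidative phosphorylation")
    _rxn(m, "CYTBD", {"nadh": -1, "o2": -0.5, "adp": -1, "atp": 1}, 0,
         DEFAULT_BOUND, "g_cydA", EN, "Oxidative phosphorylation")
    _rxn(m, "THD", {"nadph": -1, "nadh": 1}, -DEFAULT_BOUND, DEFAULT_BOUND,
         "g_sthA", EN, "Oxidative phosphorylation")
    _rxn(m, "ATPM", {"atp": -1, "adp": 1}, 0, DEFAULT_BOUND, "", EN,
         "Maintenance")

    LI = "Lipid metabolism"
    _rxn(m, "ACC", {"accoa": -1, "atp": -1, "co2": -1, "malcoa": 1, "adp": 1},
         0, DEFAULT_BOUND, "g_accA and g_accB", LI, "Fatty acid biosynthesis")
    _rxn(m, "FAS", {"malcoa": -1, "nadph": -2, "fa": 1, "co2": 1}, 0,
         DEFAULT_BOUND, "g_fabF", LI, "Fatty acid biosynthesis")

    SM = "Secondary metabolism"
    _rxn(m, "GERMA", {"accoa": -1, "malcoa": -2, "germA_e": 1, "co2": 2}, 0,
         DEFAULT_BOUND, "g_gcs", SM, "Germicidin biosynthesis")
    _rxn(m, "GERMB", {"accoa": -1, "malcoa": -2, "germB_e": 1, "co2": 2}, 0,
         DEFAULT_BOUND, "g_gcs", SM, "Germicidin biosynthesis")
    if preset.has_bgc:
        _rxn(m, "ACTS", {"malcoa": -8, "nadph": -2, "act_e": 1, "co2": 8}, 0,
             DEFAULT_BOUND, "g_actI", SM, BGC_PATHWAYS["ACTS"])
        _rxn(m, "REDS", {"malcoa": -4, "accoa": -2, "red_e": 1, "co2": 4}, 0,
             DEFAULT_BOUND, "g_redL", SM, BGC_PATHWAYS["REDS"])
        _rxn(m, "CDAS", {"malcoa": -3, "glut": -2, "atp": -1, "cda_e": 1,
                         "co2": 3, "adp": 1}, 0, DEFAULT_BOUND, "g_cdaPS", SM,
             BGC_PATHWAYS["CDAS"])
        _rxn(m, "CPKS", {"malcoa": -5, "nadph": -1, "cpk_e": 1, "co2": 5}, 0,
             DEFAULT_BOUND, "g_cpkC", SM, BGC_PATHWAYS["CPKS"])

    _rxn(m, "BIOMASS", dict(BIOMASS), 0, DEFAULT_BOUND, "", "Biomass", "Biomass")
    m.objective = "BIOMASS"

    if not curated:
        for rid in UNCURATED_OPEN:
            rxn = m.reactions[rid]
            rxn.lower_bound = -DEFAULT_BOUND
    m.validate()
    return m


def planted_max_growth(config: ToyConfig) -> float:
    """Hand-computable μ_max on the reference medium (phosphate-limited)."""
    return -REFERENCE_MEDIUM["EX_pi"] / -BIOMASS["pi"]


# ---------------------------------------------------------------------
# thermodynamics, kcats, proteins
# ---------------------------------------------------------------------


def protein_id_for_gene(gene: str) -> str:
    return "P_" + gene[2:] if gene.startswith("g_") else "P_" + gene


def make_thermo_kcats(
    model: MetabolicModel,
    config: ToyConfig,
) -> Tuple[List[ThermoRecord], List[KcatEntry], List[ProteinInfo]]:
    """ΔG estimates, turnover numbers and protein catalog for a toy GEM.

    ΔG is drawn around the planted-direction-consistent mean
    (−|ΔG| for forward-irreversible truth, 0 for truly reversible
    reactions) with Normal(0, dg_sigma) noise; ATP-rule-only reactions
    get no record.  kcats are log-normal with the configured median;
    molecular weights are uniform in ``mw_range``; one protein per
    gene.
    """
    rng = np.random.default_rng([config.seed, 11])
    curated = build_toy_gem(config, model.id.replace("toy_", "") or "M145", curated=True)

    thermo: List[ThermoRecord] = []
    kcats: List[KcatEntry] = []
    genes = sorted(model.genes)
    proteins = [
        ProteinInfo(protein_id_for_gene(g),
                    float(rng.uniform(*config.mw_range)), g)
        for g in genes
    ]
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if not rxn.gene_rule:
            continue
        truth = curated.reactions[rid] if rid in curated.reactions else rxn
        if truth.lower_bound < 0 < truth.upper_bound:
            mean = 0.0
        elif truth.lower_bound >= 0:
            mean = -config.dg_magnitude
        else:
            mean = config.dg_magnitude
        if rid not in ATP_RULE_ONLY:
            label = ("reversible" if rxn.lower_bound < 0 < rxn.upper_bound
                     else "forward" if rxn.lower_bound >= 0 else "backward")
            thermo.append(
                ThermoRecord(rid, float(mean + rng.normal(0.0, config.dg_sigma)),
                             uncertainty=config.dg_sigma, prior_label=label)
            )
        for gene in sorted(rxn.genes):
            kcat = float(np.exp(np.log(config.kcat_median)
                                + rng.normal(0.0, config.kcat_sigma)))
            kcats.append(KcatEntry(protein_id_for_gene(gene), rid, "forward", kcat))
            if rxn.lower_bound < 0 < rxn.upper_bound:
                kcat_b = float(np.exp(np.log(config.kcat_median)
                                      + rng.normal(0.0, config.kcat_sigma)))
                kcats.append(KcatEntry(protein_id_for_gene(gene), rid, "backward", kcat_b))
    return thermo, kcats, proteins


# ---------------------------------------------------------------------
# cultivation time series
# ---------------------------------------------------------------------


def sampling_times(config: ToyConfig, strain: str) -> np.ndarray:
    """8 sampling times: 3 pre-depletion, the depletion time, 4 after."""
    t_dep = config.preset(strain).t_depletion
    pre = [f * t_dep for f in config.pre_fractions]
    post = [t_dep + o for o in config.post_offsets]
    return np.array(pre + [t_dep] + post)


def make_timeseries(config: ToyConfig, strain: str, replicate: int = 0) -> TimeSeries:
    """Batch-cultivation series with the strain's planted phenotype.

    Exponential growth at the preset μ until the preset depletion time,
    then growth arrest with slow maintenance consumption of substrates;
    phosphate hits exactly zero at the depletion time (a sampling grid
    point, so interpolated detection is exact at zero noise).
    Germicidin analogs accumulate after depletion proportionally to the
    biomass at arrest and the preset scale factor, making the
    depletion-aligned biomass-normalized titer ratio equal to the scale
    factor.  BGC products appear only in BGC-carrying strains.
    """
    preset = config.preset(strain)
    strain_idx = sorted(config.strains).index(strain)
    rng = np.random.default_rng([config.seed, 23, strain_idx, replicate])
    times = sampling_times(config, strain)
    t_dep, mu, x0 = preset.t_depletion, preset.mu, config.initial_cdw

    cdw = x0 * np.exp(mu * np.minimum(times, t_dep))
    x_dep = x0 * math.exp(mu * t_dep)
    grown = cdw - x0
    frac = grown / (x_dep - x0)
    post = np.maximum(times - t_dep, 0.0)

    w = {
        "glucose": preset.glucose_share / config.yields["glucose"],
        "glutamate": (1.0 - preset.glucose_share) / config.yields["glutamate"],
    }
    conc: Dict[str, np.ndarray] = {}
    conc["phosphate"] = config.phosphate_0 * np.maximum(0.0, 1.0 - frac)
    for sub, c0 in (("glucose", config.glucose_0), ("glutamate", config.glutamate_0)):
        series = c0 - w[sub] * grown - w[sub] * config.maintenance_rate * x_dep * post
        if np.any(series < 0):
            raise ValueError(f"substrate {sub} over-consumed for strain {strain}")
        conc[sub] = series
    conc["acetate"] = preset.acetate_per_biomass * grown
    for g in ("A", "B"):
        conc[f"germicidin_{g}"] = (
            preset.germicidin_scale[g] * config.germicidin_rate[g] * x_dep * post
        )
    onset = {"act_analog": 6.0, "red_analog": 2.0}
    rate = {"act_analog": 0.4, "red_analog": 0.3}
    for prod in ("act_analog", "red_analog"):
        if preset.has_bgc:
            conc[prod] = rate[prod] * x_dep * np.maximum(times - t_dep - onset[prod], 0.0)
        else:
            conc[prod] = np.zeros_like(times)

    mu_eff = np.where(times <= t_dep, mu, 0.0)
    co2 = (config.co2_per_growth * mu_eff + config.co2_per_biomass) * cdw

    if config.noise_sd > 0:
        def jitter(arr: np.ndarray) -> np.ndarray:
            return np.maximum(0.0, arr * (1.0 + config.noise_sd * rng.standard_normal(arr.shape)))

        cdw = np.maximum(x0 * 0.1, cdw * (1.0 + config.noise_sd * rng.standard_normal(cdw.shape)))
        conc = {k: jitter(v) for k, v in conc.items()}
        co2 = jitter(co2)

    return TimeSeries(strain, times, cdw, conc, co2=co2, replicate_id=f"r{replicate+1}")


# ---------------------------------------------------------------------
# proteome samples
# ---------------------------------------------------------------------


def _gene_reactions(model: MetabolicModel) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    for rid, rxn in model.reactions.items():
        for g in rxn.genes:
            out.setdefault(g, []).append(rid)
    return out


def _reference_fluxes(
    model: MetabolicModel, config: ToyConfig, preset: StrainPreset
) -> Dict[str, Tuple[float, float]]:
    """Minimal-total-flux reference state at the measured phenotype.

    Substrate uptakes are pinned at the top of the condition band
    (measured rate × (1 + tolerance)) and growth at the preset μ; the
    split model's total flux is minimized.  Returns per original
    reaction the (forward, backward) reference flux used to size the
    proteome.
    """
    from .enzyme_constraints import split_reversible
    from .gem_core import optimize

    w_glc = preset.glucose_share / config.yields["glucose"]
    w_glut = (1.0 - preset.glucose_share) / config.yields["glutamate"]
    top = 1.0 + config.condition_tolerance
    work = model.copy()
    for ex, q in (("EX_glc", w_glc * preset.mu), ("EX_glut", w_glut * preset.mu)):
        work.reactions[ex].lower_bound = -top * q
        work.reactions[ex].upper_bound = -top * q
    work.reactions[work.objective].lower_bound = preset.mu
    # secondary metabolism and the malonyl-CoA gate operate at their
    # calibrated capacities, so the reference state cannot dump carbon
    # through enzymes that will only get trace abundances
    for rid, coeff in BGC_MALONYL.items():
        if rid in work.reactions:
            work.reactions[rid].upper_bound = config.bgc_drain_target / coeff
    for rid in ("GERMA", "GERMB"):
        work.reactions[rid].upper_bound = 0.002
    for rid, cap in CALIBRATED_CAPS.items():
        work.reactions[rid].upper_bound = cap
    split = split_reversible(work)
    sol = optimize(split, {rid: 1.0 for rid in split.reactions}, sense="min")
    if sol.status != "optimal":
        raise ValueError(
            f"reference flux state for {preset.name} is {sol.status}; "
            "check preset rates against the toy stoichiometry"
        )
    out: Dict[str, Tuple[float, float]] = {}
    for rid in model.reactions:
        out[rid] = (
            max(sol.values.get(rid, 0.0), 0.0),
            max(sol.values.get(rid + "_REV", 0.0), 0.0),
        )
    return out


def make_proteome(
    model: MetabolicModel,
    ts: TimeSeries,
    config: ToyConfig,
    kcats: Sequence[KcatEntry],
    proteins: Sequence[ProteinInfo],
) -> List[ProteomeSample]:
    """Per-sampling-time protein abundances with the planted switch shift.

    Central-metabolic enzymes are allocated from a reference flux state
    of the strain's own GEM — the minimal-total-flux solution with the
    substrate uptakes pinned at the top of their measured band and
    growth at the preset μ — as abundance = margin · v_ref / kcat.
    This makes every condition-specific model feasible by construction.
    Secondary-metabolite enzymes get calibrated small capacities (the
    BGC malonyl-CoA drain target), multiplied up after the switch;
    oxidative-phosphorylation enzymes rise and fatty-acid enzymes fall
    after the switch.  The least-abundant central proteins are withheld
    from measurement (they stay on the shared pool), and a phosphate-
    starvation regulon of pseudo-proteins is included for time-point
    alignment.
    """
    preset = config.preset(ts.strain_id)
    strain_idx = sorted(config.strains).index(ts.strain_id)
    kcat_of: Dict[Tuple[str, str, str], float] = {
        (e.reaction_id, e.direction, e.protein_id): e.kcat for e in kcats
    }
    mw = {p.protein_id: p.molecular_weight for p in proteins}
    gene_rxns = _gene_reactions(model)

    v_ref = _reference_fluxes(model, config, preset)

    base_need: Dict[str, float] = {}
    secondary: Dict[str, float] = {}
    for gene, rids in gene_rxns.items():
        pid = protein_id_for_gene(gene)
        need = 0.0
        for rid in rids:
            rxn = model.reactions[rid]
            kf = kcat_of.get((rid, "forward", pid), config.kcat_median)
            if rid in BGC_MALONYL:
                cap = config.bgc_drain_target / BGC_MALONYL[rid]
                secondary[pid] = secondary.get(pid, 0.0) + cap / kf
                continue
            if rxn.pathway == "Germicidin biosynthesis":
                secondary[pid] = secondary.get(pid, 0.0) + 0.002 / kf
                continue
            if rid in CALIBRATED_CAPS:
                secondary[pid] = secondary.get(pid, 0.0) + CALIBRATED_CAPS[rid] / kf
                continue
            fwd, bwd = v_ref.get(rid, (0.0, 0.0))
            kb = kcat_of.get((rid, "backward", pid), config.kcat_median)
            need += max(fwd / kf, bwd / kb, 0.02 / kf)
        if need > 0:
            base_need[pid] = config.allocation_margin * need

    budget = config.proteome_budget_fraction * config.pool.f * config.pool.p_total
    central_mass = sum(a * mw.get(p, 25.0) for p, a in base_need.items())
    scale = min(1.0, 0.98 * budget / central_mass) if central_mass > 0 else 1.0
    if scale < 1.0:
        import logging

        logging.getLogger(__name__).warning(
            "proteome allocation for %s exceeds budget (mass %.3f); scaled by %.2f",
            ts.strain_id, central_mass, scale,
        )
    base_abund = {p: a * scale for p, a in base_need.items()}

    # withhold the least-needed central proteins from measurement
    n_withheld = max(1, int(round(0.1 * len(base_abund))))
    withheld = set(sorted(base_abund, key=lambda p: base_abund[p] * mw.get(p, 25.0))[:n_withheld])

    pathway_of_protein: Dict[str, Set[str]] = {}
    for gene, rids in gene_rxns.items():
        pid = protein_id_for_gene(gene)
        pathway_of_protein.setdefault(pid, set()).update(
            model.reactions[r].pathway for r in rids
        )

    t_dep = preset.t_depletion
    samples: List[ProteomeSample] = []
    for t_idx, t in enumerate(ts.times):
        is_post = t > t_dep
        rng = np.random.default_rng([config.seed, 31, strain_idx, t_idx])
        abund: Dict[str, float] = {}
        for pid, a in base_abund.items():
            if pid in withheld:
                continue
            mult = 1.0
            if is_post:
                for pw in pathway_of_protein.get(pid, ()):
                    mult *= POST_SWITCH_SHIFT.get(pw, 1.0)
            abund[pid] = a * mult
        for pid, a in secondary.items():
            mult = 1.0
            if is_post:
                if any("(BGC)" in pw for pw in pathway_of_protein.get(pid, ())):
                    mult = POST_SWITCH_BGC_SHIFT
                else:
                    for pw in pathway_of_protein.get(pid, ()):
                        mult *= POST_SWITCH_SHIFT.get(pw, 1.0)
            abund[pid] = a * mult
        for i, pid in enumerate(PHO_REGULON):
            base = 2e-05 * (1.0 + 0.1 * i)
            abund[pid] = abund.get(pid, 0.0) + base * (
                POST_SWITCH_PHO_SHIFT if is_post else 1.0
            )
        if config.proteome_noise > 0:
            for pid in list(abund):
                abund[pid] *= float(np.exp(rng.normal(0.0, config.proteome_noise)))
        measured_mass = sum(a * mw.get(p, 25.0) for p, a in abund.items())
        limit = config.pool.f * config.pool.p_total
        if measured_mass > 0.98 * limit:  # keep the budget invariant after noise
            factor = 0.98 * limit / measured_mass
            abund = {p: a * factor for p, a in abund.items()}
        samples.append(ProteomeSample(ts.strain_id, float(t), abund))
    return samples


# ---------------------------------------------------------------------
# phenotype tests
# ---------------------------------------------------------------------


def _candidate_tests(model: MetabolicModel) -> List[PhenotypeTest]:
    tests: List[PhenotypeTest] = []
    i = 0

    def medium(glc: float, glut: float, pi: float) -> None:
        nonlocal i
        i += 1
        tests.append(PhenotypeTest(
            f"M{i:03d}", "growth_medium",
            {"EX_glc": glc, "EX_glut": glut, "EX_pi": pi}, observed=True))

    for glc in (-10, -9, -8, -7, -6, -5, -4, -3, -2.5, -2, -1.5, -1, -0.75, -0.5, -0.25):
        for glut in (-6, -5, -4, -3, -2.5, -2, -1.5, -1, -0.75, -0.5, -0.25, 0):
            medium(glc, glut, -0.15)
    for pi in (-0.12, -0.1, -0.08):
        for glc in (-10, -6, -3, -2, -1):
            for glut in (-6, -3, -1):
                medium(glc, glut, pi)
    for glc in (-10, -6, -3, -1, 0):
        for glut in (-6, -3, -1, 0):
            medium(glc, glut, 0.0)  # no phosphate
    for pi in (-0.15, -0.1, -0.05):
        medium(0.0, 0.0, pi)  # no carbon
    for j, gene in enumerate(sorted(model.genes)):
        tests.append(PhenotypeTest(f"K{j+1:03d}", "knockout", [gene], observed=True))
    return tests


def make_phenotype_tests(
    model: MetabolicModel,
    config: ToyConfig,
) -> List[PhenotypeTest]:
    """Growth/knockout tests with a planted confusion structure.

    Candidate media and single-gene-knockout tests are FBA-simulated on
    the ground-truth model; enough predicted-growth and predicted-
    no-growth tests are selected to reach the configured totals, then
    observed labels are flipped for a seeded subset so that evaluating
    the tests against the very model that generated them reproduces
    the target (tp, fp, tn, fn) exactly.
    """
    tp, fp, tn, fn = config.target_confusion
    n_pos, n_neg = tp + fp, tn + fn
    if n_pos + n_neg != config.n_phenotype_tests:
        raise ValueError("target confusion does not sum to n_phenotype_tests")
    positives: List[PhenotypeTest] = []
    negatives: List[PhenotypeTest] = []
    for test in _candidate_tests(model):
        predicted = _simulate_test(model, test, GROWTH_CUTOFF)
        (positives if predicted else negatives).append(test)
        if len(positives) >= n_pos and len(negatives) >= n_neg:
            break
    if len(positives) < n_pos or len(negatives) < n_neg:
        raise ValueError(
            f"candidate pool too small: {len(positives)} growth / "
            f"{len(negatives)} no-growth predictions"
        )
    positives, negatives = positives[:n_pos], negatives[:n_neg]
    rng = np.random.default_rng([config.seed, 41])
    flip_pos = set(rng.choice(n_pos, size=fp, replace=False))
    flip_neg = set(rng.choice(n_neg, size=fn, replace=False))
    out: List[PhenotypeTest] = []
    for k, test in enumerate(positives):
        out.append(dataclasses.replace(test, observed=k not in flip_pos))
    for k, test in enumerate(negatives):
        out.append(dataclasses.replace(test, observed=k in flip_neg))
    order = rng.permutation(len(out))
    return [out[k] for k in order]


# ---------------------------------------------------------------------
# condition specs
# ---------------------------------------------------------------------


def make_conditions(
    ts: TimeSeries,
    proteomes: Sequence[ProteomeSample],
    config: ToyConfig,
) -> List[ConditionSpec]:
    """One ConditionSpec per sampling time from interval rates.

    Before phosphate depletion, uptake rates are estimated from the
    whole exponential phase (q = μ̂ · ΔC/ΔX, pooling all pre-depletion
    points), because interval-wise differences of slowly-moving
    concentrations are noise-dominated early on.  After depletion,
    interval rates q = ΔC/(Δt·X̄) are used.  Bands are
    ±condition_tolerance; growth is μ̂ before depletion and the local
    log-slope (floored at 0) after.  Phosphate and products are left
    unconstrained: the model's own stoichiometry decides them.
    """
    from .cultivation_rates import detect_depletion, estimate_growth_rate, specific_rates

    rates = specific_rates(ts)
    tol = config.condition_tolerance
    by_time = {p.time: p for p in proteomes}
    t_dep = detect_depletion(ts, "phosphate", 0.0)
    if t_dep is None:
        t_dep = float(ts.times[-1])
    mu_hat = estimate_growth_rate(ts).mu

    x_dep = float(np.interp(t_dep, ts.times, ts.cdw))
    q_pre: Dict[str, float] = {}
    for compound in ("glucose", "glutamate"):
        c_dep = float(np.interp(t_dep, ts.times, ts.concentrations[compound]))
        delta_c = ts.concentrations[compound][0] - c_dep
        delta_x = x_dep - ts.cdw[0]
        q_pre[compound] = -mu_hat * delta_c / delta_x if delta_x > 0 else 0.0

    out: List[ConditionSpec] = []
    for i, t in enumerate(ts.times):
        pre = t <= t_dep
        j = max(0, i - 1)
        if pre:
            mu_local = mu_hat
        else:
            mu_local = max(0.0, math.log(ts.cdw[i] / ts.cdw[j]) / (ts.times[i] - ts.times[j]))
        bounds = {}
        for compound, ex in (("glucose", "EX_glc"), ("glutamate", "EX_glut")):
            rate = q_pre[compound] if pre else float(rates.q[compound][j])
            lb, ub = condition_bounds(rate, tol)
            bounds[ex] = (lb, min(ub, 0.0))  # uptake only
        out.append(ConditionSpec(
            strain_id=ts.strain_id,
            time=float(t),
            exchange_bounds=bounds,
            growth_rate=float(mu_local),
            proteome=by_time.get(float(t)),
        ))
    return out
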