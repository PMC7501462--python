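"""End-to-end orchestration: fixtures → curation → ec-models →
condition models → sampling → rate and omics reports.

Every stage is a pure function of the run configuration and seed, so a
rerun with the same config reproduces identical numeric outputs; the
manifest records the config hash, seed and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cultivation_rates import (
    detect_depletion,
    estimate_growth_rate,
    production_comparison,
    specific_rates,
)
from .enzyme_constraints import (
    ConditionError,
    add_enzyme_constraints,
    build_condition_model,
    ecfva_compare,
    split_reversible,
)
from .flux_sampling import metabolite_budget, pathway_activity, sample_vertices
from .gem_core import fba
from .omics_compare import align_by_regulon, expression_from_proteomes, pca_scores
from .synthetic_data import (
    BGC_PATHWAYS,
    PHO_REGULON,
    ToyConfig,
    build_toy_gem,
    make_conditions,
    make_phenotype_tests,
    make_proteome,
    make_thermo_kcats,
    make_timeseries,
)
from .thermo_curation import (
    accept_proposals,
    curate_atp_driven,
    evaluate_phenotypes,
    propose_directionality,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_fixture_bundle"]

STAGES = ("fixtures", "curate", "ecmodel", "condition", "sample", "rates", "omics")


@dataclass
class RunConfig:
    """One run's knobs; everything else derives deterministically."""

    seed: int = 42
    out_dir: str = "results"
    noise_sd: float = 0.02
    strains: Tuple[str, ...] = ("M145", "M1152")
    thermo_threshold: float = -30.0  # kJ/mol
    n_samples: int = 200  # vertex samples per condition
    top_k: int = 10  # pathways kept in the activity heatmap
    standardization: str = "joint"  # joint | per-strain Z-scoring
    condition_tolerance: float = 0.25

    def toy(self) -> ToyConfig:
        return ToyConfig(seed=self.seed, noise_sd=self.noise_sd,
                         condition_tolerance=self.condition_tolerance)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strains" in raw:
            raw["strains"] = tuple(raw["strains"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tsv(df: pd.DataFrame, out_dir: str, name: str) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_fixture_bundle(config: ToyConfig, out_dir: str) -> List[str]:
    """Write the full synthetic input bundle as TSV + SBML files."""
    from .model_io import write_model

    os.makedirs(out_dir, exist_ok=True)
    written: List[str] = []
    model = build_toy_gem(config, "M145")
    thermo, kcats, proteins = make_thermo_kcats(model, config)
    for strain in sorted(config.strains):
        m = build_toy_gem(config, strain)
        write_model(m, os.path.join(out_dir, f"model_{strain}"), "tabular")
        write_model(m, os.path.join(out_dir, f"model_{strain}.xml"), "sbml")
        written += [f"model_{strain}", f"model_{strain}.xml"]
    written.append(_tsv(pd.DataFrame(
        [{"reaction_id": t.reaction_id, "delta_g_kj_mol": t.delta_g,
          "uncertainty": t.uncertainty, "prior_label": t.prior_label} for t in thermo]
    ), out_dir, "thermo.tsv"))
    written.append(_tsv(pd.DataFrame(
        [{"protein_id": k.protein_id, "reaction_id": k.reaction_id,
          "direction": k.direction, "kcat_per_h": k.kcat,
          "match_level": k.match_level} for k in kcats]
    ), out_dir, "kcats.tsv"))
    written.append(_tsv(pd.DataFrame(
        [{"protein_id": p.protein_id, "gene_id": p.gene_id,
          "mw_g_per_mmol": p.molecular_weight} for p in proteins]
    ), out_dir, "proteins.tsv"))

    ts_rows, prot_rows, cond_rows = [], [], []
    for strain in sorted(config.strains):
        m = build_toy_gem(config, strain)
        ts = make_timeseries(config, strain)
        for i, t in enumerate(ts.times):
            ts_rows.append({"strain": strain, "replicate": ts.replicate_id,
                            "time_h": t, "variable": "cdw", "value": ts.cdw[i],
                            "unit": "g/L"})
            ts_rows.append({"strain": strain, "replicate": ts.replicate_id,
                            "time_h": t, "variable": "co2", "value": ts.co2[i],
                            "unit": "mmol/L/h"})
            for name, series in ts.concentrations.items():
                ts_rows.append({"strain": strain, "replicate": ts.replicate_id,
                                "time_h": t, "variable": name, "value": series[i],
                                "unit": "mmol/L"})
        proteomes = make_proteome(m, ts, config, kcats, proteins)
        for sample in proteomes:
            for pid, ab in sorted(sample.abundances.items()):
                prot_rows.append({"strain": strain, "time_h": sample.time,
                                  "protein_id": pid, "mmol_per_gdw": ab})
        for cond in make_conditions(ts, proteomes, config):
            for ex, (lb, ub) in cond.exchange_bounds.items():
                cond_rows.append({"strain": strain, "time_h": cond.time,
                                  "exchange_id": ex, "lb": lb, "ub": ub,
                                  "growth_rate": cond.growth_rate})
    written.append(_tsv(pd.DataFrame(ts_rows), out_dir, "timeseries.tsv"))
    written.append(_tsv(pd.DataFrame(prot_rows), out_dir, "proteome.tsv"))
    written.append(_tsv(pd.DataFrame(cond_rows), out_dir, "conditions.tsv"))

    tests = make_phenotype_tests(model, config)
    written.append(_tsv(pd.DataFrame(
        [{"test_id": t.test_id, "kind": t.kind, "spec": json.dumps(t.spec),
          "observed": int(t.observed)} for t in tests]
    ), out_dir, "phenotests.tsv"))
    return written


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> Dict[str, object]:
    """Run the requested stages; returns the result bundle in memory.

    Stage outputs are written under ``config.out_dir`` as TSV files
    plus a JSON manifest.  A failing stage aborts with its name after
    persisting whatever completed.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    toy = config.toy()
    results: Dict[str, object] = {}
    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "stages": {},
        "outputs": [],
    }

    def finish_stage(name: str, t0: float, outputs: Sequence[str] = ()) -> None:
        manifest["stages"][name] = round(time.time() - t0, 2)
        manifest["outputs"].extend(outputs)
        logger.info("stage %s done in %.1fs", name, manifest["stages"][name])

    try:
        # -- fixtures -------------------------------------------------
        t0 = time.time()
        gems = {s: build_toy_gem(toy, s) for s in sorted(toy.strains)}
        thermo, kcats, proteins = make_thermo_kcats(gems["M145"], toy)
        series = {s: make_timeseries(toy, s) for s in sorted(toy.strains)}
        proteomes = {
            s: make_proteome(gems[s], series[s], toy, kcats, proteins)
            for s in config.strains
        }
        tests = make_phenotype_tests(gems["M145"], toy)
        if "fixtures" in stages:
            fixture_files = write_fixture_bundle(toy, os.path.join(config.out_dir, "fixtures"))
            finish_stage("fixtures", t0, fixture_files)

        # -- thermodynamic curation ----------------------------------
        if "curate" in stages:
            t0 = time.time()
            uncurated = build_toy_gem(toy, "M145", curated=False)
            thermo_unc, _, _ = make_thermo_kcats(uncurated, toy)
            proposals = propose_directionality(uncurated, thermo_unc, config.thermo_threshold)
            atp = curate_atp_driven(
                uncurated, "atp", thermo_unc,
                exceptions={p.reaction_id for p in proposals},
            )
            curated, accepted, discarded = accept_proposals(uncurated, proposals + atp, tests)
            metrics = evaluate_phenotypes(curated, tests)
            accepted_ids = {p.reaction_id for p in accepted}
            report = pd.DataFrame(
                [{"reaction_id": p.reaction_id, "basis": p.basis,
                  "old_lb": p.old_bounds[0], "old_ub": p.old_bounds[1],
                  "new_lb": p.new_bounds[0], "new_ub": p.new_bounds[1],
                  "accepted": int(p.reaction_id in accepted_ids)}
                 for p in proposals + atp]
            )
            out1 = _tsv(report, config.out_dir, "curation_report.tsv")
            out2 = _tsv(pd.DataFrame([{
                "n_tests": metrics.n, "tp": metrics.tp, "fp": metrics.fp,
                "tn": metrics.tn, "fn": metrics.fn,
                "accuracy": metrics.accuracy, "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity, "mcc": metrics.mcc,
                "n_proposed": len(proposals) + len(atp),
                "n_discarded": len(discarded)}]), config.out_dir, "phenotype_metrics.tsv")
            results["curation"] = (curated, accepted, discarded, metrics)
            finish_stage("curate", t0, [out1, out2])

        # -- cultivation rates ---------------------------------------
        if "rates" in stages:
            t0 = time.time()
            rate_rows, prod_rows = [], []
            for strain, ts in series.items():
                est = estimate_growth_rate(ts)
                dep = detect_depletion(ts, "phosphate", 0.0)
                q = specific_rates(ts)
                rate_rows.append({
                    "strain": strain, "mu_per_h": est.mu, "mu_r2": est.mu_r2,
                    "window_start": est.mu_window[0], "window_end": est.mu_window[1],
                    "phosphate_depletion_h": dep,
                    "mean_uptake_ratio_glc_glut": float(np.nanmean(q.uptake_ratio)),
                })
            for alt in sorted(set(toy.strains) - {"M145"}):
                for germ in ("A", "B"):
                    prod_rows.append({
                        "strain": alt, "compound": f"germicidin_{germ}",
                        "percent_reduction_vs_M145": production_comparison(
                            series["M145"], series[alt], f"germicidin_{germ}"),
                    })
            out1 = _tsv(pd.DataFrame(rate_rows), config.out_dir, "rates.tsv")
            out2 = _tsv(pd.DataFrame(prod_rows), config.out_dir, "production_comparison.tsv")
            results["rates"] = (rate_rows, prod_rows)
            finish_stage("rates", t0, [out1, out2])

        # -- enzyme-constrained models -------------------------------
        need_ec = {"ecmodel", "condition", "sample"} & set(stages)
        ec_models = {}
        if need_ec:
            t0 = time.time()
            for strain in config.strains:
                strain_kcats = [k for k in kcats if k.reaction_id in gems[strain].reactions]
                ec_models[strain] = add_enzyme_constraints(
                    split_reversible(gems[strain]), strain_kcats, proteins, toy.pool
                )
            if "ecmodel" in stages:
                comparison = ecfva_compare(gems["M145"], ec_models["M145"])
                widths = comparison.widths().reset_index()
                out1 = _tsv(widths, config.out_dir, "ecfva_widths.tsv")
                results["ecfva"] = comparison
                finish_stage("ecmodel", t0, [out1])

        # -- condition-specific models + sampling --------------------
        if {"condition", "sample"} & set(stages):
            t0 = time.time()
            condition_models = {}
            co2_rate: Dict[str, float] = {}
            skipped = []
            for strain in config.strains:
                ts = series[strain]
                conds = make_conditions(ts, proteomes[strain], toy)
                for i, cond in enumerate(conds):
                    label = f"{strain}@{cond.time:g}h"
                    try:
                        cm = build_condition_model(
                            ec_models[strain], cond, config.condition_tolerance)
                    except ConditionError as exc:
                        logger.warning("condition %s skipped: %s", label, exc)
                        skipped.append(label)
                        continue
                    condition_models[label] = (strain, cond, cm)
                    co2_rate[label] = float(ts.co2[i] / ts.cdw[i])
            results["conditions"] = condition_models
            results["skipped_conditions"] = skipped
            if "condition" in stages:
                rows = [{"condition": label, "strain": s, "time_h": c.time,
                         "growth_rate": c.growth_rate,
                         "fba_mu": fba(cm.model).objective_value}
                        for label, (s, c, cm) in condition_models.items()]
                out1 = _tsv(pd.DataFrame(rows), config.out_dir, "condition_models.tsv")
                finish_stage("condition", t0, [out1])

        if "sample" in stages:
            t0 = time.time()
            samples = {}
            for k, (label, (strain, cond, cm)) in enumerate(condition_models.items()):
                samples[label] = sample_vertices(cm, config.n_samples,
                                                 seed=config.seed * 1000 + k)
            mean_rows = []
            for label, s in samples.items():
                for rid, v in s.net_means().values.items():
                    mean_rows.append({"condition": label, "reaction": rid, "mean_flux": v})
            out1 = _tsv(pd.DataFrame(mean_rows), config.out_dir, "mean_fluxes.tsv")

            subsystems = {r.id: r.pathway for r in gems["M145"].reactions.values()}
            outs = [out1]
            if config.standardization == "joint":
                groups = {"joint": list(samples)}
            else:
                groups = {s: [l for l in samples if l.startswith(s + "@")]
                          for s in config.strains}
            pa_frames = []
            for gname, labels in groups.items():
                pa = pathway_activity(
                    {l: samples[l] for l in labels}, subsystems,
                    {l: co2_rate[l] for l in labels}, top_k=config.top_k,
                    force_include=list(BGC_PATHWAYS.values()),
                )
                long = pa.zscores.reset_index(names="pathway").melt(
                    id_vars="pathway", var_name="condition", value_name="zscore")
                long["normalized"] = [
                    pa.normalized.loc[p, c] for p, c in zip(long["pathway"], long["condition"])]
                long["raw"] = [
                    pa.raw.loc[p, c] for p, c in zip(long["pathway"], long["condition"])]
                long["flagged_zero_sd"] = long["pathway"].isin(pa.zero_variance).astype(int)
                long.insert(0, "standardization", gname)
                pa_frames.append(long)
                results[f"pathway_activity_{gname}"] = pa
            outs.append(_tsv(pd.concat(pa_frames), config.out_dir, "pathway_activity.tsv"))

            budget_rows = []
            for label, s in samples.items():
                strain = condition_models[label][0]
                b = metabolite_budget(s.net_means(), gems[strain], "malcoa")
                for rid, v in b.producing.items():
                    budget_rows.append({"condition": label, "metabolite": "malcoa",
                                        "side": "producing", "reaction": rid, "rate": v})
                for rid, v in b.consuming.items():
                    budget_rows.append({"condition": label, "metabolite": "malcoa",
                                        "side": "consuming", "reaction": rid, "rate": v})
            outs.append(_tsv(pd.DataFrame(budget_rows), config.out_dir, "malcoa_budget.tsv"))
            results["samples"] = samples
            finish_stage("sample", t0, outs)

        # -- omics ----------------------------------------------------
        if "omics" in stages:
            t0 = time.time()
            all_samples = [p for s in config.strains for p in proteomes[s]]
            expr = expression_from_proteomes(all_samples)
            pca = pca_scores(expr, n_components=2)
            pca_df = pca.scores.reset_index(names="sample")
            pca_df["strain"] = pca.samples["strain"].to_numpy()
            pca_df["time_h"] = pca.samples["time"].to_numpy()
            out1 = _tsv(pca_df, config.out_dir, "pca_scores.tsv")
            out2 = _tsv(pd.DataFrame(
                {"component": [f"PC{i+1}" for i in range(len(pca.percent_variance))],
                 "percent_variance": pca.percent_variance}),
                config.out_dir, "pca_variance.tsv")
            outs = [out1, out2]
            if len(config.strains) >= 2:
                a, b = config.strains[0], config.strains[1]
                expr_a = expression_from_proteomes(proteomes[a])
                expr_b = expression_from_proteomes(proteomes[b])
                amap = align_by_regulon(expr_a, expr_b, set(PHO_REGULON))
                out3 = _tsv(pd.DataFrame(
                    [{"index_a": i, "index_b": j,
                      "time_a": amap.times_a[i], "time_b": amap.times_b[j]}
                     for i, j in amap.pairs]), config.out_dir, "alignment.tsv")
                outs.append(out3)
                results["alignment"] = amap
            results["pca"] = pca
            finish_stage("omics", t0, outs)
    except Exception as exc:
        current = set(STAGES) - set(manifest["stages"])
        logger.error("pipeline aborted (completed stages: %s): %s",
                     sorted(manifest["stages"]), exc)
        raise RuntimeError(
            f"pipeline failed after stages {sorted(manifest['stages'])}: {exc}"
        ) from exc
    finally:
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
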