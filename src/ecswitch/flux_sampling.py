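"""Unbiased flux estimation by random-objective vertex sampling.

Each draw maximizes an LP objective with i.i.d. standard-normal
coefficients over all reactions; the simplex optimum is a vertex of
the flux polytope.  Sign symmetry of the coefficients covers both
directions, so maximization alone is unbiased.  Vertex means summarize
pathway activity: per condition, pathway flux is the sum of |mean
flux| over member reactions, divided by the condition's CO₂ evolution
rate, then Z-scored per pathway across the standardization set (both
strains jointly by default, so cross-strain levels stay comparable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .enzyme_constraints import EcModel
from .gem_core import FluxDistribution, LinearProblem, MetabolicModel, ModelError, fba

__all__ = [
    "FluxSampleSet",
    "PathwayActivity",
    "MetaboliteBudget",
    "sample_vertices",
    "pathway_activity",
    "metabolite_budget",
]

logger = logging.getLogger(__name__)


@dataclass
class FluxSampleSet:
    """Vertex samples of one model's flux polytope.

    ``matrix`` is n_samples × n_reactions in ``reaction_ids`` order;
    ``objectives`` holds the random objective vectors actually used.
    """

    reaction_ids: List[str]
    matrix: np.ndarray
    objectives: np.ndarray
    seed: int
    ec: Optional[EcModel] = None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def means(self) -> FluxDistribution:
        mean = self.matrix.mean(axis=0)
        return FluxDistribution(dict(zip(self.reaction_ids, mean)), float("nan"))

    def net_means(self) -> FluxDistribution:
        """Mean fluxes projected onto original reactions (ec models)."""
        if self.ec is None:
            return self.means()
        return FluxDistribution(self.ec.net_fluxes(self.means().values), float("nan"))


def sample_vertices(
    model: Union[MetabolicModel, EcModel],
    n: int,
    seed: int,
    max_redraws: int = 10,
) -> FluxSampleSet:
    """Sample n vertices of the feasible flux space.

    Identical (model, n, seed) give identical sample matrices.  An
    unbounded random LP (impossible with finite default bounds) is
    redrawn with a fresh objective, logged.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    ec = model if isinstance(model, EcModel) else None
    plain = ec.model if ec is not None else model
    base = fba(plain)
    if base.status == "infeasible":
        raise ModelError("cannot sample an infeasible model")
    lp = LinearProblem(plain)
    rng = np.random.default_rng(seed)
    n_rxn = len(lp.rxn_ids)
    matrix = np.empty((n, n_rxn))
    objectives = np.empty((n, n_rxn))
    for i in range(n):
        for attempt in range(max_redraws):
            c = rng.standard_normal(n_rxn)
            status, x, _ = lp.solve(dict(zip(lp.rxn_ids, c)), sense="max")
            if status == "optimal":
                break
            logger.warning("sample %d: %s random LP, redrawing objective", i, status)
        else:
            raise ModelError("persistent unbounded/infeasible random objectives")
        matrix[i] = x
        objectives[i] = c
    return FluxSampleSet(list(lp.rxn_ids), matrix, objectives, seed, ec=ec)


@dataclass
class PathwayActivity:
    """Pathways × conditions activity at three stages of processing."""

    raw: pd.DataFrame
    normalized: pd.DataFrame
    zscores: pd.DataFrame
    co2_rate: Dict[str, float]
    zero_variance: Set[str] = field(default_factory=set)


def _mean_fluxes(sample) -> Mapping[str, float]:
    if isinstance(sample, FluxSampleSet):
        return sample.net_means().values
    if isinstance(sample, FluxDistribution):
        return sample.values
    return sample  # plain mapping


def pathway_activity(
    samples_per_condition: Mapping[str, object],
    subsystems: Mapping[str, str],
    co2_rate: Mapping[str, float],
    top_k: int = 10,
    force_include: Sequence[str] = (),
    signed: bool = False,
) -> PathwayActivity:
    """Aggregate mean fluxes into CO₂-normalized pathway Z-scores.

    ``samples_per_condition`` maps condition labels to FluxSampleSets
    (or precomputed mean-flux mappings); ``subsystems`` maps reaction
    ids to pathway labels; reactions without a label are ignored with a
    warning.  Pathway activity is Σ|mean flux| (or the signed sum with
    ``signed``).  Rows are ranked by variance of the normalized values
    and the top_k kept; ``force_include`` names are always retained.
    Zero-variance rows Z-score to 0 and are flagged, never NaN.
    """
    conditions = list(samples_per_condition)
    for cond in conditions:
        if co2_rate.get(cond, 0.0) <= 0:
            raise ValueError(f"non-positive CO2 rate for condition {cond!r}")
    pathways = sorted(set(subsystems.values()))
    raw = pd.DataFrame(0.0, index=pathways, columns=conditions)
    warned: Set[str] = set()
    for cond in conditions:
        means = _mean_fluxes(samples_per_condition[cond])
        for rid, flux in means.items():
            pathway = subsystems.get(rid)
            if pathway is None:
                if rid not in warned:
                    warned.add(rid)
                continue
            raw.loc[pathway, cond] += flux if signed else abs(flux)
    if warned:
        logger.warning("%d reactions without a pathway label were ignored", len(warned))
    normalized = raw.div(pd.Series({c: co2_rate[c] for c in conditions}), axis=1)

    zero_variance: Set[str] = set()
    z = normalized.copy()
    for pathway in z.index:
        row = normalized.loc[pathway]
        sd = row.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            z.loc[pathway] = 0.0
            zero_variance.add(pathway)
        else:
            z.loc[pathway] = (row - row.mean()) / sd

    variances = normalized.var(axis=1, ddof=1).sort_values(ascending=False)
    keep = list(variances.index[:top_k])
    for name in force_include:
        if name in z.index and name not in keep:
            keep.append(name)
    return PathwayActivity(
        raw=raw.loc[keep],
        normalized=normalized.loc[keep],
        zscores=z.loc[keep],
        co2_rate=dict(co2_rate),
        zero_variance={p for p in zero_variance if p in keep},
    )


@dataclass
class MetaboliteBudget:
    metabolite_id: str
    producing: Dict[str, float]
    consuming: Dict[str, float]

    @property
    def total_production(self) -> float:
        return sum(self.producing.values())

    @property
    def total_consumption(self) -> float:
        return sum(self.consuming.values())


def metabolite_budget(
    fluxes: Union[FluxDistribution, Mapping[str, float]],
    model: MetabolicModel,
    metabolite: str,
    tol: float = 1e-9,
) -> MetaboliteBudget:
    """Partition a metabolite's turnover into sources and sinks.

    Each reaction contributes coefficient × flux; positive rates are
    producers, negative ones consumers (stored as magnitudes).  At
    steady state the two totals balance.
    """
    if metabolite not in model.metabolites:
        raise ModelError(f"unknown metabolite {metabolite!r}")
    values = fluxes.values if isinstance(fluxes, FluxDistribution) else fluxes
    producing: Dict[str, float] = {}
    consuming: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        coef = rxn.stoichiometry.get(metabolite)
        if coef is None:
            continue
        rate = coef * values.get(rid, 0.0)
        if rate > tol:
            producing[rid] = rate
        elif rate < -tol:
            consuming[rid] = -rate
    return MetaboliteBudget(metabolite, producing, consuming)
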