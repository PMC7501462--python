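"""GECKO-style enzyme constraints and condition-specific models.

The transformation splits every reversible reaction into forward and
backward irreversible copies, expands OR-branches of gene rules into
one copy per isozyme, and couples each copy to its enzyme(s): a copy
carrying flux v consumes each required enzyme pseudo-metabolite at
coefficient 1/kcat (AND-complex subunits all at 1/kcat, subunit
stoichiometry 1).  Enzymes are supplied either from a measured usage
reaction (bounded by the protein's abundance, mmol·gDW⁻¹) or drawn
from a shared protein pool weighted by molecular weight; the pool
exchange is capped at sigma·f·p_total (g·gDW⁻¹).  Reactions with a
gene rule but no kcat match receive the model-median kcat and are
flagged; gene-rule-free reactions stay unconstrained.

Condition-specific models additionally pin measured exchange rates to
±tolerance bands and bound growth below by (1−tolerance)·measured μ.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from . import gpr
from .gem_core import (
    DEFAULT_BOUND,
    FEASIBILITY_TOL,
    FluxDistribution,
    FvaResult,
    LinearProblem,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    fba,
    fva,
    optimize,
)

__all__ = [
    "KcatEntry",
    "ProteinInfo",
    "ProteomeSample",
    "PoolParams",
    "EcModel",
    "ConditionSpec",
    "ConditionError",
    "split_reversible",
    "add_enzyme_constraints",
    "apply_proteome",
    "apply_condition",
    "build_condition_model",
    "ecfva_compare",
    "EcFvaComparison",
]

logger = logging.getLogger(__name__)

ENZYME_COMPARTMENT = "enzyme"
POOL_MET = "prot_pool"
POOL_EXCHANGE = "prot_pool_exchange"


@dataclass
class KcatEntry:
    protein_id: str
    reaction_id: str
    direction: str = "forward"  # forward | backward
    kcat: float = 3600.0  # turnover number, h^-1
    match_level: str = "exact"  # exact | median_fallback

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ValueError(f"kcat must be positive ({self.protein_id}/{self.reaction_id})")


@dataclass
class ProteinInfo:
    protein_id: str
    molecular_weight: float  # g per mmol
    gene_id: str

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"non-positive molecular weight for {self.protein_id}")


@dataclass
class ProteomeSample:
    strain_id: str
    time: float  # h after inoculation
    abundances: Dict[str, float] = field(default_factory=dict)  # mmol per gDW

    def __post_init__(self) -> None:
        bad = {p: a for p, a in self.abundances.items() if a < 0}
        if bad:
            raise ValueError(f"negative abundances: {sorted(bad)}")


@dataclass
class PoolParams:
    p_total: float = 0.45  # total protein mass fraction, g/gDW
    f: float = 0.4  # modeled-mass fraction of the proteome
    sigma: float = 0.5  # average in vivo saturation

    def __post_init__(self) -> None:
        if not (self.p_total > 0 and 0 < self.f <= 1 and 0 < self.sigma <= 1):
            raise ValueError("pool parameters out of range")

    @property
    def cap(self) -> float:
        """Pool exchange upper bound, g protein per gDW."""
        return self.sigma * self.f * self.p_total


@dataclass
class ConditionSpec:
    """Measured rates and proteome defining one strain/time condition."""

    strain_id: str
    time: float
    exchange_bounds: Dict[str, Tuple[float, float]]  # already ± tolerance
    growth_rate: float  # measured μ, h^-1
    proteome: Optional[ProteomeSample] = None

    def __post_init__(self) -> None:
        for ex, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ValueError(f"condition {self.strain_id}@{self.time}: lb > ub for {ex}")


class ConditionError(ModelError):
    """A condition's measured rates are mutually infeasible."""

    def __init__(self, message: str, violations: Optional[Dict[str, float]] = None):
        super().__init__(message)
        self.violations = violations or {}


@dataclass
class EcModel:
    """An enzyme-constrained model plus its bookkeeping maps.

    ``model`` is a plain :class:`MetabolicModel` (enzymes are species,
    usages/draws are reactions) so every LP primitive applies
    unchanged.  ``forward_copies``/``backward_copies`` map each
    original reaction id to its split/isozyme copies; net flux of an
    original reaction is the forward sum minus the backward sum.
    """

    model: MetabolicModel
    parent_reactions: List[str]
    forward_copies: Dict[str, List[str]]
    backward_copies: Dict[str, List[str]]
    proteins: Dict[str, ProteinInfo]
    usage_reactions: Dict[str, str]  # protein -> usage/draw reaction id
    measured: Set[str] = field(default_factory=set)
    pool_params: PoolParams = field(default_factory=PoolParams)
    kcat_fallbacks: List[str] = field(default_factory=list)

    def copy(self) -> "EcModel":
        return EcModel(
            model=self.model.copy(),
            parent_reactions=list(self.parent_reactions),
            forward_copies={k: list(v) for k, v in self.forward_copies.items()},
            backward_copies={k: list(v) for k, v in self.backward_copies.items()},
            proteins=dict(self.proteins),
            usage_reactions=dict(self.usage_reactions),
            measured=set(self.measured),
            pool_params=self.pool_params,
            kcat_fallbacks=list(self.kcat_fallbacks),
        )

    def net_coefficients(self, original_id: str) -> Dict[str, float]:
        """Linear combination of copy fluxes giving the original's net flux."""
        coeffs: Dict[str, float] = {}
        for rid in self.forward_copies.get(original_id, []):
            coeffs[rid] = coeffs.get(rid, 0.0) + 1.0
        for rid in self.backward_copies.get(original_id, []):
            coeffs[rid] = coeffs.get(rid, 0.0) - 1.0
        return coeffs

    def net_fluxes(self, values: Mapping[str, float]) -> Dict[str, float]:
        """Project a flux vector of the ec model onto original reactions."""
        out = {}
        for orig in self.parent_reactions:
            out[orig] = sum(
                c * values.get(rid, 0.0) for rid, c in self.net_coefficients(orig).items()
            )
        return out


# -- structural transformation ----------------------------------------


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible reaction into two irreversible copies.

    A reaction with bounds (lb < 0 < ub) becomes a forward copy with
    bounds (0, ub) and a ``<id>_REV`` copy with the negated
    stoichiometry and bounds (0, -lb).  Irreversible reactions are
    untouched.  The mapping is recorded on the returned model as
    ``split_pairs`` (forward id -> reverse id); any feasible flux of
    the original model decomposes as v = v_fwd − v_bwd and FBA optima
    are preserved.
    """
    out = model.copy()
    pairs: Dict[str, str] = {}
    for rid in list(out.reactions):
        rxn = out.reactions[rid]
        if rxn.lower_bound < 0 < rxn.upper_bound:
            rev = rxn.copy()
            rev.id = rid + "_REV"
            rev.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
            rev.lower_bound, rev.upper_bound = 0.0, -rxn.lower_bound
            rxn.lower_bound = 0.0
            out.add_reaction(rev)
            pairs[rid] = rev.id
    out.split_pairs = pairs  # type: ignore[attr-defined]
    return out


def _median_kcat(kcats: Sequence[KcatEntry]) -> float:
    if not kcats:
        return 3600.0
    return statistics.median(e.kcat for e in kcats)


def add_enzyme_constraints(
    model: MetabolicModel,
    kcats: Sequence[KcatEntry],
    proteins: Sequence[ProteinInfo],
    pool: PoolParams = PoolParams(),
) -> EcModel:
    """Couple a split model's reactions to enzyme pseudo-metabolites.

    ``model`` must already be the output of :func:`split_reversible`
    (its ``split_pairs`` attribute supplies the forward/backward map).
    All enzymes initially draw from the shared pool; apply a proteome
    with :func:`apply_proteome` to bound measured enzymes individually.
    """
    split_pairs: Dict[str, str] = getattr(model, "split_pairs", {})
    rev_ids = set(split_pairs.values())
    prot_by_gene: Dict[str, ProteinInfo] = {}
    prot_by_id: Dict[str, ProteinInfo] = {}
    for p in proteins:
        prot_by_id[p.protein_id] = p
        if p.gene_id in prot_by_gene:
            logger.warning("gene %s has several proteins; keeping %s",
                           p.gene_id, prot_by_gene[p.gene_id].protein_id)
        else:
            prot_by_gene[p.gene_id] = p

    kcat_lookup: Dict[Tuple[str, str, str], float] = {}
    for e in kcats:
        if e.reaction_id not in model.reactions and e.reaction_id + "_REV" not in model.reactions:
            raise ModelError(f"kcat entry for unknown reaction {e.reaction_id!r}")
        if e.direction not in ("forward", "backward"):
            raise ModelError(f"kcat entry with unknown direction {e.direction!r}")
        kcat_lookup[(e.reaction_id, e.direction, e.protein_id)] = e.kcat
    median = _median_kcat(kcats)

    out = model.copy()
    out.add_metabolite(Metabolite(POOL_MET, "shared protein pool", ENZYME_COMPARTMENT))
    out.add_reaction(
        Reaction(POOL_EXCHANGE, {POOL_MET: 1.0}, lower_bound=0.0, upper_bound=pool.cap,
                 subsystem="Protein pool")
    )

    forward_copies: Dict[str, List[str]] = {}
    backward_copies: Dict[str, List[str]] = {}
    used_proteins: Dict[str, ProteinInfo] = {}
    fallbacks: List[str] = []

    def ensure_enzyme(p: ProteinInfo) -> str:
        met_id = f"prot_{p.protein_id}"
        if met_id not in out.metabolites:
            out.add_metabolite(Metabolite(met_id, f"enzyme {p.protein_id}", ENZYME_COMPARTMENT))
            out.add_reaction(
                Reaction(
                    f"draw_prot_{p.protein_id}",
                    {POOL_MET: -p.molecular_weight, met_id: 1.0},
                    lower_bound=0.0,
                    upper_bound=DEFAULT_BOUND,
                    subsystem="Protein usage",
                )
            )
            used_proteins[p.protein_id] = p
        return met_id

    for rid in list(model.reactions):
        rxn = out.reactions[rid]
        if not rxn.gene_rule:
            key = rid[:-4] if rid in rev_ids else rid
            side = backward_copies if rid in rev_ids else forward_copies
            side.setdefault(key, []).append(rid)
            continue
        original = rid[:-4] if rid in rev_ids else rid
        direction = "backward" if rid in rev_ids else "forward"
        side = backward_copies if rid in rev_ids else forward_copies
        complexes = gpr.isozyme_complexes(rxn.gene_rule)
        copy_ids = [rid] if len(complexes) == 1 else [f"{rid}_No{i+1}" for i in range(len(complexes))]
        if len(complexes) > 1:
            template = rxn.copy()
            out.remove_reaction(rid)
            for cid, genes in zip(copy_ids, complexes):
                copy = template.copy()
                copy.id = cid
                copy.gene_rule = " and ".join(sorted(genes))
                out.add_reaction(copy)
        for cid, genes in zip(copy_ids, complexes):
            copy = out.reactions[cid]
            for gene in sorted(genes):
                prot = prot_by_gene.get(gene)
                if prot is None:
                    logger.warning("no protein record for gene %s (reaction %s); uncoupled", gene, cid)
                    continue
                kcat = kcat_lookup.get((original, direction, prot.protein_id))
                if kcat is None:
                    kcat = median
                    fallbacks.append(cid)
                met_id = ensure_enzyme(prot)
                copy.stoichiometry[met_id] = copy.stoichiometry.get(met_id, 0.0) - 1.0 / kcat
        side.setdefault(original, []).append(copy_ids[0] if len(copy_ids) == 1 else None)
        if len(copy_ids) > 1:
            side[original].remove(None)
            side[original].extend(copy_ids)

    parent = [r for r in model.reactions if r not in rev_ids]
    usage = {p: f"draw_prot_{p}" for p in used_proteins}
    return EcModel(
        model=out,
        parent_reactions=parent,
        forward_copies=forward_copies,
        backward_copies=backward_copies,
        proteins=used_proteins,
        usage_reactions=usage,
        pool_params=pool,
        kcat_fallbacks=sorted(set(fallbacks)),
    )


# -- proteome integration ---------------------------------------------


def apply_proteome(
    ec: EcModel,
    sample: ProteomeSample,
    flexibilize: bool = False,
    required_growth: Optional[float] = None,
    relaxation_budget: int = 20,
) -> EcModel:
    """Bound measured enzymes by abundance; rest stays on the pool.

    Each measured protein's usage becomes a direct supply reaction
    bounded above by its abundance (mmol·gDW⁻¹); the pool cap is
    reduced to sigma·(f·p_total − measured mass), floored at zero, so
    the pool only feeds unmeasured enzymes.  With ``flexibilize`` and a
    ``required_growth``, the most limiting measured bound (largest
    growth shadow price) is doubled, at most ``relaxation_budget``
    times, until the growth target is reachable.
    """
    out = ec.copy()
    pool = out.pool_params
    measured_mass = 0.0
    unknown = sorted(set(sample.abundances) - set(out.proteins))
    if unknown:
        logger.info("proteome sample has %d proteins not in the model (ignored)", len(unknown))
    for pid, prot in out.proteins.items():
        if pid not in sample.abundances:
            continue
        abundance = sample.abundances[pid]
        measured_mass += abundance * prot.molecular_weight
        met_id = f"prot_{pid}"
        draw_id = f"draw_prot_{pid}"
        usage_id = f"usage_prot_{pid}"
        if draw_id in out.model.reactions:
            out.model.remove_reaction(draw_id)
        if usage_id in out.model.reactions:
            out.model.reactions[usage_id].upper_bound = abundance
        else:
            out.model.add_reaction(
                Reaction(usage_id, {met_id: 1.0}, lower_bound=0.0, upper_bound=abundance,
                         subsystem="Protein usage")
            )
        out.usage_reactions[pid] = usage_id
        out.measured.add(pid)
    cap = max(0.0, pool.sigma * (pool.f * pool.p_total - measured_mass))
    out.model.reactions[POOL_EXCHANGE].upper_bound = cap
    logger.info("proteome %s@%s: measured mass %.4f g/gDW, pool cap %.4f",
                sample.strain_id, sample.time, measured_mass, cap)

    if flexibilize and required_growth is not None:
        _flexibilize(out, required_growth, relaxation_budget)
    return out


def _flexibilize(ec: EcModel, required_growth: float, budget: int) -> None:
    """Double the most limiting measured usage bound until μ is reachable."""
    for iteration in range(budget):
        sol = fba(ec.model)
        if sol.status == "optimal" and sol.objective_value >= required_growth - FEASIBILITY_TOL:
            return
        usage_ids = [ec.usage_reactions[p] for p in sorted(ec.measured)]
        best_id, best_gain = None, 0.0
        base = sol.objective_value if sol.status == "optimal" else -math.inf
        for uid in usage_ids:
            rxn = ec.model.reactions[uid]
            if sol.status == "optimal" and sol.values.get(uid, 0.0) < rxn.upper_bound - 1e-9:
                continue  # bound not active, zero shadow price
            old = rxn.upper_bound
            rxn.upper_bound = old * 2 if old > 0 else 1e-6
            probe = fba(ec.model)
            gain = (probe.objective_value - base) if probe.status == "optimal" else 0.0
            rxn.upper_bound = old
            if gain > best_gain + 1e-12:
                best_id, best_gain = uid, gain
        if best_id is None:
            raise ConditionError(
                f"growth {required_growth:.4g} unreachable after {iteration} relaxations; "
                "no single protein bound is limiting"
            )
        rxn = ec.model.reactions[best_id]
        rxn.upper_bound = rxn.upper_bound * 2 if rxn.upper_bound > 0 else 1e-6
        logger.info("flexibilize: doubled %s to %.4g", best_id, rxn.upper_bound)
    sol = fba(ec.model)
    if not (sol.status == "optimal" and sol.objective_value >= required_growth - FEASIBILITY_TOL):
        raise ConditionError(
            f"growth {required_growth:.4g} still unreachable after {budget} relaxations"
        )


# -- condition-specific models ----------------------------------------


def apply_condition(
    ec: EcModel,
    spec: ConditionSpec,
    tolerance_fraction: float = 0.05,
) -> EcModel:
    """Pin measured exchange rates and growth for one strain/time.

    Exchange bounds in ``spec`` are interpreted as measured rates with
    the band already applied when given as (lb, ub); growth is bounded
    below at (1 − tolerance)·measured μ.  An infeasible rate set is
    diagnosed with an elastic relaxation LP and reported.
    """
    out = ec.copy()
    constrained: Dict[str, Tuple[float, float]] = {}
    for ex_id, (lb, ub) in spec.exchange_bounds.items():
        if ex_id not in out.model.reactions:
            raise ModelError(f"condition references unknown exchange {ex_id!r}")
        rxn = out.model.reactions[ex_id]
        rxn.lower_bound, rxn.upper_bound = lb, ub
        constrained[ex_id] = (lb, ub)
    obj = out.model.objective
    if obj is not None and spec.growth_rate > 0:
        lo = (1.0 - tolerance_fraction) * spec.growth_rate
        out.model.reactions[obj].lower_bound = lo
        constrained[obj] = (lo, out.model.reactions[obj].upper_bound)

    sol = fba(out.model)
    if sol.status == "infeasible":
        violations = _diagnose_infeasibility(out.model, constrained)
        raise ConditionError(
            f"condition {spec.strain_id}@{spec.time}h infeasible; "
            f"violated constraints: {sorted(violations)}",
            violations,
        )
    return out


def condition_bounds(rate: float, tolerance_fraction: float) -> Tuple[float, float]:
    """Measured rate ± tolerance_fraction·|rate| as an (lb, ub) band."""
    width = tolerance_fraction * abs(rate)
    return (rate - width, rate + width)


def _diagnose_infeasibility(
    model: MetabolicModel, constrained: Mapping[str, Tuple[float, float]]
) -> Dict[str, float]:
    """Minimal total relaxation of the offending constraints.

    Elastic slacks are added to every condition-imposed bound and their
    sum minimized subject to S·v = 0; constraints needing nonzero slack
    are returned with the slack magnitude.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    index = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    ids = sorted(constrained)
    k = len(ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids], dtype=float)
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids], dtype=float)
    for r in ids:  # relax the constrained bounds; slacks pay for violations
        lb[index[r]] = -10 * DEFAULT_BOUND
        ub[index[r]] = 10 * DEFAULT_BOUND
    A_ub = np.zeros((2 * k, n + 2 * k))
    b_ub = np.zeros(2 * k)
    for i, r in enumerate(ids):
        j = index[r]
        A_ub[2 * i, j] = 1.0
        A_ub[2 * i, n + 2 * i] = -1.0
        b_ub[2 * i] = constrained[r][1]
        A_ub[2 * i + 1, j] = -1.0
        A_ub[2 * i + 1, n + 2 * i + 1] = -1.0
        b_ub[2 * i + 1] = -constrained[r][0]
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    bounds = [(l, u) for l, u in zip(lb, ub)] + [(0, None)] * (2 * k)
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=np.hstack([S, np.zeros((S.shape[0], 2 * k))]),
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return {r: math.inf for r in ids}
    out: Dict[str, float] = {}
    for i, r in enumerate(ids):
        slack = res.x[n + 2 * i] + res.x[n + 2 * i + 1]
        if slack > 1e-6:
            out[r] = float(slack)
    return out


def build_condition_model(
    ec: EcModel,
    spec: ConditionSpec,
    tolerance_fraction: float = 0.05,
    flexibilize: bool = True,
) -> EcModel:
    """Proteome + rates in one step: the condition-specific ec-model."""
    out = ec
    if spec.proteome is not None:
        out = apply_proteome(
            out,
            spec.proteome,
            flexibilize=flexibilize,
            required_growth=(1.0 - tolerance_fraction) * spec.growth_rate,
        )
    return apply_condition(out, spec, tolerance_fraction)


# -- flux variability comparison --------------------------------------


@dataclass
class EcFvaComparison:
    gem_ranges: Dict[str, Tuple[float, float]]
    ec_ranges: Dict[str, Tuple[float, float]]

    def widths(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        import pandas as pd

        rows = []
        for rid in self.gem_ranges:
            glo, ghi = self.gem_ranges[rid]
            elo, ehi = self.ec_ranges[rid]
            rows.append({"reaction": rid, "gem_width": ghi - glo, "ec_width": ehi - elo})
        return pd.DataFrame(rows).set_index("reaction")

    def cumulative(self) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted width vectors (gem, ec) for cumulative-distribution plots."""
        df = self.widths()
        return np.sort(df["gem_width"].to_numpy()), np.sort(df["ec_width"].to_numpy())


def ecfva_compare(
    gem: MetabolicModel,
    ec: EcModel,
    reactions: Optional[Sequence[str]] = None,
    fraction_of_optimum: float = 0.0,
) -> EcFvaComparison:
    """Per-reaction FVA range in the GEM vs net-flux range in the ec model.

    The ec range optimizes the net flux v_fwd − v_bwd of each split
    pair directly (one max-LP and one min-LP on the linear
    combination), which is immune to futile-cycle inflation of the
    individual copies.
    """
    targets = list(reactions) if reactions is not None else list(ec.parent_reactions)
    gem_res = fva(gem, targets, fraction_of_optimum)
    ec_work = ec.model
    if fraction_of_optimum > 0:
        sol = fba(ec.model)
        if sol.status != "optimal":
            raise ModelError(f"ec base FBA is {sol.status}")
        ec_work = ec.model.copy()
        obj = ec_work.objective
        ec_work.reactions[obj].lower_bound = fraction_of_optimum * sol.objective_value
    lp = LinearProblem(ec_work)
    ec_ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        coeffs = ec.net_coefficients(rid)
        _, _, lo = lp.solve(coeffs, sense="min")
        _, _, hi = lp.solve(coeffs, sense="max")
        ec_ranges[rid] = (lo, hi)
    return EcFvaComparison(gem_ranges=dict(gem_res.ranges), ec_ranges=ec_ranges)
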