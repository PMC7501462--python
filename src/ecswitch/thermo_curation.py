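"""Thermodynamics-guided reaction-directionality curation.

Standard transformed Gibbs-energy estimates classify reactions as
forward-irreversible (ΔG' ≤ −30 kJ/mol by default), backward-
irreversible (ΔG' ≥ +30 kJ/mol, the symmetric application of the same
lenient threshold) or reversible.  ATP-driven reactions are separately
curated: a reversible ATP consumer is assumed forward-irreversible
unless its ΔG' is positive or it is a listed exception (nucleoside
diphosphate kinase, ATP synthase and analogs).  Proposals are then
arbitrated against growth/knockout phenotype data: all proposals are
applied, and each is reverted (in ascending reaction-id order) iff the
reversion strictly improves the Matthews correlation coefficient of
the phenotype predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .gem_core import DEFAULT_BOUND, MetabolicModel, ModelError, fba

__all__ = [
    "ThermoRecord",
    "DirectionalityProposal",
    "PhenotypeTest",
    "ConfusionMetrics",
    "GROWTH_CUTOFF",
    "propose_directionality",
    "curate_atp_driven",
    "evaluate_phenotypes",
    "accept_proposals",
    "recover_confusion",
]

logger = logging.getLogger(__name__)

GROWTH_CUTOFF = 1e-6  # h^-1; predicted growth iff optimum exceeds this


def direction_label(lb: float, ub: float) -> str:
    if lb < 0 < ub:
        return "reversible"
    if lb >= 0:
        return "forward"
    return "backward"


@dataclass
class ThermoRecord:
    reaction_id: str
    delta_g: float  # standard transformed Gibbs energy change, kJ/mol
    uncertainty: Optional[float] = None  # carried, not used in classification
    prior_label: str = "reversible"

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError(f"non-finite delta_g for {self.reaction_id}")


@dataclass
class DirectionalityProposal:
    reaction_id: str
    old_bounds: Tuple[float, float]
    new_bounds: Tuple[float, float]
    basis: str  # "thermo" | "atp_rule"

    def __post_init__(self) -> None:
        if self.new_bounds == self.old_bounds:
            raise ValueError(f"proposal for {self.reaction_id} changes nothing")
        if self.new_bounds[0] > self.new_bounds[1]:
            raise ValueError(f"proposal for {self.reaction_id} inverts bounds")


@dataclass
class PhenotypeTest:
    """One growth observation: a medium definition or a gene knockout.

    For ``kind == "growth_medium"``, ``spec`` maps exchange-reaction
    ids to lower (uptake) bounds; for ``kind == "knockout"`` it is a
    list of deleted gene ids.  ``observed`` is True for observed
    growth.
    """

    test_id: str
    kind: str
    spec: object
    observed: bool


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: Optional[float] = field(init=False)
    sensitivity: Optional[float] = field(init=False)
    specificity: Optional[float] = field(init=False)
    mcc: Optional[float] = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        n = tp + fp + tn + fn
        self.accuracy = (tp + tn) / n if n else None
        self.sensitivity = tp / (tp + fn) if tp + fn else None
        self.specificity = tn / (tn + fp) if tn + fp else None
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        self.mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def propose_directionality(
    model: MetabolicModel,
    thermo: Sequence[ThermoRecord],
    threshold: float = -30.0,
    default_bound: float = DEFAULT_BOUND,
) -> List[DirectionalityProposal]:
    """Propose bound changes from Gibbs-energy estimates.

    ΔG' ≤ threshold → forward-irreversible (lb = 0); ΔG' ≥ −threshold →
    backward-irreversible (ub = 0, lb opened to −default_bound);
    in between → reversible (bounds opened symmetrically).  A proposal
    is emitted only where bounds actually change.
    """
    proposals: List[DirectionalityProposal] = []
    for rec in thermo:
        if rec.reaction_id not in model.reactions:
            raise ModelError(f"thermo record for unknown reaction {rec.reaction_id!r}")
        rxn = model.reactions[rec.reaction_id]
        old = (rxn.lower_bound, rxn.upper_bound)
        if rec.delta_g <= threshold:
            new = (0.0, max(rxn.upper_bound, 0.0) or default_bound)
        elif rec.delta_g >= -threshold:
            new = (-default_bound, 0.0)
        else:
            new = (-default_bound, default_bound)
        if new != old:
            proposals.append(
                DirectionalityProposal(rec.reaction_id, old, new, basis="thermo")
            )
    return proposals


def curate_atp_driven(
    model: MetabolicModel,
    atp_metabolite_id: str,
    thermo: Sequence[ThermoRecord] = (),
    exceptions: Set[str] = frozenset(),
) -> List[DirectionalityProposal]:
    """Constrain reversible ATP-consuming reactions to forward.

    ATP-driven reactions are generally assumed irreversible, except
    those with a positive ΔG' estimate or explicitly excepted (e.g.
    nucleoside diphosphate kinase, ATP synthase analogs).
    """
    if atp_metabolite_id not in model.metabolites:
        raise ModelError(f"ATP metabolite {atp_metabolite_id!r} not in model")
    delta_g = {r.reaction_id: r.delta_g for r in thermo}
    proposals: List[DirectionalityProposal] = []
    for rxn in model.reactions.values():
        if rxn.id in exceptions or not rxn.reversible:
            continue
        if rxn.stoichiometry.get(atp_metabolite_id, 0.0) >= 0:
            continue  # not an ATP consumer in the forward direction
        dg = delta_g.get(rxn.id)
        if dg is not None and dg > 0:
            continue
        proposals.append(
            DirectionalityProposal(
                rxn.id,
                (rxn.lower_bound, rxn.upper_bound),
                (0.0, rxn.upper_bound),
                basis="atp_rule",
            )
        )
    return proposals


def _simulate_test(model: MetabolicModel, test: PhenotypeTest, cutoff: float) -> bool:
    if test.kind == "growth_medium":
        work = model.copy()
        for ex_id, lb in dict(test.spec).items():
            if ex_id not in work.reactions:
                raise ModelError(f"test {test.test_id}: unknown exchange {ex_id!r}")
            work.reactions[ex_id].lower_bound = lb
    elif test.kind == "knockout":
        missing = [g for g in test.spec if g not in model.genes]
        if missing:
            raise ModelError(f"test {test.test_id}: unknown gene(s) {missing}")
        work = model.knock_out_genes(test.spec)
    else:
        raise ModelError(f"test {test.test_id}: unknown kind {test.kind!r}")
    sol = fba(work)
    if sol.status == "infeasible":
        logger.info("test %s: infeasible model counted as no-growth", test.test_id)
        return False
    return sol.objective_value > cutoff


def evaluate_phenotypes(
    model: MetabolicModel,
    tests: Sequence[PhenotypeTest],
    growth_cutoff: float = GROWTH_CUTOFF,
) -> ConfusionMetrics:
    """FBA-simulate every phenotype test and summarize the confusion.

    Growth is the positive class.  An infeasible test model counts as
    predicted no-growth.  Metrics with an undefined denominator are
    reported as None, never silently zero.
    """
    if not tests:
        raise ModelError("phenotype test list is empty")
    tp = fp = tn = fn = 0
    for test in tests:
        predicted = _simulate_test(model, test, growth_cutoff)
        if predicted and test.observed:
            tp += 1
        elif predicted and not test.observed:
            fp += 1
        elif not predicted and not test.observed:
            tn += 1
        else:
            fn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def _apply(model: MetabolicModel, proposal: DirectionalityProposal) -> None:
    rxn = model.reactions[proposal.reaction_id]
    rxn.lower_bound, rxn.upper_bound = proposal.new_bounds


def _revert(model: MetabolicModel, proposal: DirectionalityProposal) -> None:
    rxn = model.reactions[proposal.reaction_id]
    rxn.lower_bound, rxn.upper_bound = proposal.old_bounds


def accept_proposals(
    model: MetabolicModel,
    proposals: Sequence[DirectionalityProposal],
    tests: Sequence[PhenotypeTest],
    growth_cutoff: float = GROWTH_CUTOFF,
) -> Tuple[MetabolicModel, List[DirectionalityProposal], List[DirectionalityProposal]]:
    """Apply proposals, then discard those that hurt phenotype accuracy.

    All proposals are applied at once; then, in ascending reaction-id
    order, each is singly reverted and the reversion kept iff it
    strictly increases the MCC (recomputed after every kept reversion).
    Returns (curated model, accepted, discarded).
    """
    seen: Set[str] = set()
    for p in proposals:
        if p.reaction_id in seen:
            raise ModelError(f"conflicting proposals for reaction {p.reaction_id!r}")
        if p.reaction_id not in model.reactions:
            raise ModelError(f"proposal for unknown reaction {p.reaction_id!r}")
        seen.add(p.reaction_id)

    work = model.copy()
    if not proposals:
        return work, [], []
    for p in proposals:
        _apply(work, p)

    def score() -> Tuple[float, float]:
        # MCC is the criterion; accuracy breaks ties when MCC is
        # undefined (a predicted or observed class is empty)
        m = evaluate_phenotypes(work, tests, growth_cutoff)
        return (-math.inf if m.mcc is None else m.mcc, m.accuracy or 0.0)

    current = score()
    accepted: List[DirectionalityProposal] = []
    discarded: List[DirectionalityProposal] = []
    for p in sorted(proposals, key=lambda q: q.reaction_id):
        _revert(work, p)
        reverted = score()
        if reverted > current:
            discarded.append(p)
            current = reverted
        else:
            _apply(work, p)
            accepted.append(p)
    return work, accepted, discarded


def recover_confusion(
    n: int,
    accuracy: Optional[float] = None,
    sensitivity: Optional[float] = None,
    specificity: Optional[float] = None,
    decimals: int = 2,
) -> List[ConfusionMetrics]:
    """Brute-force integer confusion matrices matching rounded metrics.

    Enumerates all (tp, fn, tn, fp) with tp+fn+tn+fp = n whose
    accuracy / sensitivity / specificity round to the given values at
    ``decimals`` places (a None metric is unconstrained).  Returns all
    matches (possibly empty); callers check uniqueness.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    half = 0.5 * 10.0 ** (-decimals)

    def matches(value: Optional[float], target: Optional[float]) -> bool:
        # A printed value stands for the half-open rounding interval
        # around it; ties (e.g. 0.475 -> 0.48 at 2 d.p.) are included,
        # so the comparison is |value - target| <= half ulp.
        if target is None:
            return True
        if value is None:
            return False
        return abs(value - target) <= half + 1e-12

    def candidates(total: int, target: Optional[float]) -> range:
        """Integer counts k in [0, total] with k/total rounding to target."""
        if target is None or total == 0:
            return range(total + 1)
        lo = max(0, math.ceil((target - half) * total - 1e-12))
        hi = min(total, math.floor((target + half) * total + 1e-12))
        return range(lo, hi + 1)

    out: List[ConfusionMetrics] = []
    for pos in range(n + 1):  # observed positives = tp + fn
        neg = n - pos
        for tp in candidates(pos, sensitivity):
            sens = tp / pos if pos else None
            if not matches(sens, sensitivity):
                continue
            for tn in candidates(neg, specificity):
                spec = tn / neg if neg else None
                if not matches(spec, specificity):
                    continue
                if not matches((tp + tn) / n, accuracy):
                    continue
                out.append(ConfusionMetrics(tp=tp, fp=neg - tn, tn=tn, fn=pos - tp))
    return out
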