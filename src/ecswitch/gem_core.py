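"""Constraint-based model core: data structures, FBA and FVA.

Flux units are mmol·gDW⁻¹·h⁻¹ throughout; the biomass reaction carries
flux in h⁻¹.  The "infinite" default bound is ±1000 mmol·gDW⁻¹·h⁻¹
(the common GEM convention) and is configurable per reaction.
Exchange reactions are identified structurally — a reaction touching a
single metabolite — never by an id prefix.

Linear programs are solved with the HiGHS dual simplex through
:func:`scipy.optimize.linprog`, so every reported optimum is a basic
(vertex) solution.  Feasibility tolerance is fixed at 1e-9.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from . import gpr

__all__ = [
    "DEFAULT_BOUND",
    "FEASIBILITY_TOL",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "FvaResult",
    "ModelError",
    "ModelParseError",
    "fba",
    "fva",
    "optimize",
    "update_biomass_prosthetics",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0
FEASIBILITY_TOL = 1e-9

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


class ModelError(ValueError):
    """Structural problem with a model or an operation on it."""


class ModelParseError(ModelError):
    """A serialized model could not be interpreted."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""
    charge: Optional[int] = None


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds and a gene rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``gene_rule`` is a boolean expression over
    gene ids (AND = complex, OR = isozymes) or the empty string.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    subsystem: str = ""
    pathway: str = ""
    annotations: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> Set[str]:
        return gpr.rule_genes(self.gene_rule)

    def copy(self) -> "Reaction":
        return _copy.deepcopy(self)


class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model.

    Metabolites and reactions are held in insertion-ordered dicts keyed
    by id; ids must be unique.  ``objective`` names the reaction whose
    flux FBA maximizes by default (typically biomass).
    """

    def __init__(self, model_id: str = "model") -> None:
        self.id = model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.compartments: Set[str] = set()
        self.objective: Optional[str] = None

    @property
    def genes(self) -> Set[str]:
        """All gene ids referenced by any reaction's gene rule."""
        out: Set[str] = set()
        for rxn in self.reactions.values():
            out.update(rxn.genes)
        return out

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.add(met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelParseError(
                f"reaction {rxn.id!r} references undeclared metabolite(s): "
                + ", ".join(sorted(missing))
            )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> None:
        self.reactions.pop(rxn_id)
        if self.objective == rxn_id:
            self.objective = None

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- views ---------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def exchanges(self) -> List[str]:
        """Ids of boundary reactions (single-metabolite stoichiometry)."""
        return [r.id for r in self.reactions.values() if len(r.stoichiometry) == 1]

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S (metabolites × reactions) plus row/column id orders."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coef
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelError(f"objective {self.objective!r} is not a model reaction")
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id}: inverted bounds")

    # -- gene knockouts ------------------------------------------------
    def knock_out_genes(self, genes: Iterable[str]) -> "MetabolicModel":
        """Copy of the model with reactions disabled whose gene rule
        evaluates False once the given genes are deleted."""
        knocked = set(genes)
        out = self.copy()
        for rxn in out.reactions.values():
            if rxn.gene_rule and not gpr.evaluate_rule(rxn.gene_rule, knocked):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
        return out


@dataclass
class FluxDistribution:
    """One steady-state flux vector and the objective it achieved.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
    values are empty unless optimal.
    """

    values: Dict[str, float]
    objective_value: float
    status: str = "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]


@dataclass
class FvaResult:
    ranges: Dict[str, Tuple[float, float]]
    fraction_of_optimum: float

    def width(self, rxn_id: str) -> float:
        lo, hi = self.ranges[rxn_id]
        return hi - lo


# -- linear programming ----------------------------------------------


class LinearProblem:
    """Reusable LP skeleton (S·v = 0 plus bounds) for one model."""

    def __init__(self, model: MetabolicModel) -> None:
        self.S, self.met_ids, self.rxn_ids = model.stoichiometric_matrix()
        self.index = {r: j for j, r in enumerate(self.rxn_ids)}
        self.lb = np.array([model.reactions[r].lower_bound for r in self.rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in self.rxn_ids])

    def solve(
        self, coefficients: Mapping[str, float], sense: str = "max"
    ) -> Tuple[str, Optional[np.ndarray], float]:
        """Optimize ``sum(c_r * v_r)``; returns (status, x, objective)."""
        c = np.zeros(len(self.rxn_ids))
        for rid, coef in coefficients.items():
            c[self.index[rid]] = coef
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs-ds",
            options=_LP_OPTIONS,
        )
        if res.status == 2:
            return "infeasible", None, math.nan
        if res.status == 3:
            return "unbounded", None, math.inf if sense == "max" else -math.inf
        if not res.success:  # pragma: no cover - solver hiccup
            raise RuntimeError(f"LP solver failure: {res.message}")
        return "optimal", res.x, float(sign * res.fun)


def optimize(
    model: MetabolicModel,
    coefficients: Mapping[str, float],
    sense: str = "max",
    problem: Optional[LinearProblem] = None,
) -> FluxDistribution:
    """Optimize an arbitrary linear objective over the flux polytope."""
    lp = problem if problem is not None else LinearProblem(model)
    status, x, obj = lp.solve(coefficients, sense)
    if status != "optimal":
        return FluxDistribution({}, obj, status=status)
    return FluxDistribution(dict(zip(lp.rxn_ids, x)), obj, status="optimal")


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimize one reaction's flux.

    Solves max/min v_obj subject to S·v = 0 and bounds and returns an
    optimal vertex.  Alternative optima are not resolved — any optimal
    vertex is a valid return; assert objective values, not individual
    fluxes of degenerate reactions.
    """
    obj = objective if objective is not None else model.objective
    if obj is None or obj not in model.reactions:
        raise ModelError(f"objective reaction {obj!r} not in model")
    return optimize(model, {obj: 1.0}, sense=sense)


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    fraction_of_optimum: float = 0.0,
    objective: Optional[str] = None,
) -> FvaResult:
    """Flux variability analysis.

    Per reaction, minimizes and maximizes its flux, optionally under
    the optimality constraint v_obj ≥ fraction·optimum.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ModelError("fraction_of_optimum must lie in [0, 1]")
    work = model
    if fraction_of_optimum > 0.0:
        sol = fba(model, objective=objective)
        if sol.status != "optimal":
            raise ModelError(f"base FBA problem is {sol.status}")
        work = model.copy()
        obj = objective if objective is not None else model.objective
        rxn = work.reactions[obj]
        rxn.lower_bound = max(rxn.lower_bound, fraction_of_optimum * sol.objective_value)
    lp = LinearProblem(work)
    targets = list(reactions) if reactions is not None else list(work.reactions)
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        if rid not in work.reactions:
            raise ModelError(f"unknown reaction {rid!r} in FVA request")
        lo_status, _, lo = lp.solve({rid: 1.0}, sense="min")
        hi_status, _, hi = lp.solve({rid: 1.0}, sense="max")
        if lo_status == "infeasible" or hi_status == "infeasible":
            raise ModelError("infeasible FVA subproblem")
        ranges[rid] = (lo, hi)
    return FvaResult(ranges, fraction_of_optimum)


# -- biomass prosthetic-group curation --------------------------------


def _molar_mass(met: Metabolite) -> float:
    """Molar mass in g/mmol from the formula; 1.0 when unset."""
    if not met.formula:
        return 1.0
    from cobra import Metabolite as _CobraMet

    weight = _CobraMet("tmp", formula=met.formula).formula_weight
    return float(weight) / 1000.0 if weight else 1.0


def update_biomass_prosthetics(
    model: MetabolicModel,
    proteome,
    prosthetic_map: Mapping[str, Tuple[str, float]],
    mass_fraction: float = 0.03,
    biomass_reaction: Optional[str] = None,
) -> MetabolicModel:
    """Set biomass prosthetic-group coefficients from protein abundances.

    Each annotated protein contributes ``abundance × stoichiometry`` of
    its prosthetic-group metabolite.  Group coefficients are set
    proportional to these weighted sums and scaled so that the groups'
    total mass contribution per unit biomass flux equals
    ``mass_fraction`` (g/gDW); all other consumed biomass coefficients
    are rescaled by ``1 − mass_fraction`` to keep 1 g biomass per unit
    flux.  Doubling every abundance leaves the result unchanged.

    ``proteome`` is anything with an ``abundances`` mapping (protein id
    → mmol·gDW⁻¹) or such a mapping itself.
    """
    abundances: Mapping[str, float] = getattr(proteome, "abundances", proteome)
    out = model.copy()
    if not prosthetic_map:
        return out
    bid = biomass_reaction if biomass_reaction is not None else out.objective
    if bid is None or bid not in out.reactions:
        raise ModelError("biomass reaction not identified for prosthetic update")
    biomass = out.reactions[bid]

    weighted: Dict[str, float] = {}
    for protein, (group_met, stoich) in prosthetic_map.items():
        if group_met not in out.metabolites:
            raise ModelError(f"prosthetic group metabolite {group_met!r} not in model")
        weighted[group_met] = weighted.get(group_met, 0.0) + abundances.get(protein, 0.0) * stoich

    total_mass = sum(w * _molar_mass(out.metabolites[g]) for g, w in weighted.items())
    if total_mass <= 0:
        logger.warning("prosthetic update: zero total weighted abundance; model unchanged")
        return out

    for mid, coef in list(biomass.stoichiometry.items()):
        if coef < 0 and mid not in weighted:
            biomass.stoichiometry[mid] = coef * (1.0 - mass_fraction)
    for group_met, w in weighted.items():
        coef = mass_fraction * w / total_mass
        biomass.stoichiometry[group_met] = -coef
    return out
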