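"""Model serialization: SBML Level 3 (fbc) and a flat tabular dialect.

SBML goes through cobrapy/libsbml.  The tabular dialect is a directory
holding ``metabolites.tsv`` (id, name, compartment, formula, charge)
and ``reactions.tsv`` (id, equation, lb, ub, gene_rule, subsystem,
pathway), with equations written as ``"2 A + B --> C"`` or ``"<=>"``
for reversible reactions.  Round-tripping either dialect is the
identity on ids, stoichiometry, bounds, gene rules and subsystems.
"""

from __future__ import annotations

import math
import os
from typing import Dict, Optional, Tuple

import pandas as pd

from .gem_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelParseError,
    Reaction,
)

__all__ = ["read_model", "write_model", "model_io", "to_cobra", "from_cobra"]

_ARROWS = ("<=>", "-->", "<--")


def _format_side(terms: Dict[str, float]) -> str:
    parts = []
    for mid, coef in terms.items():
        if abs(coef - 1.0) < 1e-12:
            parts.append(mid)
        else:
            parts.append(f"{coef:g} {mid}")
    return " + ".join(parts)


def format_equation(rxn: Reaction) -> str:
    lhs = {m: -c for m, c in rxn.stoichiometry.items() if c < 0}
    rhs = {m: c for m, c in rxn.stoichiometry.items() if c > 0}
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{_format_side(lhs)} {arrow} {_format_side(rhs)}".strip()


def parse_equation(equation: str, rxn_id: str = "?") -> Tuple[Dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelParseError(f"reaction {rxn_id!r}: no arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    if arrow == "<--":
        left, right = right, left
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            tokens = term.split()
            if not tokens:
                raise ModelParseError(f"reaction {rxn_id!r}: empty term in {equation!r}")
            if len(tokens) == 2:
                coef, mid = float(tokens[0]), tokens[1]
            elif len(tokens) == 1:
                coef, mid = 1.0, tokens[0]
            else:
                raise ModelParseError(
                    f"reaction {rxn_id!r}: cannot parse term {term.strip()!r}"
                )
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return stoich, arrow == "<=>"


# -- tabular dialect ---------------------------------------------------


def _write_tabular(model: MetabolicModel, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": "" if m.charge is None else m.charge,
            }
            for m in model.metabolites.values()
        ]
    )
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "equation": format_equation(r),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
                "pathway": r.pathway,
                "objective": 1 if r.id == model.objective else 0,
            }
            for r in model.reactions.values()
        ]
    )
    mets.to_csv(os.path.join(path, "metabolites.tsv"), sep="\t", index=False)
    rxns.to_csv(os.path.join(path, "reactions.tsv"), sep="\t", index=False)


def _read_tabular(path: str, model_id: str) -> MetabolicModel:
    met_path = os.path.join(path, "metabolites.tsv")
    rxn_path = os.path.join(path, "reactions.tsv")
    for p in (met_path, rxn_path):
        if not os.path.exists(p):
            raise ModelParseError(f"tabular model file missing: {p}")
    model = MetabolicModel(model_id)
    mets = pd.read_csv(met_path, sep="\t", dtype=str, keep_default_na=False)
    for row in mets.itertuples(index=False):
        charge = None if row.charge == "" else int(float(row.charge))
        model.add_metabolite(
            Metabolite(row.id, row.name, row.compartment, row.formula, charge)
        )
    rxns = pd.read_csv(rxn_path, sep="\t", dtype=str, keep_default_na=False)
    for row in rxns.itertuples(index=False):
        stoich, reversible = parse_equation(row.equation, row.id)
        lb, ub = float(row.lb), float(row.ub)
        model.add_reaction(
            Reaction(
                row.id,
                stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=row.gene_rule,
                subsystem=row.subsystem,
                pathway=row.pathway,
            )
        )
        if getattr(row, "objective", "0") in ("1", "1.0", "True", "true"):
            model.objective = row.id
    return model


# -- SBML via cobrapy --------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML and as a test oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(
                m.id,
                name=m.name,
                compartment=m.compartment,
                formula=m.formula or None,
                charge=m.charge,
            )
            for m in model.metabolites.values()
        ]
    )
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        cr.notes["SUBSYSTEM"] = r.subsystem
        if r.pathway:
            cr.notes["PATHWAY"] = r.pathway
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()})
        cr.gene_reaction_rule = r.gene_rule
    if model.objective is not None:
        cm.objective = model.objective
    return cm


def from_cobra(cm) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    model = MetabolicModel(cm.id or "model")
    for m in cm.metabolites:
        model.add_metabolite(
            Metabolite(
                m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                formula=m.formula or "",
                charge=m.charge if m.charge is not None else None,
            )
        )
    for r in cm.reactions:
        subsystem = r.subsystem or str(r.notes.get("SUBSYSTEM", ""))
        pathway = str(r.notes.get("PATHWAY", ""))
        model.add_reaction(
            Reaction(
                r.id,
                {m.id: c for m, c in r.metabolites.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gene_rule=r.gene_reaction_rule or "",
                subsystem=subsystem,
                pathway=pathway,
            )
        )
    coeffs = linear_reaction_coefficients(cm)
    if coeffs:
        model.objective = next(iter(coeffs)).id
    return model


def _infer_dialect(path: str) -> str:
    if path.endswith((".xml", ".sbml")):
        return "sbml"
    if os.path.isdir(path) or not os.path.splitext(path)[1]:
        return "tabular"
    raise ModelParseError(f"cannot infer model dialect for {path!r}")


def read_model(path: str, dialect: Optional[str] = None, model_id: str = "model") -> MetabolicModel:
    dialect = dialect or _infer_dialect(path)
    if dialect == "tabular":
        return _read_tabular(path, model_id)
    if dialect == "sbml":
        from cobra.io import read_sbml_model

        return from_cobra(read_sbml_model(path))
    raise ModelParseError(f"unknown model dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str, dialect: Optional[str] = None) -> str:
    dialect = dialect or _infer_dialect(path)
    if dialect == "tabular":
        _write_tabular(model, path)
    elif dialect == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(to_cobra(model), path)
    else:
        raise ModelParseError(f"unknown model dialect {dialect!r}")
    return path


def model_io(path: str, direction: str, dialect: Optional[str] = None, model: Optional[MetabolicModel] = None):
    """Single entry point mirroring the read/write pair."""
    if direction == "read":
        return read_model(path, dialect)
    if direction == "write":
        if model is None:
            raise ValueError("model required for direction='write'")
        return write_model(model, path, dialect)
    raise ValueError(f"direction must be 'read' or 'write', got {direction!r}")
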