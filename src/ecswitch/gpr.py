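"""Boolean gene–protein–reaction (GPR) rules.

A rule is a boolean expression over gene identifiers, e.g.
``"gA and (gB or gC)"``.  ``and`` groups denote enzyme complexes (all
subunits required), ``or`` groups denote isozymes (either suffices).
The empty rule means "no gene association" and always evaluates True.
"""

from __future__ import annotations

import re
from typing import FrozenSet, List, Set, Tuple

__all__ = ["parse_rule", "rule_genes", "evaluate_rule", "isozyme_complexes"]

_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)

# AST nodes: ("gene", id) | ("and", [nodes]) | ("or", [nodes])
Node = Tuple


def _tokenize(rule: str) -> List[str]:
    return _TOKEN.findall(rule)


def parse_rule(rule: str) -> Node | None:
    """Parse a GPR string into an AST; ``None`` for the empty rule."""
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def parse_or() -> Node:
        nonlocal pos
        terms = [parse_and()]
        while pos < len(tokens) and tokens[pos].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and() -> Node:
        nonlocal pos
        terms = [parse_atom()]
        while pos < len(tokens) and tokens[pos].lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom() -> Node:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"truncated gene rule: {rule!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            node = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in gene rule: {rule!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed gene rule: {rule!r}")
        pos += 1
        return ("gene", tok)

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in gene rule: {rule!r}")
    return node


def rule_genes(rule: str) -> Set[str]:
    """All gene ids referenced by a rule."""
    node = parse_rule(rule)
    out: Set[str] = set()

    def walk(n):
        if n is None:
            return
        if n[0] == "gene":
            out.add(n[1])
        else:
            for c in n[1]:
                walk(c)

    walk(node)
    return out


def evaluate_rule(rule: str, knocked_out: Set[str] = frozenset()) -> bool:
    """Evaluate a rule with the given genes deleted.

    A gene evaluates True iff it is not knocked out; the empty rule is
    True (spontaneous / non-enzymatic reaction survives any knockout).
    """
    node = parse_rule(rule)

    def ev(n) -> bool:
        if n is None:
            return True
        kind = n[0]
        if kind == "gene":
            return n[1] not in knocked_out
        if kind == "and":
            return all(ev(c) for c in n[1])
        return any(ev(c) for c in n[1])

    return ev(node)


def isozyme_complexes(rule: str) -> List[FrozenSet[str]]:
    """Expand a rule to disjunctive normal form.

    Returns one frozenset of gene ids per isozyme (OR-branch); each set
    is an AND-complex whose members are all required.  Empty rule gives
    an empty list.  Redundant supersets are pruned and the result is
    sorted for determinism.
    """
    node = parse_rule(rule)
    if node is None:
        return []

    def dnf(n) -> List[FrozenSet[str]]:
        if n[0] == "gene":
            return [frozenset([n[1]])]
        if n[0] == "or":
            out: List[FrozenSet[str]] = []
            for c in n[1]:
                out.extend(dnf(c))
            return out
        # and: cartesian product of children's branches
        acc: List[FrozenSet[str]] = [frozenset()]
        for c in n[1]:
            acc = [a | b for a in acc for b in dnf(c)]
        return acc

    branches = set(dnf(node))
    minimal = [b for b in branches if not any(o < b for o in branches)]
    return sorted(minimal, key=lambda s: sorted(s))
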