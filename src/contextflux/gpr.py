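"""Gene-protein-reaction (GPR) boolean rules.

A GPR is a boolean expression over gene ids with ``and``/``or`` (case
insensitive) and parentheses.  For expression integration the rule is
evaluated over ordered categories LOW < MODERATE < HIGH: an AND node (enzyme
complex — the least expressed subunit limits) takes the minimum of its
children, an OR node (isoenzymes — the most expressed suffices) the maximum.
Genes missing from the profile and empty rules evaluate to MODERATE.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

LOW, MODERATE, HIGH = "LOW", "MODERATE", "HIGH"
CATEGORY_ORDER = {LOW: 0, MODERATE: 1, HIGH: 2}
CATEGORIES = (LOW, MODERATE, HIGH)


class GPRParseError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class _Node:
    op: str  # "gene" | "and" | "or"
    gene: str | None = None
    children: tuple = ()


def parse_gpr(rule: str) -> _Node | None:
    """Parse a GPR rule into an expression tree; None for an empty rule."""
    tokens = _TOKEN_RE.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> _Node:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return _Node("or", children=tuple(children))

    def parse_and() -> _Node:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return _Node("and", children=tuple(children))

    def parse_atom() -> _Node:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"rule {rule!r}: unexpected end of expression")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"rule {rule!r}: unbalanced parenthesis")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"rule {rule!r}: unexpected token {tok!r}")
        return _Node("gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"rule {rule!r}: trailing tokens {tokens[pos:]!r}")
    return node


def gpr_genes(rule: str) -> set[str]:
    """All gene ids referenced by a rule."""
    node = parse_gpr(rule)
    out: set[str] = set()

    def walk(n: _Node) -> None:
        if n.op == "gene":
            out.add(n.gene)
        else:
            for c in n.children:
                walk(c)

    if node is not None:
        walk(node)
    return out


def evaluate_gpr(rule: str, categories: dict[str, str]) -> str:
    """Evaluate a rule to LOW/MODERATE/HIGH given per-gene categories."""
    node = parse_gpr(rule)
    if node is None:
        return MODERATE

    def walk(n: _Node) -> int:
        if n.op == "gene":
            return CATEGORY_ORDER[categories.get(n.gene, MODERATE)]
        values = [walk(c) for c in n.children]
        return min(values) if n.op == "and" else max(values)

    return CATEGORIES[walk(node)]
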