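"""Gene-protein-reaction (GPR) rules as boolean trees.

A GPR links genes to a reaction's catalysis: ``AND`` nodes represent
enzyme complexes (all subunits required), ``OR`` nodes isozymes (any one
suffices).  The tree is consumed both for boolean evaluation (gene
knockouts) and, in :mod:`kcatevo.moment`, for building the recursive
enzyme-capacity expression of the proteome-constrained growth problem.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["GprExpression", "parse_gpr", "GprParseError"]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GprExpression:
    """Node of a GPR boolean tree.

    ``kind`` is one of ``"GENE"``, ``"AND"``, ``"OR"``.  GENE leaves carry
    the gene id in ``gene``; AND/OR nodes carry >= 2 ``children``.
    """

    kind: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "GENE":
            if not self.gene:
                raise GprParseError("GENE node requires a gene id")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise GprParseError(f"{self.kind} node requires >=2 children")
        else:
            raise GprParseError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> set[str]:
        """All gene ids appearing in the subtree."""
        return set(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        if self.kind == "GENE":
            yield self.gene  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child._iter_genes()

    def evaluate(self, active: dict[str, bool]) -> bool:
        """Evaluate the rule under a gene on/off assignment."""
        if self.kind == "GENE":
            return bool(active.get(self.gene, False))
        if self.kind == "AND":
            return all(c.evaluate(active) for c in self.children)
        return any(c.evaluate(active) for c in self.children)

    def to_string(self) -> str:
        if self.kind == "GENE":
            return self.gene  # type: ignore[return-value]
        op = " and " if self.kind == "AND" else " or "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.kind != "GENE":
                s = f"({s})"
            parts.append(s)
        return op.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


def parse_gpr(rule: str) -> GprExpression | None:
    """Parse a GPR string like ``"g1 and (g2 or g3)"`` into a tree.

    ``and``/``or`` (case-insensitive; ``&&``/``||`` accepted) associate with
    the usual precedence (``and`` binds tighter than ``or``).  Returns
    ``None`` for an empty rule (non-enzymatic reaction).
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: str | None, name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and tok == "&&") or (
            name == "or" and tok == "||"
        )

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR rule {rule!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR rule {rule!r}")
        take()
        return GprExpression("GENE", gene=tok)

    def parse_and() -> GprExpression:
        nodes = [parse_atom()]
        while is_op(peek(), "and"):
            take()
            nodes.append(parse_atom())
        if len(nodes) == 1:
            return nodes[0]
        return GprExpression("AND", children=_flatten("AND", nodes))

    def parse_or() -> GprExpression:
        nodes = [parse_and()]
        while is_op(peek(), "or"):
            take()
            nodes.append(parse_and())
        if len(nodes) == 1:
            return nodes[0]
        return GprExpression("OR", children=_flatten("OR", nodes))

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule {rule!r}")
    return node


def _flatten(kind: str, nodes: list[GprExpression]) -> tuple[GprExpression, ...]:
    # associativity: "a and b and c" becomes one AND node with 3 children
    out: list[GprExpression] = []
    for n in nodes:
        if n.kind == kind:
            out.extend(n.children)
        else:
            out.append(n)
    return tuple(out)
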