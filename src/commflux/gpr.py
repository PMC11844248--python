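"""Gene-product rules: boolean AND/OR trees over gene identifiers.

Semantics used throughout the package: AND nodes evaluate to the minimum of
their children (an enzyme complex is limited by its scarcest subunit), OR
nodes to the sum (isozymes contribute additively).  This is a declared
convention; the textual dialect is the conventional ``(g1 and g2) or g3``.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import FormatError, ValidationError

__all__ = ["GprNode", "GeneRef", "BoolOp", "GeneProductRule", "parse_gpr"]


@dataclass(frozen=True)
class GeneRef:
    gene: str

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple  # of GeneRef | BoolOp

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValidationError(f"unknown boolean operator {self.op!r}")
        if len(self.children) < 1:
            raise ValidationError("empty boolean subtree in gene-product rule")

    def to_string(self) -> str:
        parts = []
        for child in self.children:
            s = child.to_string()
            if isinstance(child, BoolOp) and child.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


GprNode = GeneRef | BoolOp


@dataclass(frozen=True)
class GeneProductRule:
    """A parsed gene-product rule.

    Attributes
    ----------
    root:
        Tree of :class:`GeneRef` / :class:`BoolOp` nodes.
    """

    root: GprNode

    @classmethod
    def from_string(cls, text: str) -> "GeneProductRule":
        return parse_gpr(text)

    def to_string(self) -> str:
        return self.root.to_string()

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(_iter_genes(self.root))

    def evaluate(
        self,
        gene_scores: Mapping[str, float],
        missing_policy: str = "median",
    ) -> float:
        """Evaluate the rule on non-negative per-gene scores.

        AND -> min of children, OR -> sum of children.  Genes absent from
        ``gene_scores`` are filled according to ``missing_policy``:

        - ``"median"`` (default): the median of the provided scores;
        - ``"zero"``: 0.0;
        - ``"error"``: raise :class:`ValidationError`.
        """
        for g, v in gene_scores.items():
            if v < 0:
                raise ValidationError(f"negative score for gene {g!r}")
        fill: float | None = None
        if missing_policy == "median":
            if gene_scores:
                fill = float(statistics.median(gene_scores.values()))
        elif missing_policy == "zero":
            fill = 0.0
        elif missing_policy != "error":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

        def rec(node: GprNode) -> float:
            if isinstance(node, GeneRef):
                if node.gene in gene_scores:
                    return float(gene_scores[node.gene])
                if fill is None:
                    raise ValidationError(
                        f"no score for gene {node.gene!r} and no fallback available"
                    )
                return fill
            vals = [rec(c) for c in node.children]
            return min(vals) if node.op == "and" else sum(vals)

        return rec(self.root)


def _iter_genes(node: GprNode) -> Iterator[str]:
    if isinstance(node, GeneRef):
        yield node.gene
    else:
        for c in node.children:
            yield from _iter_genes(c)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GeneProductRule:
    """Parse the textual dialect ``(g1 and g2) or g3`` into a rule tree."""
    if text is None or not text.strip():
        raise FormatError("empty gene-product rule")
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def combine(op: str, parts: list) -> GprNode:
        if len(parts) == 1:
            return parts[0]
        # Flatten same-operator nesting so equivalent trees compare equal.
        flat: list = []
        for p in parts:
            if isinstance(p, BoolOp) and p.op == op:
                flat.extend(p.children)
            else:
                flat.append(p)
        return BoolOp(op, tuple(flat))

    def parse_or() -> GprNode:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            parts.append(parse_and())
        return combine("or", parts)

    def parse_and() -> GprNode:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            parts.append(parse_atom())
        return combine("and", parts)

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise FormatError(f"truncated gene-product rule: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise FormatError(f"unbalanced parenthesis in rule: {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"unexpected token {tok!r} in rule: {text!r}")
        return GeneRef(advance())

    node = parse_or()
    if pos != len(tokens):
        raise FormatError(f"trailing tokens in rule: {text!r}")
    return GeneProductRule(root=node)
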