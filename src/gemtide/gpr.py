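"""Gene-protein-reaction (GPR) rule parsing and numeric propagation.

A GPR rule is a boolean expression over gene identifiers in which AND
encodes the subunits of an enzyme complex and OR encodes isozymes.  This
module parses the standard ``"gA and (gB or gC)"`` notation into an
explicit tree and propagates two kinds of per-gene numbers to a single
per-reaction value:

* signed differential-expression weights (log2 fold changes), where a
  complex inherits the evidence of its weakest subunit (minimum absolute
  magnitude under AND) and an isozyme set inherits its strongest signal
  (maximum absolute magnitude under OR);
* nonnegative transcript abundances (TPM), where a complex is limited by
  its scarcest subunit (AND = min) and isozymes are additive (OR = sum).

The signed-weight convention is exposed as a strategy so alternative
conventions (e.g. plain means) can be configured.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GPRExpression",
    "GPRParseError",
    "parse_gpr",
    "reaction_weight",
    "reaction_weight_matrix",
    "reaction_abundance",
]


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRExpression:
    """Node of a GPR boolean tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry a
    gene identifier; internal nodes carry >= 2 children.  Nested chains
    of the same operator are flattened on construction, so rendering and
    re-parsing is the identity up to whitespace and associativity.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a gene identifier")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node requires >= 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def leaves(self) -> Iterator[str]:
        """Yield gene identifiers left-to-right (with repeats)."""
        if self.kind == "gene":
            yield self.gene
        else:
            for child in self.children:
                yield from child.leaves()

    def genes(self) -> frozenset[str]:
        return frozenset(self.leaves())

    def render(self) -> str:
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for child in self.children:
            text = child.render()
            # parenthesize an OR child under AND (AND binds tighter)
            if self.kind == "and" and child.kind == "or":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


class _Parser:
    # recursive descent; OR is the top-level (loosest) operator
    def __init__(self, tokens: list[tuple[str, int]], length: int):
        self.tokens = tokens
        self.pos = 0
        self.length = length

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int] | None:
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GPRExpression:
        expr = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[0]!r}", tok[1])
        return expr

    def or_expr(self) -> GPRExpression:
        children = [self.and_expr()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "or":
                break
            self.next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else _flatten("or", children)

    def and_expr(self) -> GPRExpression:
        children = [self.factor()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "and":
                break
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else _flatten("and", children)

    def factor(self) -> GPRExpression:
        tok = self.next()
        if tok is None:
            raise GPRParseError("dangling operator or empty group", self.length)
        text, pos = tok
        if text == "(":
            inner = self.or_expr()
            closing = self.next()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            return inner
        if text == ")":
            raise GPRParseError("unbalanced parenthesis", pos)
        if text.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator {text!r}", pos)
        return GPRExpression("gene", gene=text)


def _flatten(kind: str, children: Sequence[GPRExpression]) -> GPRExpression:
    flat: list[GPRExpression] = []
    for child in children:
        if child.kind == kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GPRExpression(kind, children=tuple(flat))


def parse_gpr(text: str | None) -> GPRExpression | None:
    """Parse a GPR string; empty/None input marks an absent GPR (None).

    AND binds tighter than OR; operators are case-insensitive; gene
    tokens are any whitespace/parenthesis-free strings.
    """
    if text is None or not text.strip():
        return None
    return _Parser(_tokenize(text), len(text)).parse()


def _combine(kind: str, acc: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Fold step of the signed magnitude rule with documented tie-break.

    Among children, AND keeps the value of minimum |.| and OR the value
    of maximum |.|; on an exact magnitude tie the positive value wins,
    then the leftmost child.
    """
    a_abs, b_abs = np.abs(acc), np.abs(nxt)
    if kind == "and":
        take_next = (b_abs < a_abs) | ((b_abs == a_abs) & (nxt > acc))
    else:
        take_next = (b_abs > a_abs) | ((b_abs == a_abs) & (nxt > acc))
    return np.where(take_next, nxt, acc)


def _eval_weight(
    expr: GPRExpression,
    weight_matrix: np.ndarray,
    gene_index: Mapping[str, int],
    missing: set[str] | None,
    strategy: str,
) -> np.ndarray:
    if expr.kind == "gene":
        idx = gene_index.get(expr.gene)
        if idx is None:
            if missing is not None:
                missing.add(expr.gene)
            return np.zeros(weight_matrix.shape[0])
        return weight_matrix[:, idx]
    values = [
        _eval_weight(c, weight_matrix, gene_index, missing, strategy)
        for c in expr.children
    ]
    if strategy == "mean":
        return np.mean(values, axis=0)
    acc = values[0]
    for nxt in values[1:]:
        acc = _combine(expr.kind, acc, nxt)
    return acc


def reaction_weight_matrix(
    expr: GPRExpression,
    weight_matrix: np.ndarray,
    gene_index: Mapping[str, int],
    missing: set[str] | None = None,
    strategy: str = "magnitude",
) -> np.ndarray:
    """Vectorized weight propagation over many gene-weight assignments.

    ``weight_matrix`` has one row per assignment (e.g. per permutation)
    and one column per gene in ``gene_index``.  Returns one reaction
    value per row.  Genes absent from the index contribute weight 0 and
    are collected into ``missing`` when given.
    """
    if strategy not in ("magnitude", "mean"):
        raise ValueError(f"unknown weight strategy {strategy!r}")
    return _eval_weight(expr, np.asarray(weight_matrix, float), gene_index, missing, strategy)


def reaction_weight(
    expr: GPRExpression,
    weights: Mapping[str, float],
    strategy: str = "magnitude",
    missing: set[str] | None = None,
) -> float:
    """Propagate signed per-gene weights to a single reaction weight.

    Leaf -> its weight; AND -> child of minimum |.|; OR -> child of
    maximum |.|; magnitude ties resolve toward the positive value, then
    the leftmost child.  Missing genes count as weight 0.
    """
    genes = sorted(expr.genes())
    gene_index = {g: i for i, g in enumerate(genes) if g in weights}
    row = np.array([[weights[g] for g in genes if g in weights]], float)
    if row.size == 0:
        row = np.zeros((1, 0))
    local_missing: set[str] = set()
    value = reaction_weight_matrix(expr, row, gene_index, local_missing, strategy)
    if local_missing:
        logger.debug("GPR genes without weights (imputed 0): %s", sorted(local_missing))
        if missing is not None:
            missing.update(local_missing)
    return float(value[0])


def reaction_abundance(
    expr: GPRExpression | None,
    tpm: Mapping[str, float],
    missing: set[str] | None = None,
) -> float | None:
    """Propagate nonnegative transcript abundances to a reaction.

    AND = min over children (scarcest complex subunit), OR = sum over
    children (isozymes contribute additively).  An absent GPR returns
    None, the "unassessed" sentinel.  Genes without a TPM value count as
    abundance 0.
    """
    if expr is None:
        return None
    if expr.kind == "gene":
        if expr.gene not in tpm:
            if missing is not None:
                missing.add(expr.gene)
            return 0.0
        value = float(tpm[expr.gene])
        if value < 0:
            raise ValueError(f"negative TPM for gene {expr.gene!r}: {value}")
        return value
    values = [reaction_abundance(c, tpm, missing) for c in expr.children]
    if expr.kind == "and":
        return float(min(values))
    return float(sum(values))
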