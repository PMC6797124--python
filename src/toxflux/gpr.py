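"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` joins subunits of a protein complex (all required), ``or`` joins
isoenzymes or alternative complex configurations (any suffices).  Rules are
parsed into an explicit tree so that downstream code can evaluate them
against expression profiles (min over ``and``, sum over ``or``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["GPRNode", "GPRParseError", "parse_gpr", "render_gpr", "gene_ids"]

_KEYWORDS = {"and", "or"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRParseError(ValueError):
    """Raised for malformed rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRNode:
    """One node of a GPR tree.

    ``kind`` is ``"gene"`` for leaves (``gene_id`` set) or ``"and"``/``"or"``
    for internal nodes with at least two ``children``.
    """

    kind: str
    gene_id: str | None = None
    children: tuple["GPRNode", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene_id or self.children:
                raise ValueError("gene leaf must carry gene_id and no children")
        elif self.kind in ("and", "or"):
            if self.gene_id is not None or len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node needs >=2 children and no gene_id")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> Iterator[str]:
        if self.kind == "gene":
            yield self.gene_id  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child.genes()


def gene_ids(node: GPRNode) -> list[str]:
    """Unique gene ids in the tree, in first-appearance order."""
    seen: dict[str, None] = {}
    for g in node.genes():
        seen.setdefault(g)
    return list(seen)


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append((m.group(), m.start()))
    return tokens


class _Parser:
    """Recursive descent over  expr := term ('or' term)* ;
    term := factor ('and' factor)* ;  factor := gene | '(' expr ')'.

    ``and`` binds tighter than ``or``; consecutive same operators flatten
    into a single n-ary node.
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next_tok(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GPRNode:
        if not self.tokens:
            raise GPRParseError("empty rule", 0)
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[0]!r}", tok[1])
        return node

    def expr(self) -> GPRNode:
        children = [self.term()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "or":
                break
            self.next_tok()
            children.append(self.term())
        return children[0] if len(children) == 1 else _flatten("or", children)

    def term(self) -> GPRNode:
        children = [self.factor()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "and":
                break
            self.next_tok()
            children.append(self.factor())
        return children[0] if len(children) == 1 else _flatten("and", children)

    def factor(self) -> GPRNode:
        tok = self.next_tok()
        text, start = tok
        if text == "(":
            node = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parentheses", start)
            self.next_tok()
            return node
        if text == ")":
            raise GPRParseError("unbalanced parentheses", start)
        if text.lower() in _KEYWORDS:
            raise GPRParseError(f"dangling operator {text!r}", start)
        return GPRNode("gene", gene_id=text)


def _flatten(kind: str, children: list[GPRNode]) -> GPRNode:
    flat: list[GPRNode] = []
    for child in children:
        if child.kind == kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GPRNode(kind, children=tuple(flat))


def parse_gpr(rule_text: str) -> GPRNode:
    """Parse a boolean GPR rule string into a :class:`GPRNode` tree.

    Keywords ``and``/``or`` are case-insensitive, gene ids are any
    contiguous run of non-space, non-parenthesis characters, and ``and``
    binds tighter than ``or``.
    """
    return _Parser(rule_text).parse()


def render_gpr(node: GPRNode) -> str:
    """Canonical string form; inverse of :func:`parse_gpr` on its output."""
    if node.kind == "gene":
        return node.gene_id  # type: ignore[return-value]
    sep = f" {node.kind} "
    parts = []
    for child in node.children:
        text = render_gpr(child)
        # 'or' under 'and' must be parenthesized to survive precedence
        if node.kind == "and" and child.kind == "or":
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)
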