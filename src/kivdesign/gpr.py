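"""Gene-protein-reaction (GPR) boolean rules.

Grammar (case-insensitive keywords)::

    rule   := or_expr | <empty>
    or_expr  := and_expr ( OR and_expr )*
    and_expr := atom ( AND atom )*
    atom     := GENE_ID | '(' or_expr ')'

A gene id is any run of word characters plus ``.`` and ``-``. The empty
rule means "unconditionally present": it evaluates true under every
deletion set. Deleted genes evaluate false, all others true — so a
reaction is disabled by a knockout exactly when its rule evaluates false.
"""

from __future__ import annotations

import re

_TOKEN = re.compile(r"\s*(\(|\)|[\w.\-]+)")


class GPRSyntaxError(ValueError):
    """Raised when a GPR string does not parse."""


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            rest = rule[pos:].strip()
            if not rest:
                break
            raise GPRSyntaxError(f"unexpected character {rest[0]!r} in rule {rule!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


# AST: ("gene", id) | ("and", [nodes]) | ("or", [nodes])
Node = tuple


class _Parser:
    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule {self.rule!r}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise GPRSyntaxError(
                f"trailing token {self.peek()!r} in rule {self.rule!r}"
            )
        return node

    def or_expr(self) -> Node:
        parts = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def and_expr(self) -> Node:
        parts = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def atom(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.or_expr()
            if self.next() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in rule {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"misplaced token {tok!r} in rule {self.rule!r}")
        return ("gene", tok)


def parse_rule(rule: str) -> Node | None:
    """Parse a GPR string to an AST; ``None`` for the empty rule."""
    if not rule or not rule.strip():
        return None
    return _Parser(_tokenize(rule), rule).parse()


def _eval(node: Node, deleted: frozenset) -> bool:
    kind = node[0]
    if kind == "gene":
        return node[1] not in deleted
    if kind == "and":
        return all(_eval(child, deleted) for child in node[1])
    return any(_eval(child, deleted) for child in node[1])


def evaluate_gene_rule(rule: str, deleted: set[str]) -> bool:
    """Boolean value of ``rule`` with ``deleted`` genes set false.

    Empty rule -> True (unconditionally present). Raises
    :class:`GPRSyntaxError` for malformed rules.
    """
    ast = parse_rule(rule)
    if ast is None:
        return True
    return _eval(ast, frozenset(deleted))


def genes_in_rule(rule: str) -> set[str]:
    """All gene ids appearing in a rule; empty set for the empty rule."""
    ast = parse_rule(rule)
    out: set[str] = set()

    def walk(node: Node) -> None:
        if node[0] == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    if ast is not None:
        walk(ast)
    return out
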