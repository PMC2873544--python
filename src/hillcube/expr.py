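"""Boolean expression trees and the text-equation parser.

Expressions are finite trees over species references, the constants 0/1
and the operators AND, OR, NOT.  The text grammar accepts the symbolic
operators ``&&``, ``||``, ``~`` as well as the word aliases ``AND``,
``OR``, ``NOT`` (case-insensitive), with precedence NOT > AND > OR and
left associativity; parentheses override.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator


class ExpressionError(ValueError):
    """Malformed Boolean expression or equation text."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# --- AST -----------------------------------------------------------------

class BooleanExpression:
    """Base class for Boolean expression nodes."""

    __slots__ = ()

    def evaluate(self, env: dict[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> tuple[str, ...]:
        """Variable names in first-appearance (left-to-right) order."""
        seen: dict[str, None] = {}
        for name in self._iter_variables():
            seen.setdefault(name)
        return tuple(seen)

    def _iter_variables(self) -> Iterator[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        """Render with ``&&``/``||``/``~``; parses back to an equal tree."""
        return self._render(0)

    def _render(self, parent_prec: int) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_text()!r})"


@dataclass(frozen=True, repr=False)
class Var(BooleanExpression):
    name: str

    def evaluate(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise ExpressionError(f"unknown variable {self.name!r}") from None

    def _iter_variables(self):
        yield self.name

    def _render(self, parent_prec):
        return self.name


@dataclass(frozen=True, repr=False)
class Const(BooleanExpression):
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ExpressionError(f"constant must be 0 or 1, got {self.value!r}")

    def evaluate(self, env):
        return self.value

    def _iter_variables(self):
        return iter(())

    def _render(self, parent_prec):
        return str(self.value)


@dataclass(frozen=True, repr=False)
class Not(BooleanExpression):
    operand: BooleanExpression

    def evaluate(self, env):
        return 1 - self.operand.evaluate(env)

    def _iter_variables(self):
        yield from self.operand._iter_variables()

    def _render(self, parent_prec):
        return "~" + self.operand._render(3)


@dataclass(frozen=True, repr=False)
class And(BooleanExpression):
    left: BooleanExpression
    right: BooleanExpression

    _PREC = 2

    def evaluate(self, env):
        return self.left.evaluate(env) & self.right.evaluate(env)

    def _iter_variables(self):
        yield from self.left._iter_variables()
        yield from self.right._iter_variables()

    def _render(self, parent_prec):
        text = f"{self.left._render(self._PREC)} && {self.right._render(self._PREC + 1)}"
        return f"({text})" if parent_prec > self._PREC else text


@dataclass(frozen=True, repr=False)
class Or(BooleanExpression):
    left: BooleanExpression
    right: BooleanExpression

    _PREC = 1

    def evaluate(self, env):
        return self.left.evaluate(env) | self.right.evaluate(env)

    def _iter_variables(self):
        yield from self.left._iter_variables()
        yield from self.right._iter_variables()

    def _render(self, parent_prec):
        text = f"{self.left._render(self._PREC)} || {self.right._render(self._PREC + 1)}"
        return f"({text})" if parent_prec > self._PREC else text


# --- parsing -------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<and>&&)|(?P<or>\|\|)|(?P<not>~)|(?P<lpar>\()|(?P<rpar>\))"
    r"|(?P<const>[01])(?![A-Za-z0-9_])|(?P<name>[A-Za-z_][A-Za-z0-9_]*))"
)
_WORD_OPS = {"and": "and", "or": "or", "not": "not"}


def _tokenize(text: str, line: int | None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"unexpected character {rest[0]!r}", line)
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "name" and value.lower() in _WORD_OPS:
            kind = _WORD_OPS[value.lower()]
        tokens.append((kind, value))
    return tokens


class _Parser:
    """Recursive-descent parser: expr := term (OR term)*; term := factor
    (AND factor)*; factor := NOT factor | '(' expr ')' | name | const."""

    def __init__(self, tokens: list[tuple[str, str]], line: int | None):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, msg: str):
        raise ExpressionError(msg, self.line)

    def parse(self) -> BooleanExpression:
        if not self.tokens:
            self.fail("empty expression")
        expr = self.expr()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.tokens[self.pos][1]!r}")
        return expr

    def expr(self) -> BooleanExpression:
        node = self.term()
        while self.peek() == "or":
            self.take()
            node = Or(node, self.term())
        return node

    def term(self) -> BooleanExpression:
        node = self.factor()
        while self.peek() == "and":
            self.take()
            node = And(node, self.factor())
        return node

    def factor(self) -> BooleanExpression:
        kind = self.peek()
        if kind is None:
            self.fail("unexpected end of expression")
        if kind == "not":
            self.take()
            return Not(self.factor())
        if kind == "lpar":
            self.take()
            node = self.expr()
            if self.peek() != "rpar":
                self.fail("missing closing parenthesis")
            self.take()
            return node
        if kind == "const":
            return Const(int(self.take()[1]))
        if kind == "name":
            return Var(self.take()[1])
        self.fail(f"unexpected token {self.tokens[self.pos][1]!r}")


def parse_expression(text: str, line: int | None = None) -> BooleanExpression:
    """Parse a single Boolean expression string into an AST."""
    return _Parser(_tokenize(text, line), line).parse()
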