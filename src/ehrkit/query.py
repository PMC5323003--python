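"""Safe query construction and execution.

The ``where`` argument accepted throughout the toolkit is a closed
mini-language, deliberately not host-language ``eval``:

* comparisons ``==  !=  <  <=  >  >=``
* membership ``%in%``
* conjunction/disjunction ``&  |`` and parentheses
* ``IS NULL`` / ``IS NOT NULL``
* quoted ISO date / string literals (dates are stored as ISO-8601 text in
  the database, so lexicographic comparison is date comparison)
* ``.(expr)`` interpolation slots resolved against a caller-supplied
  environment; ``$`` inside a slot is mapping access (``CASE$yob``)

A parsed clause renders either to a SQL fragment (:func:`translate_where`)
or to a boolean mask over an in-memory :class:`pandas.DataFrame`
(:func:`where_mask`), so database-side and memory-side filtering share one
grammar.
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import EHRSchema, get_default_schema

__all__ = [
    "expand_interpolations",
    "expand_string",
    "wrap_sql_query",
    "translate_where",
    "where_mask",
    "select_events",
    "first_events",
    "last_events",
]


class WhereSyntaxError(ValueError):
    """Raised when a where clause does not parse."""


# ---------------------------------------------------------------------------
# .() interpolation


def _find_slots(template: str) -> list[tuple[int, int, str]]:
    """Locate ``.(expr)`` slots, honouring nested parentheses."""
    slots = []
    i = 0
    while i < len(template) - 1:
        if template[i] == "." and template[i + 1] == "(":
            depth = 0
            for j in range(i + 1, len(template)):
                if template[j] == "(":
                    depth += 1
                elif template[j] == ")":
                    depth -= 1
                    if depth == 0:
                        slots.append((i, j + 1, template[i + 2 : j]))
                        i = j
                        break
            else:
                raise WhereSyntaxError(f"unbalanced parentheses in slot at position {i}")
        i += 1
    return slots


def _eval_slot(expr: str, env: Mapping[str, Any] | None) -> Any:
    """Evaluate a slot expression against ``env``.

    Supports names, ``$`` member access on mappings/Series, and simple
    arithmetic; no builtins are exposed.
    """
    env = env or {}
    py = re.sub(r"\$\s*([A-Za-z_][A-Za-z0-9_]*)", r'["\1"]', expr)
    try:
        return eval(py, {"__builtins__": {}}, dict(env))  # noqa: S307 - closed namespace
    except NameError as e:
        raise KeyError(f"cannot resolve interpolation slot .({expr}): {e}") from None
    except KeyError as e:
        raise KeyError(f"cannot resolve interpolation slot .({expr}): missing key {e}") from None


def _is_listlike(v: Any) -> bool:
    return isinstance(v, (list, tuple, set, frozenset, np.ndarray, pd.Series, pd.Index))


def _scalar_text(v: Any) -> str:
    if isinstance(v, (np.integer, np.floating)):
        v = v.item()
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def expand_interpolations(template: str, env: Mapping[str, Any] | None = None) -> str:
    """Replace every ``.(expr)`` slot with its value's text form.

    Vectors of length > 1 are joined ``"v1, v2, ..."`` without parentheses;
    parenthesisation in SQL context is the translator's job.
    """
    out = []
    last = 0
    for start, end, expr in _find_slots(template):
        value = _eval_slot(expr, env)
        if _is_listlike(value):
            text = ", ".join(_scalar_text(v) for v in value)
        else:
            text = _scalar_text(value)
        out.append(template[last:start])
        out.append(text)
        last = end
    out.append(template[last:])
    return "".join(out)


#: Alias matching the toolkit's conversational name for this operation.
expand_string = expand_interpolations


def wrap_sql_query(template: str, *args: Any) -> str:
    """Substitute ``#1 .. #k`` placeholders into a raw SQL template.

    A length-1 argument is inserted as is; a longer vector is wrapped in
    parentheses and comma-separated.
    """

    def render(v: Any) -> str:
        if _is_listlike(v):
            vals = list(v)
            if len(vals) == 1:
                return _scalar_text(vals[0])
            return "(" + ", ".join(_scalar_text(x) for x in vals) + ")"
        return _scalar_text(v)

    def sub(m: re.Match) -> str:
        idx = int(m.group(1))
        if idx < 1 or idx > len(args):
            raise IndexError(
                f"placeholder #{idx} referenced but only {len(args)} argument(s) supplied"
            )
        return render(args[idx - 1])

    return re.sub(r"#(\d+)", sub, template)


# ---------------------------------------------------------------------------
# where-clause grammar

_TOKEN_RE = re.compile(
    r"""
    \s+
  | (?P<in>%in%)
  | (?P<op><=|>=|==|!=|<|>)
  | (?P<amp>&&?)
  | (?P<pipe>\|\|?)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<arith>[+\-*/])
  | (?P<num>\d+\.\d+|\.\d+|\d+)
  | (?P<str>'(?:[^']|'')*'|"(?:[^"]|"")*")
  | (?P<name>[A-Za-z_][A-Za-z0-9_.]*)
  | (?P<comma>,)
  | (?P<bad>=|\S)
    """,
    re.VERBOSE,
)


@dataclass
class _Tok:
    kind: str
    value: Any


def _tokenize(template: str, env: Mapping[str, Any] | None) -> list[_Tok]:
    tokens: list[_Tok] = []
    # pull out .() slots first so their contents are opaque to the grammar
    pieces: list[tuple[str, Any]] = []
    last = 0
    for start, end, expr in _find_slots(template):
        pieces.append(("text", template[last:start]))
        pieces.append(("slot", _eval_slot(expr, env)))
        last = end
    pieces.append(("text", template[last:]))

    for kind, payload in pieces:
        if kind == "slot":
            tokens.append(_Tok("slot", payload))
            continue
        for m in _TOKEN_RE.finditer(payload):
            if m.group("in"):
                tokens.append(_Tok("in", "%in%"))
            elif m.group("op"):
                tokens.append(_Tok("op", m.group("op")))
            elif m.group("amp"):
                tokens.append(_Tok("and", "&"))
            elif m.group("pipe"):
                tokens.append(_Tok("or", "|"))
            elif m.group("lpar"):
                tokens.append(_Tok("lpar", "("))
            elif m.group("rpar"):
                tokens.append(_Tok("rpar", ")"))
            elif m.group("arith"):
                tokens.append(_Tok("arith", m.group("arith")))
            elif m.group("num"):
                text = m.group("num")
                tokens.append(_Tok("num", float(text) if "." in text else int(text)))
            elif m.group("str"):
                raw = m.group("str")
                quote = raw[0]
                tokens.append(_Tok("str", raw[1:-1].replace(quote * 2, quote)))
            elif m.group("comma"):
                tokens.append(_Tok("comma", ","))
            elif m.group("name"):
                name = m.group("name")
                lower = name.lower()
                if lower in ("is", "not", "null", "and", "or", "in"):
                    tokens.append(_Tok("kw", lower))
                else:
                    tokens.append(_Tok("name", name))
            elif m.group("bad"):
                raise WhereSyntaxError(
                    f"unexpected token {m.group('bad')!r} in where clause (did you mean '=='?)"
                )
    return tokens


# AST nodes -----------------------------------------------------------------


@dataclass
class _Col:
    name: str


@dataclass
class _Lit:
    value: Any  # number or string


@dataclass
class _Slot:
    value: Any


@dataclass
class _Arith:
    op: str
    left: Any
    right: Any


@dataclass
class _Cmp:
    op: str
    left: Any
    right: Any


@dataclass
class _In:
    left: Any
    values: Any


@dataclass
class _NullTest:
    expr: Any
    negated: bool


@dataclass
class _Bool:
    op: str  # "and" | "or"
    left: Any
    right: Any


@dataclass
class _Paren:
    inner: Any


class _Parser:
    def __init__(self, tokens: list[_Tok]):
        self.toks = tokens
        self.i = 0

    def peek(self) -> _Tok | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise WhereSyntaxError("unexpected end of where clause")
        self.i += 1
        return tok

    def expect(self, kind: str, value: Any = None) -> _Tok:
        tok = self.next()
        if tok.kind != kind or (value is not None and tok.value != value):
            raise WhereSyntaxError(f"expected {value or kind}, got {tok.value!r}")
        return tok

    def parse(self) -> Any:
        node = self.or_expr()
        if self.peek() is not None:
            raise WhereSyntaxError(f"trailing input from {self.peek().value!r}")
        return node

    def or_expr(self) -> Any:
        node = self.and_expr()
        while True:
            tok = self.peek()
            if tok and (tok.kind == "or" or (tok.kind == "kw" and tok.value == "or")):
                self.next()
                node = _Bool("or", node, self.and_expr())
            else:
                return node

    def and_expr(self) -> Any:
        node = self.cmp_expr()
        while True:
            tok = self.peek()
            if tok and (tok.kind == "and" or (tok.kind == "kw" and tok.value == "and")):
                self.next()
                node = _Bool("and", node, self.cmp_expr())
            else:
                return node

    def cmp_expr(self) -> Any:
        left = self.sum_expr()
        tok = self.peek()
        if tok is None:
            return left
        if tok.kind == "op":
            self.next()
            return _Cmp(tok.value, left, self.sum_expr())
        if tok.kind == "in" or (tok.kind == "kw" and tok.value == "in"):
            self.next()
            return _In(left, self.in_rhs())
        if tok.kind == "kw" and tok.value == "is":
            self.next()
            negated = False
            nxt = self.next()
            if nxt.kind == "kw" and nxt.value == "not":
                negated = True
                nxt = self.next()
            if not (nxt.kind == "kw" and nxt.value == "null"):
                raise WhereSyntaxError("expected NULL after IS [NOT]")
            return _NullTest(left, negated)
        return left

    def in_rhs(self) -> Any:
        tok = self.peek()
        if tok and tok.kind == "slot":
            self.next()
            return _Slot(tok.value)
        if tok and tok.kind == "lpar":
            self.next()
            vals: list[Any] = []
            while True:
                t = self.next()
                if t.kind in ("num", "str"):
                    vals.append(t.value)
                elif t.kind == "slot":
                    if _is_listlike(t.value):
                        vals.extend(t.value)
                    else:
                        vals.append(t.value)
                else:
                    raise WhereSyntaxError(f"unexpected {t.value!r} in IN list")
                nxt = self.next()
                if nxt.kind == "rpar":
                    return _Lit(vals)
                if nxt.kind != "comma":
                    raise WhereSyntaxError(f"expected ',' or ')' in IN list, got {nxt.value!r}")
        raise WhereSyntaxError("right-hand side of %in% must be a .() slot or literal list")

    def sum_expr(self) -> Any:
        node = self.atom()
        while True:
            tok = self.peek()
            if tok and tok.kind == "arith":
                self.next()
                node = _Arith(tok.value, node, self.atom())
            else:
                return node

    def atom(self) -> Any:
        tok = self.next()
        if tok.kind == "num" or tok.kind == "str":
            return _Lit(tok.value)
        if tok.kind == "slot":
            return _Slot(tok.value)
        if tok.kind == "name":
            return _Col(tok.value)
        if tok.kind == "kw" and tok.value == "null":
            return _Lit(None)
        if tok.kind == "lpar":
            inner = self.or_expr()
            self.expect("rpar")
            return _Paren(inner)
        raise WhereSyntaxError(f"unexpected token {tok.value!r}")


def parse_where(template: str, env: Mapping[str, Any] | None = None) -> Any:
    """Parse a where template (with ``.()`` slots resolved) to an AST."""
    tokens = _tokenize(template, env)
    if not tokens:
        raise WhereSyntaxError("empty where clause")
    return _Parser(tokens).parse()


# SQL rendering -------------------------------------------------------------


def _sql_literal(v: Any) -> str:
    if v is None:
        return "NULL"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return _scalar_text(v)
    return "'" + str(v).replace("'", "''") + "'"


_SQL_CMP = {"==": "=", "!=": "!=", "<": "<", "<=": "<=", ">": ">", ">=": ">="}


def _to_sql(node: Any) -> str:
    if isinstance(node, _Col):
        return node.name
    if isinstance(node, _Lit):
        return _sql_literal(node.value)
    if isinstance(node, _Slot):
        if _is_listlike(node.value):
            return ", ".join(_sql_literal(v) for v in node.value)
        return _sql_literal(node.value)
    if isinstance(node, _Arith):
        return f"{_to_sql(node.left)} {node.op} {_to_sql(node.right)}"
    if isinstance(node, _Cmp):
        return f"{_to_sql(node.left)} {_SQL_CMP[node.op]} {_to_sql(node.right)}"
    if isinstance(node, _In):
        vals = node.values.value if isinstance(node.values, (_Slot, _Lit)) else node.values
        if not _is_listlike(vals):
            vals = [vals]
        return f"{_to_sql(node.left)} IN ({', '.join(_sql_literal(v) for v in vals)})"
    if isinstance(node, _NullTest):
        return f"{_to_sql(node.expr)} IS {'NOT ' if node.negated else ''}NULL"
    if isinstance(node, _Bool):
        return f"{_to_sql(node.left)} {node.op.upper()} {_to_sql(node.right)}"
    if isinstance(node, _Paren):
        return f"({_to_sql(node.inner)})"
    raise TypeError(f"cannot render node {node!r}")


def translate_where(template: str, env: Mapping[str, Any] | None = None) -> str:
    """Translate a where template into a SQL fragment."""
    return _to_sql(parse_where(template, env))


# in-memory evaluation ------------------------------------------------------

_PY_CMP: dict[str, Callable] = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


def _eval_value(node: Any, df: pd.DataFrame) -> Any:
    if isinstance(node, _Col):
        if node.name not in df.columns:
            raise KeyError(f"unknown column {node.name!r}")
        return df[node.name]
    if isinstance(node, _Lit):
        return node.value
    if isinstance(node, _Slot):
        return node.value
    if isinstance(node, _Arith):
        left, right = _eval_value(node.left, df), _eval_value(node.right, df)
        return {"+": operator.add, "-": operator.sub, "*": operator.mul, "/": operator.truediv}[
            node.op
        ](left, right)
    if isinstance(node, _Paren):
        return _eval_value(node.inner, df)
    raise TypeError(f"cannot evaluate node {node!r} as a value")


def _safe_cmp(left: Any, op: str, right: Any, index: pd.Index) -> pd.Series:
    """SQL three-valued comparison collapsed to a mask: NULL compares false."""
    fn = _PY_CMP[op]
    if isinstance(left, pd.Series) or isinstance(right, pd.Series):
        valid = pd.Series(True, index=index)
        for side in (left, right):
            if isinstance(side, pd.Series):
                valid &= side.notna()
            elif side is None:
                valid &= False
        out = pd.Series(False, index=index)
        if valid.any():
            lv = left[valid] if isinstance(left, pd.Series) else left
            rv = right[valid] if isinstance(right, pd.Series) else right
            out.loc[valid] = np.asarray(fn(lv, rv), dtype=bool)
        return out
    return pd.Series(bool(fn(left, right)) if left is not None and right is not None else False,
                     index=index)


def _eval_mask(node: Any, df: pd.DataFrame) -> pd.Series:
    if isinstance(node, _Bool):
        left, right = _eval_mask(node.left, df), _eval_mask(node.right, df)
        return (left & right) if node.op == "and" else (left | right)
    if isinstance(node, _Paren):
        return _eval_mask(node.inner, df)
    if isinstance(node, _Cmp):
        return _safe_cmp(_eval_value(node.left, df), node.op, _eval_value(node.right, df), df.index)
    if isinstance(node, _In):
        vals = node.values.value if isinstance(node.values, (_Slot, _Lit)) else node.values
        if not _is_listlike(vals):
            vals = [vals]
        left = _eval_value(node.left, df)
        if isinstance(left, pd.Series):
            return left.isin(list(vals))
        return pd.Series(left in list(vals), index=df.index)
    if isinstance(node, _NullTest):
        v = _eval_value(node.expr, df)
        if isinstance(v, pd.Series):
            return v.notna() if node.negated else v.isna()
        return pd.Series((v is not None) if node.negated else (v is None), index=df.index)
    raise WhereSyntaxError("where clause does not reduce to a boolean expression")


def where_mask(
    df: pd.DataFrame, template: str, env: Mapping[str, Any] | None = None
) -> pd.Series:
    """Evaluate a where template as a boolean mask over ``df``."""
    return _eval_mask(parse_where(template, env), df).astype(bool)


# ---------------------------------------------------------------------------
# database selects


def _convert_date_columns(df: pd.DataFrame, schema: EHRSchema) -> pd.DataFrame:
    for col in schema.date_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    return df


def build_select(
    tab: str,
    columns: Sequence[str] = ("*",),
    where: str | None = None,
    env: Mapping[str, Any] | None = None,
) -> str:
    """Compose the SELECT statement used by :func:`select_events`."""
    cols = ", ".join(columns)
    sql = f"SELECT {cols} FROM {tab}"
    if where:
        sql += f" WHERE {translate_where(where, env)}"
    return sql


def select_events(
    db,
    tab: str,
    columns: Sequence[str] = ("*",),
    where: str | None = None,
    env: Mapping[str, Any] | None = None,
    sql_only: bool = False,
    convert_dates: bool = False,
    schema: EHRSchema | None = None,
) -> pd.DataFrame | str:
    """Select all events in ``tab`` matching ``where``.

    ``columns`` entries pass through verbatim, so SQL fragments such as
    ``"DISTINCT patid"`` are allowed.  With ``sql_only`` the generated SQL
    is returned instead of being executed.
    """
    schema = schema or get_default_schema()
    sql = build_select(tab, columns, where, env)
    if sql_only:
        return sql
    try:
        df = pd.read_sql_query(sql, db.conn)
    except Exception as e:  # surface the generated SQL with the store's error
        raise type(e)(f"{e} [query: {sql}]") from e
    if convert_dates:
        df = _convert_date_columns(df, schema)
    return df


def _extreme_events(
    db,
    tab: str,
    columns: Sequence[str],
    where: str | None,
    env: Mapping[str, Any] | None,
    schema: EHRSchema,
    last: bool,
    convert_dates: bool,
) -> pd.DataFrame:
    cols = list(columns)
    df = select_events(
        db, tab, cols + ["rowid AS _rid"], where, env, schema=schema
    )
    pid, edate = schema.patient_id, schema.event_date
    # stable sort: ties on eventdate resolved by lowest store rowid
    df = df.sort_values([pid, edate, "_rid"], kind="stable")
    if last:
        # among rows at the per-patient maximum date, keep the lowest rowid
        df = df[df[edate] == df.groupby(pid)[edate].transform("max")]
    out = df.drop_duplicates(subset=pid, keep="first").drop(columns="_rid")
    out = out.reset_index(drop=True)
    if convert_dates:
        out = _convert_date_columns(out, schema)
    return out


def first_events(
    db,
    tab: str,
    columns: Sequence[str] = ("*",),
    where: str | None = None,
    env: Mapping[str, Any] | None = None,
    schema: EHRSchema | None = None,
    convert_dates: bool = False,
) -> pd.DataFrame:
    """Earliest matching event per patient."""
    schema = schema or get_default_schema()
    return _extreme_events(db, tab, columns, where, env, schema, False, convert_dates)


def last_events(
    db,
    tab: str,
    columns: Sequence[str] = ("*",),
    where: str | None = None,
    env: Mapping[str, Any] | None = None,
    schema: EHRSchema | None = None,
    convert_dates: bool = False,
) -> pd.DataFrame:
    """Latest matching event per patient."""
    schema = schema or get_default_schema()
    return _extreme_events(db, tab, columns, where, env, schema, True, convert_dates)
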