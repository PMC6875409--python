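"""A small, sandboxed interpreter for the embedded scripting dialect.

Script nodes carry short string-manipulation functions written in a
Lua-flavoured language.  This module implements the subset those
scripts need: function definitions, ``if/elseif/else``, ``while`` and
numeric ``for`` loops, ``local`` variables, the usual operators
(including ``..`` concatenation and ``#`` length), multiple return
values, tables, and a string library (``match``, ``find``, ``sub``,
``len``, ``upper``, ``lower``, ``rep``, ``reverse``, ``format``) whose
pattern functions use :mod:`guiforge.luapat`.

The environment is sandboxed: there is no ``io``, ``os``, ``require``
or any other route to files, processes or the network — reading such a
name raises :class:`SandboxError`.  Execution is bounded by a step
budget and a wall-clock limit so a runaway script cannot stall
assembly.

Semantics worth noting (all matching the dialect's conventions):
``string.sub(s, 0, j)`` treats 0 like 1; negative indices count from
the string end; ``find`` returns the 1-based inclusive span; only
``nil`` and ``false`` are falsy; ``==`` never coerces across types
while arithmetic coerces numeric strings.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from typing import Any, Optional

from . import luapat
from .errors import SandboxError, ScriptError

__all__ = ["LuaInterpreter", "LuaError", "run_chunk", "lua_tostring"]


class LuaError(ScriptError):
    """Runtime error raised inside an embedded script."""


_SANDBOXED_NAMES = frozenset({
    "io", "os", "require", "dofile", "load", "loadstring", "loadfile",
    "package", "debug", "collectgarbage", "getfenv", "setfenv",
    "coroutine", "arg",
})

# ---------------------------------------------------------------------------
# lexer

_KEYWORDS = frozenset({
    "and", "break", "do", "else", "elseif", "end", "false", "for",
    "function", "if", "in", "local", "nil", "not", "or", "repeat",
    "return", "then", "true", "until", "while",
})

_TOKEN_SPEC = [
    ("SKIP", r"[ \t\r\n]+"),
    ("COMMENT", r"--\[\[.*?\]\]|--[^\n]*"),
    ("NUMBER", r"0[xX][0-9a-fA-F]+|\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+"),
    ("NAME", r"[A-Za-z_][A-Za-z0-9_]*"),
    ("STRING", r'"(?:\\.|[^"\\])*"' + r"|'(?:\\.|[^'\\])*'"),
    ("OP", r"\.\.\.|\.\.|==|~=|<=|>=|[-+*/%^#<>=(){}\[\];:,.]"),
]
_TOKEN_RE = re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC),
                       re.DOTALL)

_ESCAPES = {"n": "\n", "t": "\t", "r": "\r", "a": "\a", "b": "\b",
            "f": "\f", "v": "\v", "\\": "\\", '"': '"', "'": "'",
            "\n": "\n", "0": "\0"}


@dataclass
class _Token:
    kind: str  # NAME KEYWORD NUMBER STRING OP EOF
    value: Any
    pos: int


def _unescape(raw: str) -> str:
    body = raw[1:-1]
    out: list[str] = []
    i = 0
    while i < len(body):
        c = body[i]
        if c == "\\" and i + 1 < len(body):
            nxt = body[i + 1]
            if nxt in _ESCAPES:
                out.append(_ESCAPES[nxt])
                i += 2
                continue
            if nxt.isdigit():
                j = i + 1
                while j < len(body) and j < i + 4 and body[j].isdigit():
                    j += 1
                out.append(chr(int(body[i + 1:j])))
                i = j
                continue
        out.append(c)
        i += 1
    return "".join(out)


def _tokenize(source: str) -> list[_Token]:
    # smart quotes appear when sources pass through word processors;
    # normalise them so authored examples still run
    source = (source.replace("\u201c", '"').replace("\u201d", '"')
              .replace("\u2018", "'").replace("\u2019", "'"))
    tokens: list[_Token] = []
    pos = 0
    while pos < len(source):
        m = _TOKEN_RE.match(source, pos)
        if m is None:
            raise LuaError(
                f"unexpected character {source[pos]!r} at offset {pos}")
        kind = m.lastgroup
        text = m.group()
        if kind == "SKIP" or kind == "COMMENT":
            pass
        elif kind == "NUMBER":
            if text.lower().startswith("0x"):
                value: Any = int(text, 16)
            elif "." in text or "e" in text.lower():
                value = float(text)
            else:
                value = int(text)
            tokens.append(_Token("NUMBER", value, pos))
        elif kind == "NAME":
            if text in _KEYWORDS:
                tokens.append(_Token("KEYWORD", text, pos))
            else:
                tokens.append(_Token("NAME", text, pos))
        elif kind == "STRING":
            tokens.append(_Token("STRING", _unescape(text), pos))
        else:
            tokens.append(_Token("OP", text, pos))
        pos = m.end()
    tokens.append(_Token("EOF", None, pos))
    return tokens


# ---------------------------------------------------------------------------
# AST (lightweight tuples: (tag, ...))

class _Parser:
    def __init__(self, tokens: list[_Token]) -> None:
        self.tokens = tokens
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def check(self, kind: str, value: Optional[str] = None) -> bool:
        tok = self.peek()
        return tok.kind == kind and (value is None or tok.value == value)

    def accept(self, kind: str, value: Optional[str] = None) -> bool:
        if self.check(kind, value):
            self.next()
            return True
        return False

    def expect(self, kind: str, value: Optional[str] = None) -> _Token:
        tok = self.next()
        if tok.kind != kind or (value is not None and tok.value != value):
            raise LuaError(
                f"expected {value or kind}, got {tok.value!r} "
                f"at offset {tok.pos}")
        return tok

    # ---- statements ------------------------------------------------
    def parse_chunk(self, terminators: tuple[str, ...] = ()) -> list:
        stats: list = []
        while True:
            tok = self.peek()
            if tok.kind == "EOF":
                break
            if tok.kind == "KEYWORD" and tok.value in terminators:
                break
            if self.accept("OP", ";"):
                continue
            stats.append(self.parse_statement())
            if stats[-1][0] in ("return", "break"):
                while self.accept("OP", ";"):
                    pass
                break
        return stats

    def parse_statement(self):
        tok = self.peek()
        if tok.kind == "KEYWORD":
            kw = tok.value
            if kw == "function":
                self.next()
                name = self.expect("NAME").value
                path = [name]
                is_method = False
                while self.accept("OP", "."):
                    path.append(self.expect("NAME").value)
                if self.accept("OP", ":"):
                    path.append(self.expect("NAME").value)
                    is_method = True
                func = self.parse_function_body(is_method)
                return ("funcdef", path, func)
            if kw == "local":
                self.next()
                if self.accept("KEYWORD", "function"):
                    name = self.expect("NAME").value
                    func = self.parse_function_body(False)
                    return ("localfunc", name, func)
                names = [self.expect("NAME").value]
                while self.accept("OP", ","):
                    names.append(self.expect("NAME").value)
                exprs = []
                if self.accept("OP", "="):
                    exprs = self.parse_exprlist()
                return ("local", names, exprs)
            if kw == "if":
                self.next()
                return self.parse_if()
            if kw == "while":
                self.next()
                cond = self.parse_expr()
                self.expect("KEYWORD", "do")
                body = self.parse_chunk(("end",))
                self.expect("KEYWORD", "end")
                return ("while", cond, body)
            if kw == "repeat":
                self.next()
                body = self.parse_chunk(("until",))
                self.expect("KEYWORD", "until")
                cond = self.parse_expr()
                return ("repeat", body, cond)
            if kw == "for":
                self.next()
                name = self.expect("NAME").value
                self.expect("OP", "=")
                start = self.parse_expr()
                self.expect("OP", ",")
                stop = self.parse_expr()
                step = None
                if self.accept("OP", ","):
                    step = self.parse_expr()
                self.expect("KEYWORD", "do")
                body = self.parse_chunk(("end",))
                self.expect("KEYWORD", "end")
                return ("fornum", name, start, stop, step, body)
            if kw == "return":
                self.next()
                exprs: list = []
                tok = self.peek()
                if not (tok.kind == "EOF"
                        or (tok.kind == "KEYWORD"
                            and tok.value in ("end", "else", "elseif",
                                              "until"))
                        or (tok.kind == "OP" and tok.value == ";")):
                    exprs = self.parse_exprlist()
                return ("return", exprs)
            if kw == "break":
                self.next()
                return ("break",)
            if kw == "do":
                self.next()
                body = self.parse_chunk(("end",))
                self.expect("KEYWORD", "end")
                return ("do", body)
            raise LuaError(f"unexpected keyword {kw!r} at offset {tok.pos}")
        # expression statement: assignment or call
        expr = self.parse_prefix_expr()
        if self.check("OP", "=") or self.check("OP", ","):
            targets = [expr]
            while self.accept("OP", ","):
                targets.append(self.parse_prefix_expr())
            self.expect("OP", "=")
            exprs = self.parse_exprlist()
            for t in targets:
                if t[0] not in ("name", "index"):
                    raise LuaError("cannot assign to this expression")
            return ("assign", targets, exprs)
        if expr[0] not in ("call", "methodcall"):
            raise LuaError("syntax error: expression is not a statement")
        return ("exprstat", expr)

    def parse_if(self):
        cond = self.parse_expr()
        self.expect("KEYWORD", "then")
        then = self.parse_chunk(("end", "else", "elseif"))
        tok = self.next()
        if tok.kind != "KEYWORD":
            raise LuaError(f"expected end of if at offset {tok.pos}")
        if tok.value == "end":
            return ("if", cond, then, None)
        if tok.value == "elseif":
            return ("if", cond, then, [self.parse_if()])
        if tok.value == "else":
            other = self.parse_chunk(("end",))
            self.expect("KEYWORD", "end")
            return ("if", cond, then, other)
        raise LuaError(f"malformed if at offset {tok.pos}")

    def parse_function_body(self, is_method: bool):
        self.expect("OP", "(")
        params: list[str] = ["self"] if is_method else []
        varargs = False
        if not self.check("OP", ")"):
            while True:
                if self.accept("OP", "..."):
                    varargs = True
                    break
                params.append(self.expect("NAME").value)
                if not self.accept("OP", ","):
                    break
        self.expect("OP", ")")
        body = self.parse_chunk(("end",))
        self.expect("KEYWORD", "end")
        return ("function", params, varargs, body)

    # ---- expressions -----------------------------------------------
    def parse_exprlist(self) -> list:
        exprs = [self.parse_expr()]
        while self.accept("OP", ","):
            exprs.append(self.parse_expr())
        return exprs

    def parse_expr(self):
        return self.parse_or()

    def parse_or(self):
        left = self.parse_and()
        while self.accept("KEYWORD", "or"):
            left = ("or", left, self.parse_and())
        return left

    def parse_and(self):
        left = self.parse_cmp()
        while self.accept("KEYWORD", "and"):
            left = ("and", left, self.parse_cmp())
        return left

    def parse_cmp(self):
        left = self.parse_concat()
        while self.peek().kind == "OP" and self.peek().value in (
                "==", "~=", "<", ">", "<=", ">="):
            op = self.next().value
            left = ("binop", op, left, self.parse_concat())
        return left

    def parse_concat(self):
        left = self.parse_add()
        if self.accept("OP", ".."):
            # right associative
            return ("binop", "..", left, self.parse_concat())
        return left

    def parse_add(self):
        left = self.parse_mul()
        while self.peek().kind == "OP" and self.peek().value in ("+", "-"):
            op = self.next().value
            left = ("binop", op, left, self.parse_mul())
        return left

    def parse_mul(self):
        left = self.parse_unary()
        while self.peek().kind == "OP" and self.peek().value in (
                "*", "/", "%"):
            op = self.next().value
            left = ("binop", op, left, self.parse_unary())
        return left

    def parse_unary(self):
        if self.accept("KEYWORD", "not"):
            return ("not", self.parse_unary())
        if self.accept("OP", "-"):
            return ("neg", self.parse_unary())
        if self.accept("OP", "#"):
            return ("len", self.parse_unary())
        return self.parse_pow()

    def parse_pow(self):
        left = self.parse_prefix_or_atom()
        if self.accept("OP", "^"):
            return ("binop", "^", left, self.parse_unary())
        return left

    def parse_prefix_or_atom(self):
        tok = self.peek()
        if tok.kind == "NUMBER":
            self.next()
            return ("const", tok.value)
        if tok.kind == "STRING":
            self.next()
            return ("const", tok.value)
        if tok.kind == "KEYWORD":
            if tok.value == "nil":
                self.next()
                return ("const", None)
            if tok.value == "true":
                self.next()
                return ("const", True)
            if tok.value == "false":
                self.next()
                return ("const", False)
            if tok.value == "function":
                self.next()
                return self.parse_function_body(False)
        if tok.kind == "OP" and tok.value == "{":
            return self.parse_table()
        return self.parse_prefix_expr()

    def parse_table(self):
        self.expect("OP", "{")
        array: list = []
        hash_items: list = []
        while not self.check("OP", "}"):
            if self.check("NAME") and self.tokens[self.i + 1].kind == "OP" \
                    and self.tokens[self.i + 1].value == "=":
                key = self.next().value
                self.next()
                hash_items.append((("const", key), self.parse_expr()))
            elif self.accept("OP", "["):
                key_expr = self.parse_expr()
                self.expect("OP", "]")
                self.expect("OP", "=")
                hash_items.append((key_expr, self.parse_expr()))
            else:
                array.append(self.parse_expr())
            if not (self.accept("OP", ",") or self.accept("OP", ";")):
                break
        self.expect("OP", "}")
        return ("table", array, hash_items)

    def parse_prefix_expr(self):
        tok = self.peek()
        if tok.kind == "OP" and tok.value == "(":
            self.next()
            expr = self.parse_expr()
            self.expect("OP", ")")
            expr = ("paren", expr)
        elif tok.kind == "NAME":
            self.next()
            expr = ("name", tok.value)
        else:
            raise LuaError(
                f"unexpected token {tok.value!r} at offset {tok.pos}")
        while True:
            tok = self.peek()
            if tok.kind != "OP":
                if tok.kind == "STRING":  # f"literal" call sugar
                    self.next()
                    expr = ("call", expr, [("const", tok.value)])
                    continue
                break
            if tok.value == ".":
                self.next()
                key = self.expect("NAME").value
                expr = ("index", expr, ("const", key))
            elif tok.value == "[":
                self.next()
                key_expr = self.parse_expr()
                self.expect("OP", "]")
                expr = ("index", expr, key_expr)
            elif tok.value == "(":
                self.next()
                args: list = []
                if not self.check("OP", ")"):
                    args = self.parse_exprlist()
                self.expect("OP", ")")
                expr = ("call", expr, args)
            elif tok.value == ":":
                self.next()
                method = self.expect("NAME").value
                if self.check("STRING"):
                    args = [("const", self.next().value)]
                else:
                    self.expect("OP", "(")
                    args = []
                    if not self.check("OP", ")"):
                        args = self.parse_exprlist()
                    self.expect("OP", ")")
                expr = ("methodcall", expr, method, args)
            elif tok.value == "{":
                table = self.parse_table()
                expr = ("call", expr, [table])
            else:
                break
        return expr


def parse_source(source: str) -> list:
    """Parse dialect source text into a statement list."""
    return _Parser(_tokenize(source)).parse_chunk()


# ---------------------------------------------------------------------------
# runtime values


@dataclass
class LuaFunction:
    params: list[str]
    varargs: bool
    body: list
    closure: "_Scope"


class LuaTable(dict):
    """Dialect table: 1-based array part lives in the same dict."""


@dataclass
class _Scope:
    vars: dict[str, Any] = field(default_factory=dict)
    parent: Optional["_Scope"] = None

    def lookup(self, name: str):
        scope: Optional[_Scope] = self
        while scope is not None:
            if name in scope.vars:
                return scope
            scope = scope.parent
        return None


class _Break(Exception):
    pass


class _Return(Exception):
    def __init__(self, values: tuple):
        self.values = values


def lua_tostring(value: Any) -> str:
    if value is None:
        return "nil"
    if value is True:
        return "true"
    if value is False:
        return "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return f"{value:.14g}"
    if isinstance(value, str):
        return value
    if isinstance(value, LuaTable):
        return f"table: 0x{id(value):x}"
    if isinstance(value, LuaFunction) or callable(value):
        return f"function: 0x{id(value):x}"
    return str(value)


def _tonumber(value: Any) -> Optional[float | int]:
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return value
    if isinstance(value, str):
        text = value.strip()
        try:
            if text.lower().startswith("0x"):
                return int(text, 16)
            if re.fullmatch(r"[+-]?\d+", text):
                return int(text)
            return float(text)
        except ValueError:
            return None
    return None


def _posrelat(pos: int, length: int) -> int:
    if pos >= 0:
        return pos
    if -pos > length:
        return 0
    return length + pos + 1


# ---------------------------------------------------------------------------
# interpreter


class LuaInterpreter:
    """Evaluates parsed chunks with step and wall-clock budgets."""

    def __init__(self, max_steps: int = 500_000,
                 max_seconds: float = 5.0) -> None:
        self.max_steps = max_steps
        self.max_seconds = max_seconds
        self.steps = 0
        self.deadline = 0.0
        self.globals = _Scope(vars=self._stdlib())

    # ---- sandboxed standard library --------------------------------
    def _stdlib(self) -> dict[str, Any]:
        def s_sub(s, i, j=-1.0):
            s = self._check_str(s, "sub")
            length = len(s)
            i = _posrelat(int(i), length)
            j = _posrelat(int(j), length)
            if i < 1:
                i = 1
            if j > length:
                j = length
            if i > j:
                return ("",)
            return (s[i - 1:j],)

        def s_find(s, pat, init=1, plain=False):
            s = self._check_str(s, "find")
            if plain:
                idx = s.find(pat, int(init) - 1)
                if idx < 0:
                    return (None,)
                return (idx + 1, idx + len(pat))
            r = luapat.find(s, pat, int(init))
            if r is None:
                return (None,)
            start, end, caps = r
            return (start, end, *caps)

        def s_match(s, pat, init=1):
            s = self._check_str(s, "match")
            r = luapat.find(s, pat, int(init))
            if r is None:
                return (None,)
            start, end, caps = r
            if caps:
                return tuple(caps)
            return (s[start - 1:end],)

        def s_len(s):
            return (len(self._check_str(s, "len")),)

        def s_rep(s, n, sep=""):
            s = self._check_str(s, "rep")
            n = int(n)
            if n <= 0:
                return ("",)
            return (s + (sep + s) * (n - 1),)

        def s_format(fmt, *args):
            fmt = self._check_str(fmt, "format")
            out: list[str] = []
            ai = 0
            i = 0
            while i < len(fmt):
                c = fmt[i]
                if c != "%":
                    out.append(c)
                    i += 1
                    continue
                m = re.match(r"%[-+ #0]*\d*(?:\.\d+)?[diouxXeEfgGqsc%]",
                             fmt[i:])
                if m is None:
                    raise LuaError(f"invalid format string {fmt!r}")
                spec = m.group()
                i += len(spec)
                if spec == "%%":
                    out.append("%")
                    continue
                arg = args[ai] if ai < len(args) else None
                ai += 1
                conv = spec[-1]
                if conv == "q":
                    out.append('"' + str(arg).replace("\\", "\\\\")
                               .replace('"', '\\"').replace("\n", "\\n")
                               + '"')
                elif conv == "s":
                    out.append(spec % lua_tostring(arg))
                elif conv in "diouxX":
                    num = _tonumber(arg)
                    if num is None:
                        raise LuaError("bad argument to 'format'")
                    out.append(spec.replace("i", "d") % int(num))
                else:
                    num = _tonumber(arg)
                    if num is None:
                        raise LuaError("bad argument to 'format'")
                    out.append(spec % float(num))
            return ("".join(out),)

        string_lib = LuaTable({
            "sub": s_sub, "find": s_find, "match": s_match,
            "len": s_len, "rep": s_rep, "format": s_format,
            "upper": lambda s: (self._check_str(s, "upper").upper(),),
            "lower": lambda s: (self._check_str(s, "lower").lower(),),
            "reverse": lambda s: (self._check_str(s, "reverse")[::-1],),
        })

        math_lib = LuaTable({
            "floor": lambda x: (int(_num(x) // 1),),
            "ceil": lambda x: (int(-(-_num(x) // 1)),),
            "abs": lambda x: (abs(_num(x)),),
            "max": lambda *xs: (max(_num(x) for x in xs),),
            "min": lambda *xs: (min(_num(x) for x in xs),),
            "huge": float("inf"),
            "pi": 3.141592653589793,
        })

        def _num(x):
            n = _tonumber(x)
            if n is None:
                raise LuaError("number expected")
            return n

        def l_type(v):
            if v is None:
                return ("nil",)
            if isinstance(v, bool):
                return ("boolean",)
            if isinstance(v, (int, float)):
                return ("number",)
            if isinstance(v, str):
                return ("string",)
            if isinstance(v, LuaTable):
                return ("table",)
            return ("function",)

        def l_error(msg=None, level=1):
            raise LuaError(lua_tostring(msg) if msg is not None
                           else "script error")

        def l_assert(v, msg=None, *rest):
            if v is None or v is False:
                raise LuaError(lua_tostring(msg) if msg is not None
                               else "assertion failed!")
            return (v, msg, *rest)

        def l_print(*args):
            # text sink only; scripts have no real stdout
            return (None,)

        return {
            "string": string_lib,
            "math": math_lib,
            "tostring": lambda v=None: (lua_tostring(v),),
            "tonumber": lambda v=None, base=None: (
                (int(str(v), int(base)) if base is not None
                 else _tonumber(v)),),
            "type": l_type,
            "error": l_error,
            "assert": l_assert,
            "print": l_print,
            "select": lambda n, *args: (
                (len(args),) if n == "#" else args[int(n) - 1:]),
            "unpack": lambda t: tuple(
                t[i] for i in range(1, len(t) + 1) if i in t),
        }

    def _check_str(self, value: Any, fn: str) -> str:
        if isinstance(value, str):
            return value
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return lua_tostring(value)
        raise LuaError(f"bad argument to 'string.{fn}' (string expected)")

    # ---- execution --------------------------------------------------
    def _tick(self) -> None:
        self.steps += 1
        if self.steps > self.max_steps:
            raise LuaError(
                f"script exceeded the step budget ({self.max_steps})")
        if self.steps % 1024 == 0 and time.monotonic() > self.deadline:
            raise LuaError(
                f"script exceeded the time budget ({self.max_seconds}s)")

    def run(self, source: str) -> _Scope:
        """Parse and execute a chunk in a fresh scope over the sandbox
        globals; returns the chunk scope (function definitions land in
        globals)."""
        chunk = parse_source(source)
        self.steps = 0
        self.deadline = time.monotonic() + self.max_seconds
        scope = _Scope(parent=self.globals)
        self.exec_block(chunk, scope)
        return scope

    def call_function(self, fn: Any, args: list[Any]) -> tuple:
        """Call a dialect or builtin function; returns its value tuple."""
        self.deadline = max(self.deadline,
                            time.monotonic() + self.max_seconds)
        return self._call(fn, tuple(args))

    def exec_block(self, stats: list, scope: _Scope) -> None:
        for stat in stats:
            self.exec_stat(stat, scope)

    def exec_stat(self, stat, scope: _Scope) -> None:
        self._tick()
        tag = stat[0]
        if tag == "local":
            _, names, exprs = stat
            values = self.eval_exprlist(exprs, scope)
            for i, name in enumerate(names):
                scope.vars[name] = values[i] if i < len(values) else None
        elif tag == "assign":
            _, targets, exprs = stat
            values = self.eval_exprlist(exprs, scope)
            for i, target in enumerate(targets):
                value = values[i] if i < len(values) else None
                self.assign(target, value, scope)
        elif tag == "exprstat":
            self.eval_multi(stat[1], scope)
        elif tag == "funcdef":
            _, path, func = stat
            fn = LuaFunction(func[1], func[2], func[3], scope)
            if len(path) == 1:
                target_scope = scope.lookup(path[0]) or self.globals
                target_scope.vars[path[0]] = fn
            else:
                obj = self.eval_single(("name", path[0]), scope)
                for key in path[1:-1]:
                    obj = self.index(obj, key)
                if not isinstance(obj, LuaTable):
                    raise LuaError("cannot define method on non-table")
                obj[path[-1]] = fn
        elif tag == "localfunc":
            _, name, func = stat
            scope.vars[name] = None
            scope.vars[name] = LuaFunction(func[1], func[2], func[3], scope)
        elif tag == "if":
            _, cond, then, other = stat
            if _truthy(self.eval_single(cond, scope)):
                self.exec_block(then, _Scope(parent=scope))
            elif other is not None:
                self.exec_block(other, _Scope(parent=scope))
        elif tag == "while":
            _, cond, body = stat
            while _truthy(self.eval_single(cond, scope)):
                self._tick()
                try:
                    self.exec_block(body, _Scope(parent=scope))
                except _Break:
                    break
        elif tag == "repeat":
            _, body, cond = stat
            while True:
                self._tick()
                inner = _Scope(parent=scope)
                try:
                    self.exec_block(body, inner)
                except _Break:
                    break
                if _truthy(self.eval_single(cond, inner)):
                    break
        elif tag == "fornum":
            _, name, start_e, stop_e, step_e, body = stat
            start = _tonumber(self.eval_single(start_e, scope))
            stop = _tonumber(self.eval_single(stop_e, scope))
            step = (_tonumber(self.eval_single(step_e, scope))
                    if step_e is not None else 1)
            if start is None or stop is None or step is None or step == 0:
                raise LuaError("'for' limits must be numbers")
            i = start
            while (step > 0 and i <= stop) or (step < 0 and i >= stop):
                self._tick()
                inner = _Scope(parent=scope)
                inner.vars[name] = i
                try:
                    self.exec_block(body, inner)
                except _Break:
                    break
                i += step
        elif tag == "return":
            _, exprs = stat
            raise _Return(tuple(self.eval_exprlist(exprs, scope)))
        elif tag == "break":
            raise _Break()
        elif tag == "do":
            self.exec_block(stat[1], _Scope(parent=scope))
        else:  # pragma: no cover
            raise LuaError(f"unknown statement {tag!r}")

    def assign(self, target, value, scope: _Scope) -> None:
        if target[0] == "name":
            name = target[1]
            holder = scope.lookup(name)
            if holder is None:
                if name in _SANDBOXED_NAMES:
                    raise SandboxError(
                        f"'{name}' is not available in the script sandbox")
                holder = self.globals
            holder.vars[name] = value
        else:  # index
            obj = self.eval_single(target[1], scope)
            key = self.eval_single(target[2], scope)
            if not isinstance(obj, LuaTable):
                raise LuaError("cannot index a non-table value")
            if value is None:
                obj.pop(key, None)
            else:
                obj[key] = value

    # ---- expression evaluation --------------------------------------
    def eval_exprlist(self, exprs: list, scope: _Scope) -> list:
        values: list = []
        for i, expr in enumerate(exprs):
            multi = self.eval_multi(expr, scope)
            if i == len(exprs) - 1:
                values.extend(multi)
            else:
                values.append(multi[0] if multi else None)
        return values

    def eval_single(self, expr, scope: _Scope):
        multi = self.eval_multi(expr, scope)
        return multi[0] if multi else None

    def index(self, obj, key):
        if isinstance(obj, LuaTable):
            if isinstance(key, float) and key == int(key):
                key = int(key)
            return obj.get(key)
        if isinstance(obj, str):
            # strings carry the string library as methods
            lib = self.globals.vars["string"]
            return lib.get(key)
        if obj is None:
            raise LuaError("attempt to index a nil value")
        raise LuaError(f"attempt to index a {type(obj).__name__} value")

    def _call(self, fn, args: tuple) -> tuple:
        self._tick()
        if isinstance(fn, LuaFunction):
            scope = _Scope(parent=fn.closure)
            for i, param in enumerate(fn.params):
                scope.vars[param] = args[i] if i < len(args) else None
            if fn.varargs:
                scope.vars["..."] = args[len(fn.params):]
            try:
                self.exec_block(fn.body, scope)
            except _Return as ret:
                return ret.values
            return ()
        if callable(fn):
            result = fn(*args)
            if isinstance(result, tuple):
                return result
            return (result,)
        if fn is None:
            raise LuaError("attempt to call a nil value")
        raise LuaError(f"attempt to call a {type(fn).__name__} value")

    def eval_multi(self, expr, scope: _Scope) -> tuple:
        self._tick()
        tag = expr[0]
        if tag == "const":
            return (expr[1],)
        if tag == "name":
            name = expr[1]
            holder = scope.lookup(name)
            if holder is not None:
                return (holder.vars[name],)
            if name in _SANDBOXED_NAMES:
                raise SandboxError(
                    f"'{name}' is not available in the script sandbox")
            if name == "...":
                return tuple(scope.lookup("...").vars["..."]
                             if scope.lookup("...") else ())
            return (None,)
        if tag == "paren":
            return (self.eval_single(expr[1], scope),)
        if tag == "index":
            obj = self.eval_single(expr[1], scope)
            key = self.eval_single(expr[2], scope)
            return (self.index(obj, key),)
        if tag == "call":
            fn = self.eval_single(expr[1], scope)
            args = tuple(self.eval_exprlist(expr[2], scope))
            return self._call(fn, args)
        if tag == "methodcall":
            obj = self.eval_single(expr[1], scope)
            method = self.index(obj, expr[2])
            if method is None:
                raise LuaError(f"method {expr[2]!r} not found")
            args = tuple(self.eval_exprlist(expr[3], scope))
            return self._call(method, (obj,) + args)
        if tag == "function":
            return (LuaFunction(expr[1], expr[2], expr[3], scope),)
        if tag == "table":
            table = LuaTable()
            _, array, hash_items = expr
            for i, item in enumerate(array):
                if i == len(array) - 1:
                    for j, v in enumerate(self.eval_multi(item, scope)):
                        table[i + 1 + j] = v
                else:
                    table[i + 1] = self.eval_single(item, scope)
            for key_expr, value_expr in hash_items:
                key = self.eval_single(key_expr, scope)
                table[key] = self.eval_single(value_expr, scope)
            return (table,)
        if tag == "and":
            left = self.eval_single(expr[1], scope)
            if not _truthy(left):
                return (left,)
            return (self.eval_single(expr[2], scope),)
        if tag == "or":
            left = self.eval_single(expr[1], scope)
            if _truthy(left):
                return (left,)
            return (self.eval_single(expr[2], scope),)
        if tag == "not":
            return (not _truthy(self.eval_single(expr[1], scope)),)
        if tag == "neg":
            num = _tonumber(self.eval_single(expr[1], scope))
            if num is None:
                raise LuaError("attempt to negate a non-number")
            return (-num,)
        if tag == "len":
            value = self.eval_single(expr[1], scope)
            if isinstance(value, str):
                return (len(value),)
            if isinstance(value, LuaTable):
                n = 0
                while (n + 1) in value:
                    n += 1
                return (n,)
            raise LuaError("attempt to get length of a non-string")
        if tag == "binop":
            return (self.binop(expr[1],
                               self.eval_single(expr[2], scope),
                               self.eval_single(expr[3], scope)),)
        raise LuaError(f"unknown expression {tag!r}")  # pragma: no cover

    def binop(self, op: str, left, right):
        if op == "..":
            for v in (left, right):
                if not isinstance(v, (str, int, float)) \
                        or isinstance(v, bool):
                    raise LuaError("attempt to concatenate a non-string")
            return lua_tostring(left) + lua_tostring(right)
        if op in ("==", "~="):
            if isinstance(left, bool) or isinstance(right, bool):
                eq = left is right
            elif isinstance(left, (int, float)) \
                    and isinstance(right, (int, float)):
                eq = left == right
            else:
                eq = type(left) is type(right) and left == right
            return eq if op == "==" else not eq
        if op in ("<", "<=", ">", ">="):
            if isinstance(left, str) and isinstance(right, str):
                pass
            else:
                ln, rn = _tonumber(left), _tonumber(right)
                if isinstance(left, str) or isinstance(right, str) \
                        or ln is None or rn is None:
                    raise LuaError(
                        "attempt to compare incompatible values")
                left, right = ln, rn
            if op == "<":
                return left < right
            if op == "<=":
                return left <= right
            if op == ">":
                return left > right
            return left >= right
        ln, rn = _tonumber(left), _tonumber(right)
        if ln is None or rn is None:
            raise LuaError("attempt to perform arithmetic on a non-number")
        if op == "+":
            return ln + rn
        if op == "-":
            return ln - rn
        if op == "*":
            return ln * rn
        if op == "/":
            if rn == 0:
                return float("inf") if ln > 0 else (
                    float("-inf") if ln < 0 else float("nan"))
            return ln / rn
        if op == "%":
            if rn == 0:
                return float("nan")
            return ln - (ln // rn) * rn
        if op == "^":
            return float(ln) ** float(rn)
        raise LuaError(f"unknown operator {op!r}")  # pragma: no cover


def _truthy(value: Any) -> bool:
    return value is not None and value is not False


def run_chunk(source: str, max_steps: int = 500_000,
              max_seconds: float = 5.0) -> tuple[LuaInterpreter, _Scope]:
    """Convenience: run a chunk in a fresh interpreter."""
    interp = LuaInterpreter(max_steps=max_steps, max_seconds=max_seconds)
    scope = interp.run(source)
    return interp, scope
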