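"""Script-node host: run a template's ``evaluate`` function.

A ``<script>`` node ships the source of an ``evaluate`` function in an
embedded dialect (the built-in one is the Lua-flavoured language of
:mod:`guiforge.luascript`).  On evaluation the host calls ``evaluate``
with the node's ``argv`` reference values, takes the last return value
of the call, and renders it as text.  Scripts are sandboxed: no file,
process or network access, bounded steps and wall time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol

from . import luapat, luascript
from .dsl import ScriptNode
from .errors import ScriptError

__all__ = [
    "ScriptResult",
    "Dialect",
    "LuaDialect",
    "register_dialect",
    "get_dialect",
    "evaluate_script",
    "match_pattern",
]


@dataclass
class ScriptResult:
    """Outcome of one script evaluation."""

    value: str
    diagnostics: list[str] = field(default_factory=list)


class Dialect(Protocol):
    """A registered scripting dialect."""

    name: str

    def evaluate(self, source: str, args: list[str]) -> ScriptResult:
        """Run ``source``, call its ``evaluate`` with ``args``, return
        the final value rendered as text."""
        ...  # pragma: no cover


class LuaDialect:
    """The built-in Lua-flavoured dialect."""

    name = "lua"

    def __init__(self, max_steps: int = 500_000,
                 max_seconds: float = 5.0) -> None:
        self.max_steps = max_steps
        self.max_seconds = max_seconds

    def evaluate(self, source: str, args: list[str]) -> ScriptResult:
        interp = luascript.LuaInterpreter(max_steps=self.max_steps,
                                          max_seconds=self.max_seconds)
        try:
            interp.run(source)
        except ScriptError:
            raise
        except RecursionError as exc:
            raise ScriptError(f"script recursion overflow: {exc}") from exc
        fn = interp.globals.vars.get("evaluate")
        if not isinstance(fn, luascript.LuaFunction):
            raise ScriptError(
                "script does not define an 'evaluate' function")
        try:
            values = interp.call_function(fn, list(args))
        except ScriptError:
            raise
        except RecursionError as exc:
            raise ScriptError(f"script recursion overflow: {exc}") from exc
        if not values:
            raise ScriptError("'evaluate' returned no value")
        # the last value of the call's return list is the node's output
        final = values[-1]
        if final is None:
            raise ScriptError("'evaluate' returned nil")
        if isinstance(final, bool):
            return ScriptResult(value="TRUE" if final else "FALSE")
        if isinstance(final, (int, float, str)):
            return ScriptResult(value=luascript.lua_tostring(final))
        raise ScriptError(
            f"'evaluate' returned a non-text value "
            f"({luascript.lua_tostring(final)})")


_REGISTRY: dict[str, Dialect] = {"lua": LuaDialect()}


def register_dialect(dialect: Dialect) -> None:
    """Register (or replace) a dialect under ``dialect.name``."""
    _REGISTRY[dialect.name] = dialect


def get_dialect(name: str) -> Dialect:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ScriptError(f"unknown script dialect {name!r}") from None


def evaluate_script(node: ScriptNode, args: list[str]) -> str:
    """Evaluate a script node with already-resolved argv values."""
    dialect = get_dialect(node.dialect)
    return dialect.evaluate(node.source, list(args)).value


def match_pattern(s: str, pattern: str) -> Optional[tuple[int, int]]:
    """Leftmost match span of the dialect's pattern syntax, 1-based
    inclusive, or ``None``.  Exposed host-side so templates' pattern
    behaviour can be checked without running a script."""
    return luapat.match_span(s, pattern)
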