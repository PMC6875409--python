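"""Execution engine: bindings, the dataflow network, command assembly.

Evaluating the execution model works like simulating a petri net: every
node is a place, its function the transition, and a transition needs
tokens (evaluated values) on all of its input places before producing
its own output token.  Tokens are produced on demand and memoized, so a
node shared by several parents is evaluated exactly once per assembly.

Assembly is pure: no process is started and no file is touched;
identical (template, bindings, injected environment) always produce
identical :class:`CommandInvocation` objects.
"""

from __future__ import annotations

import getpass
import os
import platform
import re
import socket
import tempfile
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from . import scripting
from .dsl import (AddNode, ConstNode, EnvNode, ExecNode, ExecuteNode, IfNode,
                  ScriptNode, Template, WindowElement)
from .errors import BindingError, EvaluationError, SubstitutionError

__all__ = [
    "InputBindings",
    "InjectedEnv",
    "ExecutionNetwork",
    "CommandInvocation",
    "collect_bindings",
    "substitute",
    "build_network",
    "assemble_invocation",
    "live_environment",
]

TRUE, FALSE = "TRUE", "FALSE"


@dataclass
class InputBindings:
    """User-supplied values, one per bindable window element.

    Booleans (checkboxes, checkable groups) are rendered exactly
    ``"TRUE"``/``"FALSE"``.  Values originating from a file dialog are
    flagged path-typed so backends may translate them; values flagged
    secret are never persisted or logged.
    """

    values: dict[str, str] = field(default_factory=dict)
    path_typed: set[str] = field(default_factory=set)
    secret: set[str] = field(default_factory=set)

    def __getitem__(self, key: str) -> str:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def public_values(self) -> dict[str, str]:
        """Values with secret-flagged entries removed."""
        return {k: v for k, v in self.values.items() if k not in self.secret}


def _render_bool(raw: object) -> str:
    if isinstance(raw, bool):
        return TRUE if raw else FALSE
    text = str(raw)
    if text in (TRUE, FALSE):
        return text
    if text.lower() in ("true", "1", "yes", "on"):
        return TRUE
    if text.lower() in ("false", "0", "no", "off"):
        return FALSE
    raise BindingError(f"boolean value must be TRUE/FALSE, got {text!r}")


def collect_bindings(window: WindowElement,
                     raw: Mapping[str, object],
                     secret_ids: set[str] | None = None) -> InputBindings:
    """Collect raw form values into total :class:`InputBindings`.

    Checkboxes and checkable groups render to ``"TRUE"``/``"FALSE"``
    (defaulting to unchecked when neither value nor default is given);
    file-dialog values are flagged path-typed; everything else passes
    through verbatim.  A missing value with no default raises
    :class:`BindingError` naming the offending id.
    """
    bindings = InputBindings(secret=set(secret_ids or ()))
    for elem in window.walk():
        if not elem.bindable:
            continue
        eid = elem.id
        assert eid is not None
        is_bool = elem.kind == "checkbox" or (
            elem.kind == "group" and elem.checkable)
        if eid in raw:
            value: object = raw[eid]
        elif elem.default is not None:
            value = elem.default
        elif is_bool:
            value = FALSE
        elif elem.kind == "combobox" and elem.options:
            value = elem.options[0]
        else:
            raise BindingError(
                f"no value and no default for element {eid!r}")
        if is_bool:
            bindings.values[eid] = _render_bool(value)
        else:
            bindings.values[eid] = str(value)
            if elem.kind == "filedialog":
                bindings.path_typed.add(eid)
    return bindings


# ---------------------------------------------------------------------------
# substitution

_TOKEN_RE = re.compile(r"\$(\$|\{)?")


def substitute(text: str, resolve) -> str:
    """Replace every ``${id}`` in ``text`` using ``resolve(id)``.

    ``$$`` is an escaped literal ``$``.  An unterminated ``${`` or a
    malformed identifier raises :class:`SubstitutionError`; ``resolve``
    raises for unknown ids.  A ``$`` not followed by ``$`` or ``{`` is
    kept literally.
    """
    out: list[str] = []
    pos = 0
    while True:
        m = _TOKEN_RE.search(text, pos)
        if m is None:
            out.append(text[pos:])
            return "".join(out)
        out.append(text[pos:m.start()])
        kind = m.group(1)
        if kind == "$":
            out.append("$")
            pos = m.end()
        elif kind == "{":
            end = text.find("}", m.end())
            if end < 0:
                raise SubstitutionError(
                    f"unterminated ${{ at offset {m.start()} in {text!r}")
            ident = text[m.end():end]
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", ident):
                raise SubstitutionError(
                    f"invalid reference identifier {ident!r} in {text!r}")
            out.append(resolve(ident))
            pos = end + 1
        else:
            out.append("$")
            pos = m.end()


# ---------------------------------------------------------------------------
# injected environment

InjectedEnv = Mapping[str, str]


def live_environment() -> dict[str, str]:
    """Probe the running system for the standard environment keys.

    Used at runtime; tests inject a fixed mapping instead so assembly
    stays deterministic.
    """
    try:
        ip = socket.gethostbyname(socket.gethostname())
    except OSError:
        ip = "127.0.0.1"
    env = {
        "os": platform.system(),
        "ip": ip,
        "home": os.path.expanduser("~"),
        "tmp": tempfile.gettempdir(),
        "appdir": os.getcwd(),
    }
    try:
        env["user"] = getpass.getuser()
    except Exception:  # pragma: no cover - depends on host accounts
        pass
    return env


# ---------------------------------------------------------------------------
# network construction

Part = Union[ExecNode, str]


@dataclass
class _Place:
    """One place of the network: a node or a referenced window element."""

    id: str
    kind: str                      # node class name or "input"
    node: Optional[ExecNode] = None
    inputs: tuple[str, ...] = ()   # ids of places this transition consumes


@dataclass
class ExecutionNetwork:
    """The place/transition view of a validated execution model.

    ``places`` maps an id to its :class:`_Place`; window-element inputs
    are places of kind ``"input"`` with no transition.  ``sinks`` are
    the execute nodes in document order.
    """

    places: dict[str, _Place]
    sinks: tuple[ExecuteNode, ...]
    anonymous: tuple[ExecNode, ...] = ()

    def out_degree(self, place_id: str) -> int:
        """Number of transitions consuming the token of ``place_id``."""
        n = 0
        for place in self.places.values():
            n += place.inputs.count(place_id)
        return n


def _direct_refs(node: ExecNode) -> list[str]:
    """Ids consumed by a node's transition, including those of anonymous
    descendants (whose evaluation is folded into the parent transition)."""
    from .dsl import iter_subnodes, node_references

    refs: list[str] = []
    for sub in iter_subnodes(node):
        if sub is node or sub.id is None:
            refs.extend(node_references(sub))
        else:
            refs.append(sub.id)  # identified child is its own place
    # iter_subnodes stops at nothing; identified descendants of an
    # anonymous chain still need their refs handled by their own place
    return refs


def build_network(exec_model: tuple[ExecNode, ...] | list[ExecNode],
                  known_inputs: set[str] | None = None) -> ExecutionNetwork:
    """Build the place/transition network for a validated model.

    Each identified node becomes exactly one place; a node referenced by
    k parents keeps a single place with out-degree k (single
    evaluation).  Referenced ids that are not nodes become input places.
    Cycles are re-checked here even though validation catches them.
    """
    places: dict[str, _Place] = {}
    sinks: list[ExecuteNode] = []
    anonymous: list[ExecNode] = []

    from .dsl import iter_subnodes

    node_ids: set[str] = set()
    all_nodes: list[ExecNode] = []
    for node in exec_model:
        for sub in iter_subnodes(node):
            all_nodes.append(sub)
            if sub.id is not None:
                node_ids.add(sub.id)

    for node in exec_model:
        for sub in iter_subnodes(node):
            if sub.id is None:
                if sub is node:
                    anonymous.append(sub)
                continue
            refs = tuple(_direct_refs(sub))
            places[sub.id] = _Place(id=sub.id,
                                    kind=type(sub).__name__,
                                    node=sub, inputs=refs)
        if isinstance(node, ExecuteNode):
            sinks.append(node)

    # input places for referenced non-node ids
    for place in list(places.values()):
        for ref in place.inputs:
            if ref not in places and ref not in node_ids:
                if known_inputs is not None and ref not in known_inputs:
                    raise EvaluationError(
                        f"unresolved reference ${{{ref}}}")
                places[ref] = _Place(id=ref, kind="input")
    for node in anonymous:
        for ref in _direct_refs(node):
            if ref not in places and ref not in node_ids:
                if known_inputs is not None and ref not in known_inputs:
                    raise EvaluationError(f"unresolved reference ${{{ref}}}")
                places[ref] = _Place(id=ref, kind="input")

    # acyclicity re-check (defense in depth; validation reports nicely)
    state: dict[str, int] = {}

    def visit(pid: str, stack: tuple[str, ...]) -> None:
        if state.get(pid) == 2:
            return
        if state.get(pid) == 1:
            raise EvaluationError(
                "cycle in execution network: " + " -> ".join(stack + (pid,)))
        state[pid] = 1
        for ref in places[pid].inputs:
            if ref in places:
                visit(ref, stack + (pid,))
        state[pid] = 2

    for pid in places:
        if state.get(pid, 0) == 0:
            visit(pid, ())

    return ExecutionNetwork(places=places, sinks=tuple(sinks),
                            anonymous=tuple(anonymous))


# ---------------------------------------------------------------------------
# evaluation

class _Evaluator:
    """On-demand, memoized token production over an ExecutionNetwork."""

    def __init__(self, network: ExecutionNetwork, bindings: InputBindings,
                 env: InjectedEnv,
                 trace: Optional[dict[str, int]] = None) -> None:
        self.network = network
        self.bindings = bindings
        self.env = env
        self.tokens: dict[str, str] = {}
        self.trace = trace  # id -> number of transition firings

    def resolve(self, ident: str) -> str:
        if ident in self.tokens:
            return self.tokens[ident]
        place = self.network.places.get(ident)
        if place is not None and place.node is not None:
            return self.token_for(ident)
        if ident in self.bindings:
            value = self.bindings[ident]
            self.tokens[ident] = value
            return value
        raise EvaluationError(f"unresolved reference ${{{ident}}}")

    def token_for(self, node_id: str) -> str:
        if node_id in self.tokens:
            return self.tokens[node_id]
        place = self.network.places[node_id]
        assert place.node is not None
        if self.trace is not None:
            self.trace[node_id] = self.trace.get(node_id, 0) + 1
        value = self.eval_node(place.node)
        self.tokens[node_id] = value
        return value

    def eval_part(self, part: Part) -> str:
        if isinstance(part, str):
            return substitute(part, self.resolve)
        if part.id is not None:
            return self.token_for(part.id)
        return self.eval_node(part)

    def eval_node(self, node: ExecNode) -> str:
        if isinstance(node, ConstNode):
            return node.value
        if isinstance(node, AddNode):
            return node.sep.join(self.eval_part(p) for p in node.parts)
        if isinstance(node, EnvNode):
            if node.key not in self.env:
                raise EvaluationError(
                    f"unknown environment key {node.key!r}")
            return self.env[node.key]
        if isinstance(node, IfNode):
            probe = substitute(node.probe, self.resolve)
            if probe == node.equals:
                return self.eval_part(node.then)
            if node.els is None:
                return ""
            return self.eval_part(node.els)
        if isinstance(node, ScriptNode):
            args = [substitute(a, self.resolve) for a in node.argv]
            return scripting.evaluate_script(node, args)
        if isinstance(node, ExecuteNode):
            raise EvaluationError(
                "execute nodes are sinks; they cannot feed other nodes")
        raise EvaluationError(f"unknown node variant {type(node).__name__}")


def _shell_quote(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


@dataclass(repr=False)
class CommandInvocation:
    """The engine's sole output before execution: a program, its fully
    evaluated argument text and a bindings snapshot for the backends.

    ``args`` holds the evaluated parameters in order with empty results
    dropped; ``argument_text`` joins them with single spaces.  The
    bindings snapshot lets backends translate path-typed values (WSL)
    or encode form fields (HTTP) without re-running assembly.
    """

    program: str
    args: tuple[str, ...]
    bindings: dict[str, str] = field(default_factory=dict)
    path_typed: frozenset[str] = frozenset()
    secret: frozenset[str] = frozenset()
    argv_style: bool = False

    @property
    def argument_text(self) -> str:
        return " ".join(self.args)

    @property
    def command_text(self) -> str:
        if not self.args:
            return self.program
        return f"{self.program} {self.argument_text}"

    def __repr__(self) -> str:
        def mask(key: str, value: str) -> str:
            return "***" if key in self.secret else value
        shown = tuple(
            "***" if any(self.bindings.get(k) == a and k in self.secret
                         for k in self.bindings) else a
            for a in self.args)
        return (f"CommandInvocation(program={self.program!r}, "
                f"args={shown!r})")


def evaluate_reference(network: ExecutionNetwork, ident: str,
                       bindings: InputBindings, env: InjectedEnv) -> str:
    """Evaluate a single node or binding reference (mainly for tests)."""
    return _Evaluator(network, bindings, env).resolve(ident)


def assemble_invocation(t: Template, bindings: InputBindings,
                        env: Optional[InjectedEnv] = None,
                        trace: Optional[dict[str, int]] = None
                        ) -> list[CommandInvocation]:
    """Assemble one invocation per execute node, in document order.

    Pure: nothing is executed and nothing is written.  ``env`` defaults
    to :func:`live_environment`; pass a fixed mapping for deterministic
    assembly.  ``trace`` (id -> firing count) is filled when given and
    exposes the single-evaluation token semantics.
    """
    if env is None:
        env = live_environment()
    network = build_network(t.execution,
                            known_inputs=set(bindings.values))
    evaluator = _Evaluator(network, bindings, env, trace=trace)
    invocations: list[CommandInvocation] = []
    for sink in network.sinks:
        program = substitute(sink.program, evaluator.resolve)
        args: list[str] = []
        for param in sink.params:
            value = substitute(param.text, evaluator.resolve)
            if param.quote:
                value = _shell_quote(value)
            if value != "":
                args.append(value)
        invocations.append(CommandInvocation(
            program=program,
            args=tuple(args),
            bindings=dict(bindings.values),
            path_typed=frozenset(bindings.path_typed),
            secret=frozenset(bindings.secret),
        ))
    return invocations
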