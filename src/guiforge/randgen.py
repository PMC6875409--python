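"""Seeded random fixture generators.

Used by the test-suite properties and the acceptance script: random
acyclic execution networks (const/add/if/env nodes), random CLI specs,
random Windows drive-letter paths and random filenames.  Everything is
driven by a caller-supplied :class:`random.Random` so runs are exactly
reproducible from a seed.
"""

from __future__ import annotations

import random
import string
from typing import Optional

from .dsl import (AddNode, ConstNode, EnvNode, ExecNode, ExecuteNode,
                  IfNode, Param, Template, WindowElement)
from .generators import CliInput, CliSpec

__all__ = [
    "random_network_template",
    "random_cli_spec",
    "random_windows_path",
    "random_filename",
]

_WORDS = ("alpha", "bravo", "charlie", "delta", "echo", "foxtrot",
          "golf", "hotel", "india", "juliet", "kilo", "lima")


def _ident(rng: random.Random, prefix: str, n: int) -> str:
    return f"{prefix}{n}"


def random_network_template(rng: random.Random,
                            max_nodes: int = 30,
                            max_depth: int = 6) -> Template:
    """A valid template whose execution model is a random DAG of
    const/add/if/env nodes feeding one execute node.

    Node k may only reference nodes 0..k-1 or the window inputs, which
    guarantees acyclicity by construction; sharing arises naturally
    because several later nodes may reference the same earlier one.
    ``max_depth`` bounds the add-node nesting of anonymous parts.
    """
    n_inputs = rng.randint(1, 4)
    inputs = [f"in{i}" for i in range(n_inputs)]
    widgets = [WindowElement(kind="textinput", id=name,
                             label=name, default="")
               for name in inputs]
    widgets.append(WindowElement(kind="checkbox", id="flag",
                                 default="FALSE"))
    widgets.append(WindowElement(kind="actionbutton", label="Run"))
    env_keys = ("os", "ip", "home")

    n_nodes = rng.randint(3, max_nodes)
    nodes: list[ExecNode] = []
    ids: list[str] = []

    def ref_text(depth: int) -> str:
        pool = inputs + ["flag"] + ids
        choice = rng.random()
        if choice < 0.55 and pool:
            return f"${{{rng.choice(pool)}}}"
        return rng.choice(_WORDS) + str(rng.randint(0, 9))

    def make_part(depth: int):
        if depth <= 0 or rng.random() < 0.6:
            return ref_text(depth)
        return make_node(None, depth - 1)

    def make_node(node_id: Optional[str], depth: int) -> ExecNode:
        kind = rng.choice(("const", "add", "add", "if", "env"))
        if kind == "const":
            return ConstNode(id=node_id,
                             value=rng.choice(_WORDS) + " "
                             + str(rng.randint(0, 99)))
        if kind == "add":
            n_parts = rng.randint(1, 4)
            sep = rng.choice(("", "", " ", "-"))
            return AddNode(id=node_id, sep=sep,
                           parts=tuple(make_part(depth)
                                       for _ in range(n_parts)))
        if kind == "if":
            probe = f"${{{rng.choice(inputs + ['flag'] + ids)}}}" \
                if (ids or inputs) else "x"
            equals = rng.choice(("TRUE", "FALSE", "x", _WORDS[0]))
            els = make_part(depth) if rng.random() < 0.7 else None
            return IfNode(id=node_id, probe=probe, equals=equals,
                          then=make_part(depth), els=els)
        return EnvNode(id=node_id, key=rng.choice(env_keys))

    for k in range(n_nodes):
        node_id = _ident(rng, "n", k)
        nodes.append(make_node(node_id, max_depth))
        ids.append(node_id)

    # sink references a handful of nodes so most of the graph is live
    n_params = rng.randint(1, 5)
    params = tuple(Param(text=f"${{{rng.choice(ids)}}}")
                   for _ in range(n_params))
    nodes.append(ExecuteNode(id="run", program="echo", params=params))

    return Template(
        id=f"random-{rng.randint(0, 10**6)}",
        title="random network",
        window=WindowElement(kind="group", children=tuple(widgets)),
        execution=tuple(nodes),
    )


def random_bindings(rng: random.Random, template: Template) -> dict:
    """Raw values for every bindable element of ``template``."""
    raw: dict[str, object] = {}
    for elem in template.window_elements():
        if not elem.bindable:
            continue
        if elem.kind == "checkbox" or (elem.kind == "group"
                                       and elem.checkable):
            raw[elem.id] = rng.choice(("TRUE", "FALSE"))
        elif elem.kind == "combobox" and elem.options:
            raw[elem.id] = rng.choice(elem.options)
        else:
            raw[elem.id] = rng.choice(_WORDS) + str(rng.randint(0, 99))
    return raw


_TYPES = ("boolean", "integer", "float", "string", "file", "directory",
          "choice", "unknown")


def random_cli_spec(rng: random.Random, max_inputs: int = 8) -> CliSpec:
    """A valid random CliSpec with a mix of flags, booleans, choices
    and positionals."""
    n = rng.randint(1, max_inputs)
    inputs = []
    position = 1
    for i in range(n):
        vt = rng.choice(_TYPES)
        name = f"{rng.choice(_WORDS)}_{i}"
        positional = vt not in ("boolean",) and rng.random() < 0.3
        inputs.append(CliInput(
            name=name,
            value_type=vt,
            flag=None if positional else f"--{name.replace('_', '-')}",
            required=positional or rng.random() < 0.5,
            default=None,
            help=f"value for {name}",
            position=position if positional else None,
            options=tuple(f"opt{j}" for j in range(rng.randint(2, 4)))
            if vt == "choice" else (),
        ))
        if positional:
            position += 1
    return CliSpec(
        tool_name=f"tool{rng.randint(0, 9999)}",
        description="randomly generated tool",
        base_command=("mytool",),
        inputs=tuple(inputs),
    )


def random_windows_path(rng: random.Random, max_depth: int = 6) -> str:
    """A drive-letter path with 1..max_depth components; names may
    contain spaces.  Drive letters are uppercase (canonical form)."""
    drive = rng.choice(string.ascii_uppercase)
    depth = rng.randint(1, max_depth)
    parts = []
    for _ in range(depth):
        name = "".join(rng.choice(string.ascii_letters + "0123456789")
                       for _ in range(rng.randint(1, 8)))
        if rng.random() < 0.25:
            name = name[:3] + " " + name[3:] if len(name) > 3 else name
        parts.append(name)
    if rng.random() < 0.3:
        parts[-1] += rng.choice((".txt", ".fq", ".bam", ".gz"))
    return drive + ":\\" + "\\".join(parts)


def random_filename(rng: random.Random, max_len: int = 16) -> str:
    """A filename over the alphabet [a-z0-9.] (dialect-pattern fodder)."""
    alphabet = string.ascii_lowercase + "0123456789."
    length = rng.randint(1, max_len)
    return "".join(rng.choice(alphabet) for _ in range(length))
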