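"""Template generation from CWL CommandLineTool documents and from
neutral CLI-parser specs.

Both sources are normalised into a :class:`CliSpec` first.  The widget
mapping is: boolean -> checkbox, file/directory -> open file dialog,
choice -> combobox, integer/float/string -> text input, and every
unknown or unsupported type falls back to a text input so the user can
always type the value by hand.  Boolean flags follow the store-true
convention: the flag is emitted when the box is checked and nothing
otherwise.  Subcommands become a combobox whose value gates one
argument group per subcommand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Union

import yaml

from .dsl import (ConstNode, ExecuteNode, IfNode, Param, Template,
                  WindowElement)
from .errors import GeneratorError

__all__ = [
    "CliInput",
    "CliSpec",
    "widget_for",
    "from_cli_spec",
    "from_cwl",
    "load_cli_spec",
]

VALUE_TYPES = frozenset({"boolean", "integer", "float", "string", "file",
                         "directory", "choice", "unknown"})


@dataclass
class CliInput:
    """One input of a CLI parser."""

    name: str
    value_type: str = "string"
    flag: Optional[str] = None
    required: bool = False
    default: Optional[str] = None
    help: str = ""
    position: Optional[int] = None
    options: tuple[str, ...] = ()  # choice only

    def validate(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise GeneratorError(
                f"input {self.name!r}: unknown value type "
                f"{self.value_type!r}")
        if self.value_type == "choice" and not self.options:
            raise GeneratorError(
                f"choice input {self.name!r} has no options")


@dataclass
class CliSpec:
    """Neutral description of a CLI parser."""

    tool_name: str
    description: str = ""
    base_command: tuple[str, ...] = ()
    inputs: tuple[CliInput, ...] = ()
    subcommands: tuple["CliSpec", ...] = ()
    notes: tuple[str, ...] = ()

    def validate(self) -> None:
        names = [i.name for i in self.inputs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GeneratorError(
                f"duplicate input names: {sorted(dupes)}")
        for inp in self.inputs:
            inp.validate()
        sub_names = [s.tool_name for s in self.subcommands]
        if len(sub_names) != len(set(sub_names)):
            raise GeneratorError("duplicate subcommand names")
        for sub in self.subcommands:
            sub.validate()


# ---------------------------------------------------------------------------
# widget mapping

_WIDGET_TABLE = {
    "boolean": "checkbox",
    "file": "filedialog",
    "directory": "filedialog",
    "choice": "combobox",
    "integer": "textinput",
    "float": "textinput",
    "string": "textinput",
    "unknown": "textinput",
}


def widget_for(value_type: str) -> str:
    """Window-element kind for a CLI value type (total: anything not in
    the table falls back to a text input)."""
    return _WIDGET_TABLE.get(value_type, "textinput")


# ---------------------------------------------------------------------------
# template generation


def _label_for(inp: CliInput) -> str:
    if inp.help:
        text = inp.help.strip().splitlines()[0]
        return text[:57] + "..." if len(text) > 60 else text
    return inp.name


def _widget_element(inp: CliInput, ident: str) -> WindowElement:
    kind = widget_for(inp.value_type)
    default = inp.default
    if default is None and not inp.required and kind == "textinput":
        default = ""
    if kind == "checkbox" and default is None:
        default = "FALSE"
    return WindowElement(
        kind=kind,
        id=ident,
        label=_label_for(inp),
        hint=inp.help,
        default=default,
        mode="open",
        options=inp.options if kind == "combobox" else (),
    )


def _arg_params(inputs: tuple[CliInput, ...],
                gate: Optional[tuple[str, str]] = None
                ) -> tuple[list, list[Param]]:
    """Per-input argument pieces: flagged options (booleans gated by an
    if node, optional flags suppressed when empty) in declaration
    order, then positionals by position."""
    nodes: list = []
    params: list[Param] = []

    def emit(node_id: str, piece: Union[str, IfNode]) -> None:
        """Attach one argument piece, wrapping it in the subcommand
        gate when one is active."""
        if gate is not None:
            inner: Union[str, IfNode] = piece
            if isinstance(inner, IfNode):
                nodes.append(inner)
                inner = f"${{{node_id}}}"
                node_id = f"sub_{node_id}"
            piece = IfNode(id=node_id, probe=f"${{{gate[0]}}}",
                           equals=gate[1], then=inner)
        if isinstance(piece, str):
            params.append(Param(text=piece))
        else:
            nodes.append(piece)
            params.append(Param(text=f"${{{piece.id}}}"))

    flagged = [i for i in inputs if i.position is None]
    positional = sorted((i for i in inputs if i.position is not None),
                        key=lambda i: i.position)
    for inp in flagged:
        node_id = f"arg_{inp.name}"
        flag = inp.flag or f"--{inp.name}"
        if inp.value_type == "boolean":
            emit(node_id, IfNode(id=node_id, probe=f"${{{inp.name}}}",
                                 equals="TRUE",
                                 then=ConstNode(value=flag)))
        elif inp.required:
            emit(node_id, f"{flag} ${{{inp.name}}}")
        else:
            # optional flag: emit nothing when the field is left empty
            emit(node_id, IfNode(id=node_id, probe=f"${{{inp.name}}}",
                                 equals="", then="",
                                 els=f"{flag} ${{{inp.name}}}"))
    for inp in positional:
        emit(f"arg_{inp.name}", f"${{{inp.name}}}")
    return nodes, params


def from_cli_spec(spec: CliSpec) -> Template:
    """Generate a template with one bindable widget per input.

    The generated template always validates: window elements in spec
    order plus an action button and a text output; one execute node
    whose params emit flag+value for flagged inputs, bare values for
    positionals in position order, and the bare flag (gated on "TRUE")
    for booleans.  Subcommands are selected via a combobox that gates
    one argument group per subcommand.
    """
    spec.validate()
    if not spec.base_command:
        raise GeneratorError("spec has no base command")

    widgets: list[WindowElement] = []
    if spec.description:
        widgets.append(WindowElement(kind="label", label=spec.description))
    for inp in spec.inputs:
        widgets.append(_widget_element(inp, inp.name))

    exec_nodes: list = []
    params: list[Param] = []
    for extra in spec.base_command[1:]:
        params.append(Param(text=extra.replace("$", "$$")))

    top_nodes, top_params = _arg_params(spec.inputs)
    exec_nodes.extend(top_nodes)
    params.extend(top_params)

    if spec.subcommands:
        sub_names = tuple(s.tool_name for s in spec.subcommands)
        widgets.append(WindowElement(
            kind="combobox", id="subcommand", label="Subcommand",
            options=sub_names, default=sub_names[0]))
        for sub in spec.subcommands:
            name_node = IfNode(
                id=f"subname_{sub.tool_name}",
                probe="${subcommand}", equals=sub.tool_name,
                then=ConstNode(value=sub.tool_name))
            exec_nodes.append(name_node)
            params.append(Param(text=f"${{subname_{sub.tool_name}}}"))
            for inp in sub.inputs:
                widgets.append(_widget_element(
                    inp, f"{sub.tool_name}_{inp.name}"))
            renamed = tuple(
                CliInput(name=f"{sub.tool_name}_{i.name}",
                         value_type=i.value_type, flag=i.flag,
                         required=i.required, default=i.default,
                         help=i.help, position=i.position,
                         options=i.options)
                for i in sub.inputs)
            sub_nodes, sub_params = _arg_params(
                renamed, gate=("subcommand", sub.tool_name))
            exec_nodes.extend(sub_nodes)
            params.extend(sub_params)

    widgets.append(WindowElement(kind="actionbutton", label="Run"))
    widgets.append(WindowElement(kind="textoutput"))

    exec_nodes.append(ExecuteNode(
        id="run",
        program=spec.base_command[0],
        params=tuple(params)))

    return Template(
        id=spec.tool_name,
        title=spec.tool_name,
        description=spec.description,
        window=WindowElement(kind="group", layout="vertical",
                             children=tuple(widgets)),
        execution=tuple(exec_nodes),
    )


# ---------------------------------------------------------------------------
# CWL ingestion

_CWL_TYPE_MAP = {
    "boolean": "boolean",
    "int": "integer",
    "long": "integer",
    "float": "float",
    "double": "float",
    "string": "string",
    "File": "file",
    "Directory": "directory",
    "stdin": "file",
}


def _cwl_type(raw) -> tuple[str, bool, tuple[str, ...]]:
    """Map a CWL type expression to (value_type, required, options)."""
    required = True
    if isinstance(raw, str):
        if raw.endswith("?"):
            required = False
            raw = raw[:-1]
        if raw in _CWL_TYPE_MAP:
            return _CWL_TYPE_MAP[raw], required, ()
        return "unknown", required, ()
    if isinstance(raw, list):
        members = [m for m in raw if m != "null"]
        if len(members) < len(raw):
            required = False
        if len(members) == 1:
            vt, _, opts = _cwl_type(members[0])
            return vt, required, opts
        return "unknown", required, ()
    if isinstance(raw, dict):
        if raw.get("type") == "enum":
            symbols = tuple(str(s).split("/")[-1]
                            for s in raw.get("symbols", ()))
            if symbols:
                return "choice", required, symbols
        return "unknown", required, ()
    return "unknown", required, ()


def from_cwl(doc: Union[str, dict]) -> CliSpec:
    """Normalise a CWL CommandLineTool (v1.x subset) into a CliSpec.

    Outputs, requirements, hints and expressions are ignored (noted in
    ``spec.notes``); complex types map to ``unknown`` and thus to a
    text input downstream.
    """
    if isinstance(doc, str):
        try:
            data = yaml.safe_load(doc)
        except yaml.YAMLError as exc:
            raise GeneratorError(f"cannot parse CWL document: {exc}") from exc
    else:
        data = doc
    if not isinstance(data, dict):
        raise GeneratorError("CWL document is not a mapping")
    cls = data.get("class")
    if cls != "CommandLineTool":
        raise GeneratorError(
            f"unsupported CWL document class {cls!r} "
            "(only CommandLineTool is supported)")
    version = str(data.get("cwlVersion", ""))
    if version and not version.startswith("v1."):
        raise GeneratorError(
            f"unsupported cwlVersion {version!r} (v1.x required)")

    notes: list[str] = []
    for ignored in ("outputs", "requirements", "hints"):
        if data.get(ignored):
            notes.append(f"CWL {ignored} section ignored")

    base = data.get("baseCommand", ())
    if isinstance(base, str):
        base_command: tuple[str, ...] = (base,)
    else:
        base_command = tuple(str(b) for b in base)

    raw_inputs = data.get("inputs")
    inputs: list[CliInput] = []
    if raw_inputs is None:
        notes.append("CWL document has no inputs section")
        raw_items: list[tuple[str, dict]] = []
    elif isinstance(raw_inputs, dict):
        raw_items = [(name, spec if isinstance(spec, dict)
                      else {"type": spec})
                     for name, spec in raw_inputs.items()]
    elif isinstance(raw_inputs, list):
        raw_items = []
        for item in raw_inputs:
            if not isinstance(item, dict) or "id" not in item:
                raise GeneratorError("CWL input entry lacks an id")
            raw_items.append((str(item["id"]).lstrip("#"), item))
    else:
        raise GeneratorError("CWL inputs section is malformed")

    for name, item in raw_items:
        value_type, required, options = _cwl_type(item.get("type"))
        binding = item.get("inputBinding") or {}
        flag = binding.get("prefix")
        position = binding.get("position")
        help_text = str(item.get("doc") or item.get("label") or "")
        default = item.get("default")
        if isinstance(default, dict):  # e.g. File literals
            default = default.get("path") or default.get("location")
        inputs.append(CliInput(
            name=name,
            value_type=value_type,
            flag=flag,
            required=required and default is None,
            default=None if default is None else str(default),
            help=help_text,
            position=None if position is None else int(position),
            options=options,
        ))

    tool_name = str(data.get("id") or (base_command[0] if base_command
                                       else "tool")).lstrip("#")
    spec = CliSpec(
        tool_name=tool_name,
        description=str(data.get("doc") or data.get("label") or ""),
        base_command=base_command,
        inputs=tuple(inputs),
        notes=tuple(notes),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# neutral JSON ingestion


def load_cli_spec(text: str) -> CliSpec:
    """Parse the neutral CliSpec JSON format."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GeneratorError(f"cannot parse spec JSON: {exc}") from exc
    return _spec_from_dict(data)


def _spec_from_dict(data: dict) -> CliSpec:
    if not isinstance(data, dict):
        raise GeneratorError("spec document must be a JSON object")
    if "toolName" not in data:
        raise GeneratorError("spec lacks toolName")
    base = data.get("baseCommand", [])
    if isinstance(base, str):
        base = [base]
    inputs = []
    for item in data.get("inputs", []):
        if "name" not in item:
            raise GeneratorError("spec input lacks a name")
        inputs.append(CliInput(
            name=str(item["name"]),
            value_type=str(item.get("valueType", "string")),
            flag=item.get("flag"),
            required=bool(item.get("required", False)),
            default=(None if item.get("default") is None
                     else str(item["default"])),
            help=str(item.get("help", "")),
            position=(None if item.get("position") is None
                      else int(item["position"])),
            options=tuple(str(o) for o in item.get("options", ())),
        ))
    spec = CliSpec(
        tool_name=str(data["toolName"]),
        description=str(data.get("description", "")),
        base_command=tuple(str(b) for b in base),
        inputs=tuple(inputs),
        subcommands=tuple(_spec_from_dict(s)
                          for s in data.get("subcommands", [])),
    )
    spec.validate()
    return spec
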