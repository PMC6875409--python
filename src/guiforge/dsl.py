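"""Core template DSL: domain types, XML parsing/serialization, validation.

A template document has two parts.  The ``<window>`` model is a tree of
form widgets (labels, text inputs, file dialogs, checkable group boxes,
an action button, a stream/text output).  The ``<execution>`` model is a
directed acyclic graph of value nodes (``const``, ``add``, ``env``,
``if``, ``script``) culminating in one or more ``execute`` nodes that
name a program and its parameters.  Any ``${id}`` inside node text is a
reference to a window element or another execution node; ids share one
namespace across both models.

Window tags: ``label, input, checkbox, filedialog, combobox, group,
action, streambox``.  Execution tags: ``const, add, env, if, script,
execute`` (with ``param`` children under ``execute``).
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .errors import TemplateParseError

__all__ = [
    "WindowElement",
    "ConstNode",
    "AddNode",
    "EnvNode",
    "IfNode",
    "ScriptNode",
    "Param",
    "ExecuteNode",
    "ExecNode",
    "Template",
    "Diagnostic",
    "FormEntry",
    "FormSchema",
    "parse_template",
    "validate_template",
    "serialize_template",
    "to_form_schema",
    "find_references",
    "IDENT_RE",
]

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

# reference scan used by validation; mirrors the substitution grammar:
# ``$$`` is a literal dollar, ``${IDENT}`` is a reference
_REF_RE = re.compile(r"\$\$|\$\{([A-Za-z_][A-Za-z0-9_]*)\}")

WINDOW_KINDS = frozenset(
    {"label", "textinput", "checkbox", "filedialog", "combobox",
     "group", "actionbutton", "textoutput"}
)

# XML tag -> internal widget kind
_WINDOW_TAGS = {
    "label": "label",
    "input": "textinput",
    "checkbox": "checkbox",
    "filedialog": "filedialog",
    "combobox": "combobox",
    "group": "group",
    "action": "actionbutton",
    "streambox": "textoutput",
}
_WINDOW_TAG_OF_KIND = {v: k for k, v in _WINDOW_TAGS.items()}

_KNOWN_WINDOW_ATTRS = {
    "label": {"id"},
    "textinput": {"id", "label", "hint", "default"},
    "checkbox": {"id", "label", "hint", "default"},
    "filedialog": {"id", "label", "hint", "default", "mode"},
    "combobox": {"id", "label", "hint", "default"},
    "group": {"id", "title", "hint", "checkable", "default", "layout"},
    "actionbutton": {"id"},
    "textoutput": {"id"},
}


@dataclass
class WindowElement:
    """One widget of the window model.

    ``kind`` is one of :data:`WINDOW_KINDS`.  ``id`` is absent for labels
    and optional for action buttons / text outputs, which never bind a
    value.  File dialogs carry ``mode`` (open|save); combo boxes carry
    ``options``; groups carry ``title``, ``checkable`` and ``layout``
    plus ``children``.
    """

    kind: str
    id: Optional[str] = None
    label: str = ""
    hint: str = ""
    default: Optional[str] = None
    mode: str = "open"
    options: tuple[str, ...] = ()
    title: str = ""
    checkable: bool = False
    layout: str = "vertical"
    children: tuple["WindowElement", ...] = ()

    def walk(self) -> Iterator["WindowElement"]:
        """Yield this element then all descendants in document order."""
        yield self
        for child in self.children:
            yield from child.walk()

    @property
    def bindable(self) -> bool:
        """True if the element contributes a value binding."""
        if self.kind in ("textinput", "checkbox", "filedialog", "combobox"):
            return self.id is not None
        if self.kind == "group":
            return self.checkable and self.id is not None
        return False


@dataclass
class ConstNode:
    """A literal text value; never substituted."""

    value: str
    id: Optional[str] = None


@dataclass
class AddNode:
    """Ordered concatenation of parts (child nodes or reference text)."""

    parts: tuple[Union["ExecNode", str], ...]
    sep: str = ""
    id: Optional[str] = None


@dataclass
class EnvNode:
    """Looks up a key in the injected environment (os, ip, home, ...)."""

    key: str
    id: Optional[str] = None


@dataclass
class IfNode:
    """String-equality branch: ``then`` if probe text equals ``equals``.

    An absent ``else`` branch evaluates to the empty string, keeping
    assembly total for every probe value.
    """

    probe: str
    equals: str
    then: Union["ExecNode", str]
    els: Optional[Union["ExecNode", str]] = None
    id: Optional[str] = None


@dataclass
class ScriptNode:
    """Delegates evaluation to an ``evaluate`` function in an embedded
    scripting dialect, called with the evaluated ``argv`` references."""

    argv: tuple[str, ...]
    source: str
    dialect: str = "lua"
    id: Optional[str] = None


@dataclass
class Param:
    """One parameter of an execute node: reference text, optionally
    shell-quoted (wrapped in double quotes, embedded quotes escaped)."""

    text: str
    quote: bool = False


@dataclass
class ExecuteNode:
    """Terminal node: a program plus its ordered parameter texts."""

    program: str
    params: tuple[Param, ...]
    id: Optional[str] = None


ExecNode = Union[ConstNode, AddNode, EnvNode, IfNode, ScriptNode, ExecuteNode]


@dataclass
class Template:
    """A parsed two-part template document."""

    id: str
    title: str = ""
    description: str = ""
    window: WindowElement = field(
        default_factory=lambda: WindowElement(kind="group", layout="vertical")
    )
    execution: tuple[ExecNode, ...] = ()
    # unknown-attribute notes collected while parsing; surfaced as warnings
    attr_notes: tuple[str, ...] = field(default=(), compare=False)

    def window_elements(self) -> list[WindowElement]:
        """All window elements in document order (excluding the implicit
        root group)."""
        return [e for e in self.window.walk() if e is not self.window]

    def bindable_ids(self) -> list[str]:
        return [e.id for e in self.window_elements() if e.bindable]

    def execute_nodes(self) -> list[ExecuteNode]:
        return [n for n in self.execution if isinstance(n, ExecuteNode)]


@dataclass
class Diagnostic:
    severity: str  # "error" | "warning"
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.severity}: [{self.location}] {self.message}"


# ---------------------------------------------------------------------------
# parsing


def _clean_fragment(text: Optional[str]) -> str:
    """Normalise a mixed-content text fragment.

    Indentation around line breaks comes from XML pretty-printing, not
    from the author; strip whitespace runs that contain a newline at
    either end, keep single-line inner spacing verbatim.
    """
    if not text:
        return ""
    text = re.sub(r"^[ \t]*\n\s*", "", text)
    text = re.sub(r"\s*\n[ \t]*$", "", text)
    return text


def _text_content(elem: ET.Element) -> str:
    return _clean_fragment(elem.text) if elem.text else ""


def _bool_attr(elem: ET.Element, name: str, default: bool = False) -> bool:
    raw = elem.get(name)
    if raw is None:
        return default
    if raw.lower() in ("true", "1", "yes"):
        return True
    if raw.lower() in ("false", "0", "no"):
        return False
    raise TemplateParseError(
        f"attribute {name!r} on <{elem.tag}> must be true/false, got {raw!r}"
    )


def _parse_window_element(elem: ET.Element, notes: list[str]) -> WindowElement:
    tag = elem.tag
    if tag not in _WINDOW_TAGS:
        raise TemplateParseError(f"unknown window element <{tag}>")
    kind = _WINDOW_TAGS[tag]
    for attr in elem.attrib:
        if attr not in _KNOWN_WINDOW_ATTRS[kind]:
            notes.append(f"unknown attribute {attr!r} on <{tag}>")

    elem_id = elem.get("id")
    label = elem.get("label", "")
    hint = elem.get("hint", "")
    default = elem.get("default")

    if kind == "label":
        return WindowElement(kind=kind, label=_text_content(elem))
    if kind == "actionbutton":
        return WindowElement(kind=kind, id=elem_id,
                             label=_text_content(elem) or "Run")
    if kind == "textoutput":
        return WindowElement(kind=kind, id=elem_id)
    if kind == "filedialog":
        mode = elem.get("mode", "open")
        if mode not in ("open", "save"):
            raise TemplateParseError(
                f"filedialog mode must be open|save, got {mode!r}")
        return WindowElement(kind=kind, id=elem_id, label=label, hint=hint,
                             default=default, mode=mode)
    if kind == "combobox":
        options = []
        for child in elem:
            if child.tag != "option":
                raise TemplateParseError(
                    f"unknown element <{child.tag}> inside <combobox>")
            options.append(_text_content(child))
        return WindowElement(kind=kind, id=elem_id, label=label, hint=hint,
                             default=default, options=tuple(options))
    if kind == "group":
        layout = elem.get("layout", "vertical")
        if layout not in ("vertical", "horizontal"):
            raise TemplateParseError(
                f"group layout must be vertical|horizontal, got {layout!r}")
        children = tuple(_parse_window_element(c, notes) for c in elem)
        return WindowElement(kind=kind, id=elem_id, hint=hint,
                             title=elem.get("title", ""),
                             checkable=_bool_attr(elem, "checkable"),
                             default=default, layout=layout,
                             children=children)
    # textinput / checkbox
    return WindowElement(kind=kind, id=elem_id, label=label, hint=hint,
                         default=default)


def _parse_part(elem: ET.Element, notes: list[str]) -> ExecNode:
    return _parse_exec_node(elem, notes)


def _mixed_parts(elem: ET.Element,
                 notes: list[str]) -> tuple[Union[ExecNode, str], ...]:
    """Parse mixed content (text fragments and node children) in order."""
    parts: list[Union[ExecNode, str]] = []
    head = _clean_fragment(elem.text)
    if head:
        parts.append(head)
    for child in elem:
        parts.append(_parse_part(child, notes))
        tail = _clean_fragment(child.tail)
        if tail:
            parts.append(tail)
    return tuple(parts)


def _branch_content(elem: ET.Element,
                    notes: list[str]) -> Union[ExecNode, str]:
    """Content of a ``<then>``/``<else>`` wrapper: plain reference text,
    a single node, or an implicit concatenation of mixed content."""
    parts = _mixed_parts(elem, notes)
    if len(parts) == 0:
        return ""
    if len(parts) == 1:
        return parts[0]
    return AddNode(parts=parts)


_EXEC_TAGS = {"const", "add", "env", "if", "script", "execute"}


def _parse_exec_node(elem: ET.Element, notes: list[str]) -> ExecNode:
    tag = elem.tag
    if tag not in _EXEC_TAGS:
        raise TemplateParseError(f"unknown execution node <{tag}>")
    node_id = elem.get("id")

    if tag == "const":
        for attr in elem.attrib:
            if attr != "id":
                notes.append(f"unknown attribute {attr!r} on <const>")
        return ConstNode(id=node_id, value=_text_content(elem))

    if tag == "add":
        for attr in elem.attrib:
            if attr not in ("id", "sep"):
                notes.append(f"unknown attribute {attr!r} on <add>")
        return AddNode(id=node_id, sep=elem.get("sep", ""),
                       parts=_mixed_parts(elem, notes))

    if tag == "env":
        key = elem.get("key")
        if key is None:
            raise TemplateParseError("<env> requires a key attribute")
        for attr in elem.attrib:
            if attr not in ("id", "key"):
                notes.append(f"unknown attribute {attr!r} on <env>")
        return EnvNode(id=node_id, key=key)

    if tag == "if":
        probe = elem.get("probe")
        equals = elem.get("equals")
        if probe is None or equals is None:
            raise TemplateParseError(
                "<if> requires probe and equals attributes")
        for attr in elem.attrib:
            if attr not in ("id", "probe", "equals"):
                notes.append(f"unknown attribute {attr!r} on <if>")
        then_part: Optional[Union[ExecNode, str]] = None
        else_part: Optional[Union[ExecNode, str]] = None
        for child in elem:
            if child.tag == "then":
                if then_part is not None:
                    raise TemplateParseError("<if> has more than one <then>")
                then_part = _branch_content(child, notes)
            elif child.tag == "else":
                if else_part is not None:
                    raise TemplateParseError("<if> has more than one <else>")
                else_part = _branch_content(child, notes)
            else:
                raise TemplateParseError(
                    f"unknown element <{child.tag}> inside <if>")
        if then_part is None:
            raise TemplateParseError("<if> requires a <then> branch")
        return IfNode(id=node_id, probe=probe, equals=equals,
                      then=then_part, els=else_part)

    if tag == "script":
        argv_raw = elem.get("argv", "")
        argv = tuple(a.strip() for a in argv_raw.split(",") if a.strip())
        dialect = elem.get("dialect", "lua")
        for attr in elem.attrib:
            if attr not in ("id", "argv", "dialect"):
                notes.append(f"unknown attribute {attr!r} on <script>")
        return ScriptNode(id=node_id, argv=argv,
                          source=elem.text or "", dialect=dialect)

    # execute
    program = elem.get("program")
    if program is None:
        raise TemplateParseError("<execute> requires a program attribute")
    for attr in elem.attrib:
        if attr not in ("id", "program"):
            notes.append(f"unknown attribute {attr!r} on <execute>")
    params = []
    for child in elem:
        if child.tag != "param":
            raise TemplateParseError(
                f"unknown element <{child.tag}> inside <execute>")
        quote = child.get("quote")
        if quote not in (None, "shell"):
            raise TemplateParseError(
                f'param quote must be "shell", got {quote!r}')
        params.append(Param(text=_text_content(child), quote=quote == "shell"))
    return ExecuteNode(id=node_id, program=program, params=tuple(params))


def parse_template(doc: str) -> Template:
    """Parse an XML template document into a :class:`Template`.

    Document order of window elements and execution nodes is preserved.
    Unknown tags raise :class:`TemplateParseError`; unknown attributes
    are tolerated and surfaced as warnings by :func:`validate_template`.
    """
    try:
        root = ET.parse(io.StringIO(doc)).getroot()
    except ET.ParseError as exc:
        raise TemplateParseError(f"malformed XML: {exc}") from exc

    if root.tag != "template":
        raise TemplateParseError(
            f"root element must be <template>, got <{root.tag}>")

    notes: list[str] = []
    for attr in root.attrib:
        if attr not in ("id", "title", "description"):
            notes.append(f"unknown attribute {attr!r} on <template>")

    window: Optional[WindowElement] = None
    execution: list[ExecNode] = []
    for section in root:
        if section.tag == "window":
            if window is not None:
                raise TemplateParseError("more than one <window> section")
            layout = section.get("layout", "vertical")
            window = WindowElement(
                kind="group", layout=layout,
                children=tuple(_parse_window_element(c, notes)
                               for c in section))
        elif section.tag == "execution":
            execution.extend(_parse_exec_node(c, notes) for c in section)
        elif section.tag in ("title", "description"):
            pass  # handled via attributes below
        else:
            raise TemplateParseError(f"unknown section <{section.tag}>")

    title = root.get("title", "")
    description = root.get("description", "")
    for section in root:
        if section.tag == "title":
            title = _text_content(section)
        elif section.tag == "description":
            description = _text_content(section)

    return Template(
        id=root.get("id", ""),
        title=title,
        description=description,
        window=window or WindowElement(kind="group"),
        execution=tuple(execution),
        attr_notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# reference extraction


def find_references(text: str) -> list[str]:
    """Ids referenced via ``${id}`` in reference text (``$$`` escapes)."""
    return [m.group(1) for m in _REF_RE.finditer(text) if m.group(1)]


def node_references(node: ExecNode) -> list[str]:
    """All ids a node refers to, in evaluation order (non-recursive into
    anonymous child nodes — use :func:`iter_subnodes` for those)."""
    refs: list[str] = []
    if isinstance(node, AddNode):
        for part in node.parts:
            if isinstance(part, str):
                refs.extend(find_references(part))
    elif isinstance(node, IfNode):
        refs.extend(find_references(node.probe))
        for part in (node.then, node.els):
            if isinstance(part, str):
                refs.extend(find_references(part))
    elif isinstance(node, ScriptNode):
        for arg in node.argv:
            refs.extend(find_references(arg))
    elif isinstance(node, ExecuteNode):
        refs.extend(find_references(node.program))
        for p in node.params:
            refs.extend(find_references(p.text))
    return refs


def iter_subnodes(node: ExecNode) -> Iterator[ExecNode]:
    """Yield ``node`` and all anonymous nested nodes, depth-first."""
    yield node
    if isinstance(node, AddNode):
        for part in node.parts:
            if not isinstance(part, str):
                yield from iter_subnodes(part)
    elif isinstance(node, IfNode):
        for part in (node.then, node.els):
            if part is not None and not isinstance(part, str):
                yield from iter_subnodes(part)


# ---------------------------------------------------------------------------
# validation


def validate_template(t: Template) -> list[Diagnostic]:
    """Statically check a template; returns diagnostics (empty iff valid).

    Errors: duplicate ids, unresolved references, reference cycles,
    missing execute node, multiple action buttons.  Warnings: unknown
    attributes seen at parse time, missing action button.
    """
    diags: list[Diagnostic] = []
    for note in t.attr_notes:
        diags.append(Diagnostic("warning", t.id or "template", note))

    # id uniqueness across both models
    seen: dict[str, str] = {}
    window_ids: set[str] = set()
    for elem in t.window_elements():
        if elem.id is not None:
            if elem.id in seen:
                diags.append(Diagnostic(
                    "error", elem.id,
                    f"duplicate id {elem.id!r} (also used by {seen[elem.id]})"))
            else:
                seen[elem.id] = f"window {elem.kind}"
                window_ids.add(elem.id)

    node_ids: set[str] = set()
    top_nodes: dict[str, ExecNode] = {}
    for node in t.execution:
        for sub in iter_subnodes(node):
            if sub.id is not None:
                if sub.id in seen:
                    diags.append(Diagnostic(
                        "error", sub.id,
                        f"duplicate id {sub.id!r} "
                        f"(also used by {seen[sub.id]})"))
                else:
                    seen[sub.id] = f"execution {type(sub).__name__}"
                    node_ids.add(sub.id)
                    top_nodes[sub.id] = sub

    known = window_ids | node_ids

    # unresolved references
    def check_refs(node: ExecNode) -> None:
        for sub in iter_subnodes(node):
            for ref in node_references(sub):
                if ref not in known:
                    diags.append(Diagnostic(
                        "error", sub.id or type(sub).__name__,
                        f"unresolved reference ${{{ref}}}"))

    for node in t.execution:
        check_refs(node)

    # cycle detection over the id-level reference graph
    edges: dict[str, set[str]] = {}
    for nid, node in top_nodes.items():
        targets: set[str] = set()
        for sub in iter_subnodes(node):
            targets.update(r for r in node_references(sub) if r in node_ids)
        edges[nid] = targets

    WHITE, GRAY, BLACK = 0, 1, 2
    color = {nid: WHITE for nid in edges}
    reported_cycles: set[str] = set()

    def dfs(nid: str, stack: list[str]) -> None:
        color[nid] = GRAY
        stack.append(nid)
        for nxt in sorted(edges.get(nid, ())):
            if color.get(nxt) == GRAY:
                cyc = stack[stack.index(nxt):] + [nxt]
                key = "->".join(sorted(set(cyc)))
                if key not in reported_cycles:
                    reported_cycles.add(key)
                    diags.append(Diagnostic(
                        "error", nxt,
                        "cycle in execution model: " + " -> ".join(cyc)))
            elif color.get(nxt) == WHITE:
                dfs(nxt, stack)
        stack.pop()
        color[nid] = BLACK

    for nid in sorted(edges):
        if color[nid] == WHITE:
            dfs(nid, [])

    # structural expectations
    if not t.execute_nodes():
        diags.append(Diagnostic(
            "error", t.id or "template", "execution model has no <execute> node"))
    actions = [e for e in t.window_elements() if e.kind == "actionbutton"]
    if len(actions) > 1:
        diags.append(Diagnostic(
            "error", t.id or "template",
            f"{len(actions)} action buttons; exactly one may trigger assembly"))
    elif not actions:
        diags.append(Diagnostic(
            "warning", t.id or "template", "no action button declared"))

    return diags


# ---------------------------------------------------------------------------
# serialization


def _window_to_xml(elem: WindowElement) -> ET.Element:
    tag = _WINDOW_TAG_OF_KIND[elem.kind]
    e = ET.Element(tag)
    if elem.id is not None:
        e.set("id", elem.id)
    if elem.kind == "label":
        e.text = elem.label
        return e
    if elem.kind == "actionbutton":
        e.text = elem.label
        return e
    if elem.kind == "textoutput":
        return e
    if elem.label:
        e.set("label", elem.label)
    if elem.hint:
        e.set("hint", elem.hint)
    if elem.default is not None:
        e.set("default", elem.default)
    if elem.kind == "filedialog":
        e.set("mode", elem.mode)
    elif elem.kind == "combobox":
        for opt in elem.options:
            o = ET.SubElement(e, "option")
            o.text = opt
    elif elem.kind == "group":
        if elem.title:
            e.set("title", elem.title)
        if elem.checkable:
            e.set("checkable", "true")
        if elem.layout != "vertical":
            e.set("layout", elem.layout)
        for child in elem.children:
            e.append(_window_to_xml(child))
    return e


def _part_to_xml(parent: ET.Element, part: Union[ExecNode, str]) -> None:
    if isinstance(part, str):
        if len(parent) == 0:
            parent.text = (parent.text or "") + part
        else:
            last = parent[-1]
            last.tail = (last.tail or "") + part
    else:
        parent.append(_node_to_xml(part))


def _safe_text_join(left: str, sep: str, right: str) -> str:
    """Join two text parts as one, preserving substitution semantics.

    A ``$`` run left dangling at the boundary could pair with the next
    character and form a spurious ``$$`` or ``${...}`` token; padding an
    odd run to even keeps it literal, exactly as it was when the parts
    were substituted separately.
    """
    merged = left + sep
    trailing = len(merged) - len(merged.rstrip("$"))
    if trailing % 2 == 1:
        merged += "$"
    return merged + right


def _merge_adjacent_text(parts, sep: str):
    """Collapse runs of consecutive string parts into one string.

    Mixed XML content cannot record a boundary between two adjacent
    text runs, so the serializer folds the separator in up front; the
    re-parsed single part substitutes to the same text.
    """
    merged: list = []
    for part in parts:
        if isinstance(part, str) and merged \
                and isinstance(merged[-1], str):
            merged[-1] = _safe_text_join(merged[-1], sep, part)
        else:
            merged.append(part)
    return merged


def _node_to_xml(node: ExecNode) -> ET.Element:
    if isinstance(node, ConstNode):
        e = ET.Element("const")
        e.text = node.value
    elif isinstance(node, AddNode):
        e = ET.Element("add")
        if node.sep:
            e.set("sep", node.sep)
        for part in _merge_adjacent_text(node.parts, node.sep):
            _part_to_xml(e, part)
    elif isinstance(node, EnvNode):
        e = ET.Element("env")
        e.set("key", node.key)
    elif isinstance(node, IfNode):
        e = ET.Element("if")
        e.set("probe", node.probe)
        e.set("equals", node.equals)
        then = ET.SubElement(e, "then")
        _part_to_xml(then, node.then)
        if node.els is not None:
            els = ET.SubElement(e, "else")
            _part_to_xml(els, node.els)
    elif isinstance(node, ScriptNode):
        e = ET.Element("script")
        if node.argv:
            e.set("argv", ",".join(node.argv))
        if node.dialect != "lua":
            e.set("dialect", node.dialect)
        e.text = node.source
    elif isinstance(node, ExecuteNode):
        e = ET.Element("execute")
        e.set("program", node.program)
        for p in node.params:
            pe = ET.SubElement(e, "param")
            if p.quote:
                pe.set("quote", "shell")
            pe.text = p.text
    else:  # pragma: no cover - guarded by the type union
        raise TemplateParseError(f"unknown node variant {type(node).__name__}")
    if node.id is not None:
        e.set("id", node.id)
    return e


def serialize_template(t: Template) -> str:
    """Serialize a template to canonical XML.

    ``parse_template(serialize_template(t))`` is structurally equal to
    ``t`` for any template obtained from :func:`parse_template` or the
    generators.
    """
    root = ET.Element("template")
    if t.id:
        root.set("id", t.id)
    if t.title:
        root.set("title", t.title)
    if t.description:
        root.set("description", t.description)
    window = ET.SubElement(root, "window")
    if t.window.layout != "vertical":
        window.set("layout", t.window.layout)
    for child in t.window.children:
        window.append(_window_to_xml(child))
    execution = ET.SubElement(root, "execution")
    for node in t.execution:
        execution.append(_node_to_xml(node))
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# form schema


@dataclass
class FormEntry:
    """Renderer-agnostic description of one widget."""

    id: Optional[str]
    kind: str
    label: str = ""
    hint: str = ""
    default: Optional[str] = None
    required: bool = False
    path_typed: bool = False
    checkable: bool = False
    options: tuple[str, ...] = ()
    children: tuple["FormEntry", ...] = ()

    def to_dict(self) -> dict:
        d = {"id": self.id, "kind": self.kind, "label": self.label,
             "hint": self.hint, "default": self.default,
             "required": self.required, "pathTyped": self.path_typed}
        if self.kind == "combobox":
            d["options"] = list(self.options)
        if self.kind == "group":
            d["checkable"] = self.checkable
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class FormSchema:
    """Ordered, neutral export of the window model."""

    entries: tuple[FormEntry, ...]

    def binding_keys(self) -> list[str]:
        """Ids of entries that contribute a value binding, in order."""
        keys: list[str] = []

        def visit(entry: FormEntry) -> None:
            if entry.kind in ("textinput", "checkbox", "filedialog",
                              "combobox") and entry.id is not None:
                keys.append(entry.id)
            if entry.kind == "group":
                if entry.checkable and entry.id is not None:
                    keys.append(entry.id)
                for child in entry.children:
                    visit(child)

        for entry in self.entries:
            visit(entry)
        return keys

    def to_dict(self) -> dict:
        return {"entries": [e.to_dict() for e in self.entries]}


def _entry_for(elem: WindowElement) -> FormEntry:
    return FormEntry(
        id=elem.id,
        kind=elem.kind,
        label=elem.label or elem.title,
        hint=elem.hint,
        default=elem.default,
        required=elem.bindable and elem.default is None
        and elem.kind not in ("checkbox",) and not elem.kind == "group",
        path_typed=elem.kind == "filedialog",
        checkable=elem.checkable,
        options=elem.options,
        children=tuple(_entry_for(c) for c in elem.children),
    )


def to_form_schema(t: Template) -> FormSchema:
    """Export the window model as a neutral form schema.

    One entry per window element in document order; file dialogs are
    flagged path-typed; labels and text outputs carry no binding key.
    """
    return FormSchema(entries=tuple(_entry_for(c)
                                    for c in t.window.children))
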