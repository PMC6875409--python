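"""Local template store: registered templates, saved filled templates
and search.

Layout under one root directory::

    manifest.json     # ordered entries {id, name, description, kind, path}
    templates/        # one XML file per registered template
    modules/          # install-module scripts
    filled/           # saved (template, bindings) documents, JSON

Saving a filled template records the template id, a content hash of the
template XML, the public (non-secret) bindings and a label; reloading
and reassembling with the same injected environment reproduces the
original invocation exactly, which is what makes saved runs citable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from . import dsl, engine
from .dsl import Template
from .engine import InputBindings
from .errors import StoreError

__all__ = ["StoreEntry", "FilledTemplate", "TemplateStore"]


@dataclass
class StoreEntry:
    id: str
    name: str
    description: str
    kind: str  # "template" | "install-module"
    path: str

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name,
                "description": self.description, "kind": self.kind,
                "path": self.path}


@dataclass
class FilledTemplate:
    """A saved set of parameters for one template."""

    template_id: str
    content_hash: str
    bindings: dict[str, str]
    path_typed: tuple[str, ...]
    label: str
    saved_at: str

    def to_dict(self) -> dict:
        return {
            "templateId": self.template_id,
            "contentHash": self.content_hash,
            "bindings": self.bindings,
            "pathTyped": sorted(self.path_typed),
            "label": self.label,
            "savedAt": self.saved_at,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FilledTemplate":
        return cls(
            template_id=data["templateId"],
            content_hash=data["contentHash"],
            bindings=dict(data["bindings"]),
            path_typed=tuple(data.get("pathTyped", ())),
            label=data["label"],
            saved_at=data["savedAt"],
        )


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "-"
                   for c in text) or "unnamed"


def _template_hash(xml_text: str) -> str:
    return hashlib.sha256(xml_text.encode("utf-8")).hexdigest()[:16]


class TemplateStore:
    """Filesystem-backed store rooted at one directory."""

    def __init__(self, root: Path | str) -> None:
        self.root = Path(root)
        self.templates_dir = self.root / "templates"
        self.modules_dir = self.root / "modules"
        self.filled_dir = self.root / "filled"
        for d in (self.root, self.templates_dir, self.modules_dir,
                  self.filled_dir):
            d.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.root / "manifest.json"
        if not self.manifest_path.exists():
            self._write_manifest([])

    # ---- manifest ---------------------------------------------------
    def _write_manifest(self, entries: list[StoreEntry]) -> None:
        doc = {"entries": [e.to_dict() for e in entries]}
        self.manifest_path.write_text(
            json.dumps(doc, indent=2, sort_keys=False) + "\n",
            encoding="utf-8")

    def entries(self) -> list[StoreEntry]:
        try:
            doc = json.loads(self.manifest_path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise StoreError(f"cannot read manifest: {exc}") from exc
        return [StoreEntry(**e) for e in doc.get("entries", [])]

    # ---- registration ----------------------------------------------
    def register_template(self, template: Template) -> StoreEntry:
        """Register (or update in place) a template; idempotent per id."""
        if not template.id:
            raise StoreError("template has no id")
        xml_text = dsl.serialize_template(template)
        path = self.templates_dir / f"{_slug(template.id)}.xml"
        path.write_text(xml_text, encoding="utf-8")
        entry = StoreEntry(
            id=template.id,
            name=template.title or template.id,
            description=template.description,
            kind="template",
            path=str(path.relative_to(self.root)))
        self._upsert(entry)
        return entry

    def register_module(self, module_id: str, script_text: str,
                        name: str = "", description: str = "") -> StoreEntry:
        path = self.modules_dir / f"{_slug(module_id)}.sh"
        path.write_text(script_text, encoding="utf-8")
        entry = StoreEntry(
            id=module_id, name=name or module_id,
            description=description, kind="install-module",
            path=str(path.relative_to(self.root)))
        self._upsert(entry)
        return entry

    def _upsert(self, entry: StoreEntry) -> None:
        entries = self.entries()
        for i, existing in enumerate(entries):
            if existing.id == entry.id:
                entries[i] = entry
                break
        else:
            entries.append(entry)
        self._write_manifest(entries)

    def remove(self, entry_id: str) -> None:
        entries = self.entries()
        kept = [e for e in entries if e.id != entry_id]
        if len(kept) == len(entries):
            raise StoreError(f"unknown store entry {entry_id!r}")
        for e in entries:
            if e.id == entry_id:
                target = self.root / e.path
                if target.exists():
                    target.unlink()
        self._write_manifest(kept)

    def get_template(self, template_id: str) -> Template:
        for entry in self.entries():
            if entry.id == template_id and entry.kind == "template":
                xml_text = (self.root / entry.path).read_text(
                    encoding="utf-8")
                return dsl.parse_template(xml_text)
        raise StoreError(f"template {template_id!r} is not registered")

    # ---- search -----------------------------------------------------
    def search(self, query: str) -> list[StoreEntry]:
        """Case-insensitive substring match over name + description, in
        stable manifest order.  An empty query returns everything."""
        needle = query.lower()
        return [e for e in self.entries()
                if needle in e.name.lower()
                or needle in e.description.lower()]

    # ---- filled templates -------------------------------------------
    def save_filled(self, template: Template, bindings: InputBindings,
                    label: str) -> FilledTemplate:
        """Persist the (template, bindings) pair under ``label``.

        Secret-flagged values are dropped before writing; everything
        else round-trips bit-exactly.
        """
        ids = {e.id for e in self.entries() if e.kind == "template"}
        if template.id not in ids:
            raise StoreError(
                f"template {template.id!r} is not registered")
        xml_text = dsl.serialize_template(template)
        filled = FilledTemplate(
            template_id=template.id,
            content_hash=_template_hash(xml_text),
            bindings=bindings.public_values(),
            path_typed=tuple(k for k in sorted(bindings.path_typed)
                             if k not in bindings.secret),
            label=label,
            saved_at=datetime.now(timezone.utc).isoformat(),
        )
        path = self.filled_dir / f"{_slug(label)}.json"
        path.write_text(json.dumps(filled.to_dict(), indent=2) + "\n",
                        encoding="utf-8")
        return filled

    def load_filled(self, label: str) -> FilledTemplate:
        path = self.filled_dir / f"{_slug(label)}.json"
        if not path.exists():
            raise StoreError(f"no saved run labelled {label!r}")
        return FilledTemplate.from_dict(
            json.loads(path.read_text(encoding="utf-8")))

    def reassemble(self, label: str,
                   env: Optional[dict[str, str]] = None
                   ) -> list[engine.CommandInvocation]:
        """Reload a saved run and assemble it again."""
        filled = self.load_filled(label)
        template = self.get_template(filled.template_id)
        bindings = InputBindings(
            values=dict(filled.bindings),
            path_typed=set(filled.path_typed))
        return engine.assemble_invocation(template, bindings, env=env)
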