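"""Template store: registration, search, saved filled templates and
exact reassembly of saved runs."""

import json
import random

import pytest

from guiforge import dsl, engine
from guiforge.engine import InputBindings
from guiforge.errors import StoreError
from guiforge.randgen import (random_bindings, random_network_template)
from guiforge.store import FilledTemplate, TemplateStore

from conftest import STREAM_OR_SAVE_XML

ENV = {"os": "Linux", "ip": "192.168.1.100", "home": "/home/u",
       "tmp": "/tmp", "appdir": "/app"}


@pytest.fixture
def store(tmp_path):
    return TemplateStore(tmp_path / "store")


class TestRegistration:
    def test_register_list_get(self, store, stream_or_save):
        entry = store.register_template(stream_or_save)
        assert entry.kind == "template"
        (listed,) = store.entries()
        assert listed.id == stream_or_save.id
        loaded = store.get_template(stream_or_save.id)
        assert dsl.serialize_template(loaded) \
            == dsl.serialize_template(stream_or_save)

    def test_register_is_idempotent_per_id(self, store, stream_or_save):
        store.register_template(stream_or_save)
        store.register_template(stream_or_save)
        assert len(store.entries()) == 1

    def test_reregistration_updates_in_place(self, store, stream_or_save):
        store.register_template(stream_or_save)
        updated = dsl.parse_template(
            STREAM_OR_SAVE_XML.replace(
                'title="Stream or save a file"', 'title="Renamed"'))
        store.register_template(updated)
        (entry,) = store.entries()
        assert entry.name == "Renamed"

    def test_template_without_id_rejected(self, store):
        t = dsl.Template(id="", window=dsl.WindowElement(kind="group"),
                         execution=())
        with pytest.raises(StoreError, match="id"):
            store.register_template(t)

    def test_remove_deletes_entry_and_file(self, store, stream_or_save):
        entry = store.register_template(stream_or_save)
        store.remove(stream_or_save.id)
        assert store.entries() == []
        assert not (store.root / entry.path).exists()

    def test_remove_unknown_id_errors(self, store):
        with pytest.raises(StoreError, match="unknown"):
            store.remove("ghost")

    def test_register_module_script(self, store):
        store.register_module("hisat2-installer", "#!/bin/sh\n",
                              name="Install hisat2",
                              description="spliced aligner setup")
        (entry,) = store.entries()
        assert entry.kind == "install-module"
        assert (store.root / entry.path).read_text() == "#!/bin/sh\n"

    def test_store_reopens_from_disk(self, tmp_path, stream_or_save):
        TemplateStore(tmp_path / "s").register_template(stream_or_save)
        reopened = TemplateStore(tmp_path / "s")
        assert reopened.get_template(stream_or_save.id).id \
            == stream_or_save.id


class TestSearch:
    @pytest.fixture
    def populated(self, store, stream_or_save):
        store.register_template(stream_or_save)
        store.register_module("hisat2-installer", "#!/bin/sh\n",
                              name="Install hisat2",
                              description="spliced aligner setup")
        store.register_module("bwa-installer", "#!/bin/sh\n",
                              name="Install BWA",
                              description="short-read aligner")
        return store

    def test_case_insensitive_substring_over_name(self, populated):
        assert [e.id for e in populated.search("hisat")] \
            == ["hisat2-installer"]
        assert [e.id for e in populated.search("HISAT")] \
            == ["hisat2-installer"]

    def test_description_is_searched_too(self, populated):
        assert {e.id for e in populated.search("aligner")} \
            == {"hisat2-installer", "bwa-installer"}

    def test_empty_query_returns_everything_in_order(self, populated):
        assert [e.id for e in populated.search("")] == [
            "stream-or-save", "hisat2-installer", "bwa-installer"]

    def test_no_match_returns_empty(self, populated):
        assert populated.search("salmon") == []


class TestFilledTemplates:
    def test_save_requires_registration(self, store, stream_or_save):
        with pytest.raises(StoreError, match="registered"):
            store.save_filled(stream_or_save, InputBindings(), "run1")

    def test_save_load_round_trip(self, store, stream_or_save):
        store.register_template(stream_or_save)
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": True, "output": "/tmp/out.txt"})
        saved = store.save_filled(stream_or_save, b, "stream run")
        loaded = store.load_filled("stream run")
        assert loaded == FilledTemplate.from_dict(saved.to_dict())
        assert loaded.bindings["os"] == "TRUE"
        assert "input" in loaded.path_typed

    def test_load_unknown_label_errors(self, store):
        with pytest.raises(StoreError, match="label"):
            store.load_filled("missing")

    def test_reassembly_reproduces_the_invocation_exactly(
            self, store, stream_or_save):
        store.register_template(stream_or_save)
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": True, "output": "/tmp/out.txt"})
        original = engine.assemble_invocation(stream_or_save, b, env=ENV)
        store.save_filled(stream_or_save, b, "run")
        replayed = store.reassemble("run", env=ENV)
        assert [(i.program, i.args) for i in replayed] \
            == [(i.program, i.args) for i in original]

    def test_reassembly_on_seeded_random_templates(self, store):
        """Save/reload/reassemble is string-exact on 40 seeded random
        networks with random bindings."""
        rng = random.Random(20240004)
        for k in range(40):
            t = random_network_template(rng)
            t = dsl.Template(id=f"rand-{k}", title=t.title,
                             description=t.description,
                             window=t.window, execution=t.execution)
            store.register_template(t)
            raw = random_bindings(rng, t)
            b = engine.collect_bindings(t.window, raw)
            original = engine.assemble_invocation(t, b, env=ENV)
            store.save_filled(t, b, f"run-{k}")
            replayed = store.reassemble(f"run-{k}", env=ENV)
            assert [(i.program, i.args) for i in replayed] \
                == [(i.program, i.args) for i in original]

    def test_secret_bindings_never_persisted(self, store, stream_or_save):
        store.register_template(stream_or_save)
        b = InputBindings(
            values={"input": "f", "os": "TRUE", "output": "o",
                    "token": "s3same"},
            path_typed={"input", "output"},
            secret={"token"})
        store.save_filled(stream_or_save, b, "secret run")
        for path in store.root.rglob("*"):
            if path.is_file():
                assert "s3same" not in path.read_text(encoding="utf-8")
        assert "token" not in store.load_filled("secret run").bindings

    def test_content_hash_tracks_the_template_text(self, store,
                                                   stream_or_save):
        store.register_template(stream_or_save)
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "f", "os": True, "output": "o"})
        first = store.save_filled(stream_or_save, b, "a")
        changed = dsl.parse_template(
            STREAM_OR_SAVE_XML.replace("55025", "55026"))
        store.register_template(changed)
        second = store.save_filled(changed, b, "b")
        assert first.content_hash != second.content_hash


class TestManifest:
    def test_manifest_is_valid_json_with_ordered_entries(
            self, store, stream_or_save):
        store.register_template(stream_or_save)
        store.register_module("m1", "#!/bin/sh\n")
        doc = json.loads(store.manifest_path.read_text(encoding="utf-8"))
        assert [e["id"] for e in doc["entries"]] \
            == [stream_or_save.id, "m1"]

    def test_corrupt_manifest_surfaces_store_error(self, store):
        store.manifest_path.write_text("{broken", encoding="utf-8")
        with pytest.raises(StoreError, match="manifest"):
            store.entries()
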