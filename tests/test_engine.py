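"""Engine: bindings, substitution, network building, token evaluation
and command assembly, checked against a naive recursive oracle."""

import os
import random

import pytest

from guiforge import dsl, engine
from guiforge.dsl import AddNode, ConstNode, EnvNode, ExecuteNode, IfNode, Param
from guiforge.errors import BindingError, EvaluationError, SubstitutionError
from guiforge.randgen import random_bindings, random_network_template

from conftest import naive_assemble, naive_evaluate

ENV = {"os": "Linux", "ip": "192.168.1.100", "home": "/home/u",
       "tmp": "/tmp", "appdir": "/app"}


class TestCollectBindings:
    def test_checked_group_renders_true(self, stream_or_save):
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": True, "output": "o"})
        assert b["os"] == "TRUE"

    def test_unchecked_group_renders_false(self, stream_or_save):
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": False, "output": "o"})
        assert b["os"] == "FALSE"

    def test_filedialog_value_flagged_path_typed(self, stream_or_save):
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": True, "output": "o"})
        assert b["input"] == "inputFile"
        assert "input" in b.path_typed and "output" in b.path_typed
        assert "os" not in b.path_typed

    def test_defaults_fill_gaps(self, rich_template):
        b = engine.collect_bindings(rich_template.window, {"reads": "r.fq"})
        assert b["threads"] == "4"
        assert b["verbose"] == "FALSE"
        assert b["preset"] == "fast"

    def test_missing_value_without_default_names_the_id(
            self, stream_or_save):
        with pytest.raises(BindingError, match="input"):
            engine.collect_bindings(stream_or_save.window,
                                    {"os": False, "output": "o"})

    def test_bad_boolean_rejected(self, stream_or_save):
        with pytest.raises(BindingError):
            engine.collect_bindings(
                stream_or_save.window,
                {"input": "f", "os": "maybe", "output": "o"})


class TestSubstitute:
    @pytest.mark.parametrize("text, expected", [
        ("no refs", "no refs"),
        ("cat ${input}", "cat inputFile"),
        ("$${input}", "${input}"),
        ("a$$b", "a$b"),
        ("$5 literal", "$5 literal"),
        ("${input}${input}", "inputFileinputFile"),
    ])
    def test_substitution_grammar(self, text, expected):
        resolve = {"input": "inputFile"}.__getitem__
        assert engine.substitute(text, resolve) == expected

    def test_unterminated_reference_raises(self):
        with pytest.raises(SubstitutionError, match="unterminated"):
            engine.substitute("cat ${input", lambda i: "x")

    def test_invalid_identifier_raises(self):
        with pytest.raises(SubstitutionError, match="identifier"):
            engine.substitute("${9bad}", lambda i: "x")


class TestBuildNetwork:
    def test_const_feeding_add(self):
        model = (ConstNode(id="c", value="x"),
                 AddNode(id="a", parts=("${c}",)),
                 ExecuteNode(id="run", program="echo",
                             params=(Param(text="${a}"),)))
        net = engine.build_network(model)
        assert set(net.places) == {"c", "a", "run"}
        assert net.places["a"].inputs == ("c",)

    def test_shared_node_single_place_out_degree_two(self):
        model = (ConstNode(id="c", value="x"),
                 AddNode(id="a1", parts=("${c}",)),
                 AddNode(id="a2", parts=("${c}",)),
                 ExecuteNode(id="run", program="echo",
                             params=(Param(text="${a1} ${a2}"),)))
        net = engine.build_network(model)
        assert sum(1 for p in net.places.values() if p.id == "c") == 1
        assert net.out_degree("c") == 2

    def test_sink_is_the_execute_node(self, stream_or_save):
        net = engine.build_network(stream_or_save.execution)
        assert [s.program for s in net.sinks] == ["sh"]

    def test_cycle_rechecked_at_build_time(self):
        model = (AddNode(id="a", parts=("${b}",)),
                 AddNode(id="b", parts=("${a}",)),
                 ExecuteNode(id="run", program="echo",
                             params=(Param(text="${a}"),)))
        with pytest.raises(EvaluationError, match="cycle"):
            engine.build_network(model)


class TestEvaluateNode:
    def _eval(self, model, ident, bindings=None):
        net = engine.build_network(tuple(model))
        b = engine.InputBindings(values=bindings or {})
        return engine.evaluate_reference(net, ident, b, ENV)

    def test_const_literal(self):
        assert self._eval([ConstNode(id="c", value="-a ")], "c") == "-a "

    def test_add_concatenates_in_order(self):
        model = [AddNode(id="a",
                         parts=("netcat ", "192.168.1.100", " 55025"))]
        assert self._eval(model, "a") == "netcat 192.168.1.100 55025"

    def test_add_separator(self):
        model = [AddNode(id="a", sep=",", parts=("x", "y", "z"))]
        assert self._eval(model, "a") == "x,y,z"

    def test_env_lookup(self):
        assert self._eval([EnvNode(id="e", key="os")], "e") == "Linux"

    def test_env_unknown_key_errors(self):
        with pytest.raises(EvaluationError, match="nope"):
            self._eval([EnvNode(id="e", key="nope")], "e")

    def test_if_without_else_defaults_to_empty(self):
        model = [IfNode(id="i", probe="${os_flag}", equals="TRUE",
                        then="yes")]
        assert self._eval(model, "i", {"os_flag": "FALSE"}) == ""

    def test_if_comparison_is_case_sensitive(self):
        model = [IfNode(id="i", probe="${x}", equals="TRUE", then="y",
                        els="n")]
        assert self._eval(model, "i", {"x": "true"}) == "n"


class TestAssemble:
    def test_worked_example_checked(self, stream_or_save):
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": True, "output": "/tmp/out.txt"})
        (inv,) = engine.assemble_invocation(stream_or_save, b, env=ENV)
        assert inv.program == "sh"
        assert inv.argument_text == \
            '-c "cat inputFile | netcat 192.168.1.100 55025"'

    def test_worked_example_unchecked(self, stream_or_save):
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "inputFile", "os": False, "output": "/tmp/out.txt"})
        (inv,) = engine.assemble_invocation(stream_or_save, b, env=ENV)
        assert inv.argument_text == '-c "cat inputFile | tee -a /tmp/out.txt"'

    def test_shared_node_fires_exactly_once(self):
        model = (ConstNode(id="c", value="x"),
                 AddNode(id="a1", parts=("${c}",)),
                 AddNode(id="a2", parts=("${c}${c}",)),
                 ExecuteNode(id="run", program="echo",
                             params=(Param(text="${a1} ${a2} ${c}"),)))
        t = dsl.Template(id="t", window=dsl.WindowElement(kind="group"),
                         execution=model)
        trace = {}
        engine.assemble_invocation(
            t, engine.InputBindings(), env=ENV, trace=trace)
        assert trace["c"] == 1

    def test_rich_template_with_script_and_env(self, rich_template):
        b = engine.collect_bindings(rich_template.window,
                                    {"reads": "reads.fq", "verbose": True})
        (inv,) = engine.assemble_invocation(rich_template, b, env=ENV)
        assert inv.program == "hisat2"
        assert inv.argument_text == (
            "-p 4 --preset fast --verbose -x genome -U reads.fq "
            "--un /home/u/unaligned.fq")

    def test_empty_params_are_dropped(self, rich_template):
        b = engine.collect_bindings(rich_template.window,
                                    {"reads": "reads.fq"})
        (inv,) = engine.assemble_invocation(rich_template, b, env=ENV)
        assert "--verbose" not in inv.argument_text
        assert "  " not in inv.argument_text

    def test_determinism_across_runs(self, rich_template):
        b = engine.collect_bindings(rich_template.window,
                                    {"reads": "r.fq"})
        first = engine.assemble_invocation(rich_template, b, env=ENV)
        second = engine.assemble_invocation(rich_template, b, env=ENV)
        assert [(i.program, i.args) for i in first] == \
            [(i.program, i.args) for i in second]

    def test_assembly_is_pure_no_files_or_processes(
            self, stream_or_save, tmp_path, monkeypatch):
        """Assembly must not touch the filesystem or spawn anything."""
        import subprocess

        monkeypatch.chdir(tmp_path)

        def forbidden(*a, **k):  # pragma: no cover - should not run
            raise AssertionError("assembly spawned a process")

        monkeypatch.setattr(subprocess, "Popen", forbidden)
        monkeypatch.setattr(os, "system", forbidden)
        b = engine.collect_bindings(
            stream_or_save.window,
            {"input": "f", "os": True, "output": "o"})
        engine.assemble_invocation(stream_or_save, b, env=ENV)
        assert list(tmp_path.iterdir()) == []


class TestOracleEquivalence:
    def test_memoized_equals_naive_recursive_on_random_networks(self):
        """Exact agreement with re-evaluating recursion on 120 seeded
        random acyclic networks of up to 30 const/add/if/env nodes."""
        rng = random.Random(20240001)
        for _ in range(120):
            t = random_network_template(rng)
            assert dsl.validate_template(t) == []
            raw = random_bindings(rng, t)
            b = engine.collect_bindings(t.window, raw)
            got = [(i.program, i.argument_text)
                   for i in engine.assemble_invocation(t, b, env=ENV)]
            assert got == naive_assemble(t, b, ENV)

    def test_every_identified_node_agrees_with_oracle(self):
        rng = random.Random(7)
        t = random_network_template(rng)
        raw = random_bindings(rng, t)
        b = engine.collect_bindings(t.window, raw)
        net = engine.build_network(t.execution, known_inputs=set(b.values))
        for node in t.execution:
            if node.id and not isinstance(node, ExecuteNode):
                assert engine.evaluate_reference(net, node.id, b, ENV) \
                    == naive_evaluate(t, b, ENV, node.id)
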