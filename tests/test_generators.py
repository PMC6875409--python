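"""Generators: widget mapping, CliSpec -> template, CWL ingestion."""

import random

import pytest

from guiforge import dsl, engine, generators
from guiforge.generators import CliInput, CliSpec
from guiforge.errors import GeneratorError
from guiforge.randgen import random_cli_spec

ENV = {"os": "Linux", "ip": "1.2.3.4", "home": "/home/u"}

WC_CWL = """\
cwlVersion: v1.2
class: CommandLineTool
baseCommand: wc
doc: Count bytes in a file
inputs:
  f:
    type: File
    doc: the file to measure
    inputBinding:
      prefix: -c
outputs: []
"""

GREP_CWL = """\
cwlVersion: v1.0
class: CommandLineTool
baseCommand: [grep]
inputs:
  - id: pattern
    type: string
    inputBinding:
      position: 1
  - id: ignore_case
    type: boolean?
    inputBinding:
      prefix: -i
  - id: infile
    type: File
    inputBinding:
      position: 2
  - id: mode
    type:
      type: enum
      symbols: [fixed, extended]
    inputBinding:
      prefix: --mode
outputs: []
"""

RECORD_CWL = """\
cwlVersion: v1.1
class: CommandLineTool
baseCommand: tool
inputs:
  complex:
    type:
      type: record
      fields: []
  plain:
    type: string?
    inputBinding:
      prefix: --plain
outputs: []
"""

CWL_FIXTURES = [WC_CWL, GREP_CWL, RECORD_CWL]


def assemble(template, raw):
    bindings = engine.collect_bindings(template.window, raw)
    return engine.assemble_invocation(template, bindings, env=ENV)


class TestWidgetFor:
    @pytest.mark.parametrize("value_type, kind", [
        ("boolean", "checkbox"),
        ("file", "filedialog"),
        ("directory", "filedialog"),
        ("choice", "combobox"),
        ("integer", "textinput"),
        ("float", "textinput"),
        ("string", "textinput"),
        ("unknown", "textinput"),
        ("something-new", "textinput"),  # total fallback
    ])
    def test_mapping(self, value_type, kind):
        assert generators.widget_for(value_type) == kind


class TestFromCliSpec:
    def test_single_positional_pass_through(self):
        spec = CliSpec(tool_name="echoer", base_command=("echo",),
                       inputs=(CliInput(name="msg", value_type="string",
                                        required=True, position=1),))
        t = generators.from_cli_spec(spec)
        assert dsl.validate_template(t) == []
        (inv,) = assemble(t, {"msg": "hi"})
        assert inv.program == "echo"
        assert inv.argument_text == "hi"

    def test_boolean_gating(self):
        spec = CliSpec(tool_name="t", base_command=("tool",),
                       inputs=(CliInput(name="verbose",
                                        value_type="boolean",
                                        flag="--verbose"),))
        t = generators.from_cli_spec(spec)
        (checked,) = assemble(t, {"verbose": True})
        assert "--verbose" in checked.argument_text
        (unchecked,) = assemble(t, {"verbose": False})
        assert "--verbose" not in unchecked.argument_text

    def test_flagged_value_emits_flag_plus_value(self):
        spec = CliSpec(tool_name="t", base_command=("tool",),
                       inputs=(CliInput(name="out", value_type="file",
                                        flag="-o", required=True),))
        t = generators.from_cli_spec(spec)
        (inv,) = assemble(t, {"out": "result.txt"})
        assert inv.argument_text == "-o result.txt"

    def test_optional_flag_suppressed_when_empty(self):
        spec = CliSpec(tool_name="t", base_command=("tool",),
                       inputs=(CliInput(name="extra", value_type="string",
                                        flag="--extra", required=False),))
        t = generators.from_cli_spec(spec)
        (inv,) = assemble(t, {})
        assert inv.argument_text == ""
        (filled,) = assemble(t, {"extra": "x"})
        assert filled.argument_text == "--extra x"

    def test_positionals_ordered_by_position(self):
        spec = CliSpec(tool_name="t", base_command=("cp",),
                       inputs=(
                           CliInput(name="dest", value_type="file",
                                    required=True, position=2),
                           CliInput(name="src", value_type="file",
                                    required=True, position=1),
                       ))
        t = generators.from_cli_spec(spec)
        (inv,) = assemble(t, {"src": "a", "dest": "b"})
        assert inv.argument_text == "a b"

    def test_base_command_extras_become_leading_params(self):
        spec = CliSpec(tool_name="t", base_command=("python", "-m", "tool"),
                       inputs=(CliInput(name="n", value_type="integer",
                                        required=True, position=1),))
        t = generators.from_cli_spec(spec)
        (inv,) = assemble(t, {"n": "3"})
        assert inv.program == "python"
        assert inv.argument_text == "-m tool 3"

    def test_subcommands_gated_by_combobox(self):
        spec = CliSpec(
            tool_name="multi", base_command=("multi",),
            subcommands=(
                CliSpec(tool_name="index", base_command=("x",),
                        inputs=(CliInput(name="genome", value_type="file",
                                         flag="-g", required=True),)),
                CliSpec(tool_name="align", base_command=("x",),
                        inputs=(CliInput(name="reads", value_type="file",
                                         flag="-r", required=True),)),
            ))
        t = generators.from_cli_spec(spec)
        assert dsl.validate_template(t) == []
        raw = {"subcommand": "index", "index_genome": "g.fa",
               "align_reads": "r.fq"}
        (inv,) = assemble(t, raw)
        assert inv.argument_text == "index -g g.fa"
        raw["subcommand"] = "align"
        (inv,) = assemble(t, raw)
        assert inv.argument_text == "align -r r.fq"

    def test_duplicate_names_rejected(self):
        spec = CliSpec(tool_name="t", base_command=("t",),
                       inputs=(CliInput(name="a"), CliInput(name="a")))
        with pytest.raises(GeneratorError, match="duplicate"):
            generators.from_cli_spec(spec)

    def test_generated_template_has_action_and_output(self):
        t = generators.from_cli_spec(
            CliSpec(tool_name="t", base_command=("t",),
                    inputs=(CliInput(name="a"),)))
        kinds = [e.kind for e in t.window_elements()]
        assert kinds.count("actionbutton") == 1
        assert kinds.count("textoutput") == 1


class TestGeneratorProperties:
    def test_totality_on_seeded_random_specs(self):
        """50 seeded random specs: the template validates cleanly, has
        exactly one bindable widget per input, and its assembly with
        all-required bindings mentions every required flag."""
        rng = random.Random(20240003)
        for _ in range(50):
            spec = random_cli_spec(rng)
            t = generators.from_cli_spec(spec)
            assert dsl.validate_template(t) == []
            schema = dsl.to_form_schema(t)
            assert len(schema.binding_keys()) == len(spec.inputs)
            raw = {}
            for inp in spec.inputs:
                if inp.value_type == "boolean":
                    raw[inp.name] = "TRUE"
                elif inp.value_type == "choice":
                    raw[inp.name] = inp.options[0]
                else:
                    raw[inp.name] = "v"
            (inv,) = assemble(t, raw)
            for inp in spec.inputs:
                if inp.required and inp.flag:
                    assert inp.flag in inv.argument_text

    def test_fallback_widening_keeps_the_widget(self):
        rng = random.Random(5)
        spec = random_cli_spec(rng)
        widened = CliSpec(
            tool_name=spec.tool_name,
            base_command=spec.base_command,
            inputs=tuple(
                CliInput(name=i.name, value_type="unknown", flag=i.flag,
                         required=i.required, position=i.position)
                for i in spec.inputs))
        t = generators.from_cli_spec(widened)
        schema = dsl.to_form_schema(t)
        assert len(schema.binding_keys()) == len(spec.inputs)
        bindables = [e for e in t.window_elements() if e.bindable]
        assert all(e.kind == "textinput" for e in bindables)


class TestFromCwl:
    def test_file_input_with_prefix(self):
        spec = generators.from_cwl(WC_CWL)
        assert spec.base_command == ("wc",)
        assert len(spec.inputs) == 1
        inp = spec.inputs[0]
        assert inp.value_type == "file"
        assert inp.flag == "-c"
        assert inp.required
        assert "measure" in inp.help

    def test_list_style_inputs_with_types(self):
        spec = generators.from_cwl(GREP_CWL)
        by_name = {i.name: i for i in spec.inputs}
        assert by_name["pattern"].position == 1
        assert by_name["ignore_case"].value_type == "boolean"
        assert not by_name["ignore_case"].required
        assert by_name["mode"].value_type == "choice"
        assert by_name["mode"].options == ("fixed", "extended")

    def test_record_type_falls_back_to_text_input(self):
        spec = generators.from_cwl(RECORD_CWL)
        by_name = {i.name: i for i in spec.inputs}
        assert by_name["complex"].value_type == "unknown"
        t = generators.from_cli_spec(spec)
        widget = next(e for e in t.window_elements()
                      if e.id == "complex")
        assert widget.kind == "textinput"

    def test_workflow_class_rejected(self):
        with pytest.raises(GeneratorError, match="Workflow"):
            generators.from_cwl("class: Workflow\ncwlVersion: v1.0\n")

    def test_missing_class_rejected(self):
        with pytest.raises(GeneratorError, match="class"):
            generators.from_cwl("cwlVersion: v1.0\ninputs: {}\n")

    def test_missing_inputs_yields_empty_spec_with_note(self):
        spec = generators.from_cwl(
            "class: CommandLineTool\ncwlVersion: v1.0\nbaseCommand: ls\n")
        assert spec.inputs == ()
        assert any("inputs" in n for n in spec.notes)

    @pytest.mark.parametrize("doc", CWL_FIXTURES)
    def test_composition_validates_and_covers_required_flags(self, doc):
        spec = generators.from_cwl(doc)
        t = generators.from_cli_spec(spec)
        assert dsl.validate_template(t) == []
        raw = {i.name: (i.options[0] if i.value_type == "choice" else "v")
               for i in spec.inputs if i.value_type != "boolean"}
        (inv,) = assemble(t, raw)
        for inp in spec.inputs:
            if inp.required and inp.flag:
                assert inp.flag in inv.argument_text


class TestCliSpecJson:
    def test_round_trip_through_neutral_json(self):
        text = """{
          "toolName": "demo",
          "baseCommand": ["demo"],
          "inputs": [
            {"name": "f", "valueType": "file", "flag": "-f",
             "required": true},
            {"name": "v", "valueType": "boolean", "flag": "-v"}
          ]
        }"""
        spec = generators.load_cli_spec(text)
        assert spec.tool_name == "demo"
        assert spec.inputs[0].value_type == "file"
        t = generators.from_cli_spec(spec)
        assert dsl.validate_template(t) == []

    def test_malformed_json_rejected(self):
        with pytest.raises(GeneratorError, match="JSON|parse"):
            generators.load_cli_spec("{not json")

    def test_input_without_name_rejected(self):
        with pytest.raises(GeneratorError, match="name"):
            generators.load_cli_spec(
                '{"toolName": "x", "inputs": [{"flag": "-a"}]}')
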