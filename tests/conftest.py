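"""Shared fixtures: hand-written template documents, install-module
scripts and independent oracles used across the suite."""

from __future__ import annotations

import re
import textwrap
from pathlib import Path

import pytest

from guiforge import dsl

# The stream-or-save example: a file is either piped over the network
# (group box checked) or appended to an output file.
STREAM_OR_SAVE_XML = """\
<template id="stream-or-save" title="Stream or save a file"
          description="Pipe a file over the network or tee it to disk">
  <window>
    <label>Select the input file</label>
    <filedialog id="input" label="Input file" mode="open"/>
    <group id="os" title="Send over network" checkable="true">
      <filedialog id="output" label="Output file" mode="save"/>
    </group>
    <action>Run</action>
    <streambox/>
  </window>
  <execution>
    <if id="sink" probe="${os}" equals="TRUE">
      <then>netcat 192.168.1.100 55025</then>
      <else>tee -a ${output}</else>
    </if>
    <execute program="sh">
      <param>-c</param>
      <param>"cat ${input} | ${sink}"</param>
    </execute>
  </execution>
</template>
"""

MINIMAL_XML = """\
<template id="minimal" title="Minimal">
  <window>
    <filedialog id="input" label="Input" mode="open"/>
    <action>Go</action>
  </window>
  <execution>
    <execute program="cat">
      <param>${input}</param>
    </execute>
  </execution>
</template>
"""

# an aligner front-end exercising const/add/env/script nodes together
RICH_XML = """\
<template id="aligner" title="Short-read aligner">
  <window>
    <label>Alignment settings</label>
    <input id="threads" label="Threads" default="4"/>
    <filedialog id="reads" label="Reads (FASTQ)" mode="open"/>
    <input id="index" label="Index file" default="genome.1.ht2"/>
    <checkbox id="verbose" label="Verbose output" default="FALSE"/>
    <combobox id="preset" label="Preset" default="fast">
      <option>fast</option>
      <option>sensitive</option>
    </combobox>
    <action>Align</action>
    <streambox/>
  </window>
  <execution>
    <const id="prog">hisat2</const>
    <script id="index_base" argv="${index}"><![CDATA[
function evaluate(arg1)
    if (string.match(arg1, ".%d.ht2$")) then
      return(string.sub(arg1, 0, arg1:find(".%d.ht2$")-1))
    end
   return(arg1)
  end
]]></script>
    <if id="vflag" probe="${verbose}" equals="TRUE">
      <then>--verbose</then>
    </if>
    <add id="threadopt" sep=" "><const>-p</const>${threads}</add>
    <env id="homedir" key="home"/>
    <execute program="${prog}">
      <param>${threadopt}</param>
      <param>--preset ${preset}</param>
      <param>${vflag}</param>
      <param>-x ${index_base}</param>
      <param>-U ${reads}</param>
      <param>--un ${homedir}/unaligned.fq</param>
    </execute>
  </execution>
</template>
"""

LISTING1_SOURCE = """\
function evaluate(arg1)
    if (string.match(arg1, ".%d.ht2$")) then
      return(string.sub(arg1, 0, arg1:find(".%d.ht2$")-1))
    end
   return(arg1)
  end
"""


@pytest.fixture
def stream_or_save():
    return dsl.parse_template(STREAM_OR_SAVE_XML)


@pytest.fixture
def minimal_template():
    return dsl.parse_template(MINIMAL_XML)


@pytest.fixture
def rich_template():
    return dsl.parse_template(RICH_XML)


@pytest.fixture(params=["stream_or_save", "minimal", "rich"])
def any_fixture_xml(request):
    return {"stream_or_save": STREAM_OR_SAVE_XML,
            "minimal": MINIMAL_XML,
            "rich": RICH_XML}[request.param]


# ---------------------------------------------------------------------------
# independent oracles


def naive_evaluate(template, bindings, env, ident):
    """Reference evaluator: plain recursion over the node definitions,
    re-evaluating on every reference, with its own substitution. Kept
    free of the engine's network/memoization machinery on purpose."""
    nodes = {}
    for node in template.execution:
        for sub in dsl.iter_subnodes(node):
            if sub.id is not None:
                nodes[sub.id] = sub

    def subst(text):
        out = []
        i = 0
        while i < len(text):
            if text.startswith("$$", i):
                out.append("$")
                i += 2
            elif text.startswith("${", i):
                j = text.index("}", i)
                out.append(resolve(text[i + 2:j]))
                i = j + 1
            else:
                out.append(text[i])
                i += 1
        return "".join(out)

    def resolve(name):
        if name in nodes:
            return eval_node(nodes[name])
        return bindings.values[name]

    def eval_part(part):
        if isinstance(part, str):
            return subst(part)
        return eval_node(part)

    def eval_node(node):
        if isinstance(node, dsl.ConstNode):
            return node.value
        if isinstance(node, dsl.AddNode):
            return node.sep.join(eval_part(p) for p in node.parts)
        if isinstance(node, dsl.EnvNode):
            return env[node.key]
        if isinstance(node, dsl.IfNode):
            if subst(node.probe) == node.equals:
                return eval_part(node.then)
            return eval_part(node.els) if node.els is not None else ""
        raise AssertionError(f"oracle cannot evaluate {node}")

    return resolve(ident)


def naive_assemble(template, bindings, env):
    """Reference assembly of each execute node's argument text."""
    results = []
    for node in template.execute_nodes():
        args = []
        for param in node.params:
            value = naive_evaluate_text(template, bindings, env, param.text)
            if param.quote:
                value = ('"' + value.replace("\\", "\\\\")
                         .replace('"', '\\"') + '"')
            if value != "":
                args.append(value)
        program = naive_evaluate_text(template, bindings, env, node.program)
        results.append((program, " ".join(args)))
    return results


def naive_evaluate_text(template, bindings, env, text):
    marker = "___oracle_text___"
    fake = dsl.AddNode(id=marker, parts=(text,))
    patched = dsl.Template(
        id=template.id, title=template.title,
        window=template.window,
        execution=template.execution + (fake,))
    return naive_evaluate(patched, bindings, env, marker)


# ---- dialect-pattern reference interpreter -------------------------

_CLASS_TO_RE = {"d": r"\d", "a": "[a-zA-Z]", "l": "[a-z]", "u": "[A-Z]",
                "w": "[a-zA-Z0-9]", "s": r"[ \t\n\r\f\v]"}


def pattern_to_regex(pattern: str) -> str:
    """Translate a restricted dialect pattern (literals, ``.``, ``%d``
    and friends, ``* + - ?`` quantifiers, ``^``/``$`` anchors) to a
    Python regex.  Independent of the package's matcher."""
    out = []
    i = 0
    if pattern.startswith("^"):
        out.append("^")
        i = 1
    while i < len(pattern):
        c = pattern[i]
        if c == "$" and i == len(pattern) - 1:
            out.append(r"\Z")
            i += 1
            continue
        if c == "%":
            cls = pattern[i + 1]
            piece = _CLASS_TO_RE.get(cls, re.escape(cls))
            i += 2
        elif c == ".":
            piece = "."
            i += 1
        else:
            piece = re.escape(c)
            i += 1
        if i < len(pattern) and pattern[i] in "*+-?":
            quant = pattern[i]
            piece += {"*": "*", "+": "+", "-": "*?", "?": "?"}[quant]
            i += 1
        out.append(piece)
    return "".join(out)


def reference_match_span(s: str, pattern: str):
    """1-based inclusive leftmost span per the reference translation."""
    m = re.search(pattern_to_regex(pattern), s)
    if m is None:
        return None
    return (m.start() + 1, m.end())


# ---------------------------------------------------------------------------
# install-module fixtures


ECHO_MODULE = textwrap.dedent("""\
    #!/bin/sh
    # synthetic install module used for contract tests
    echo "ARG1=$1"
    echo "ARG2=$2"
    echo "ARG3=$3"
    shift 3
    for extra in "$@"; do
      echo "EXTRA=$extra"
    done
    """)

TEMPLATE_MODULE = textwrap.dedent("""\
    #!/bin/sh
    # synthetic install module: installs a marker file and ships its
    # template on stdout
    installdir="$1"
    mkdir -p "$installdir"
    echo "installed" > "$installdir/tool.txt"
    cat <<'EOT'
    ### BIOGUI-TEMPLATE-BEGIN
    <template id="echo-tool" title="Echo tool">
      <window>
        <input id="message" label="Message" default="hi"/>
        <action>Run</action>
      </window>
      <execution>
        <execute program="echo">
          <param>${message}</param>
        </execute>
      </execution>
    </template>
    ### BIOGUI-TEMPLATE-END
    EOT
    """)

FAILING_MODULE = "#!/bin/sh\nexit 1\n"


@pytest.fixture
def module_script(tmp_path):
    def write(name: str, content: str) -> Path:
        path = tmp_path / name
        path.write_text(content, encoding="utf-8")
        path.chmod(0o755)
        return path

    return write
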