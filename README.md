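# guiforge

Deterministic assembly of command-line invocations from declarative XML
templates, aimed at making bioinformatics tools usable (and re-runnable)
without writing a wrapper per tool.

## The problem

Most bioinformatics software ships as a command-line program with tens
of flags, unix-only path conventions and no interface beyond `--help`.
Wrapping each tool by hand in a GUI or web form does not scale, and
ad-hoc wrappers rarely record *how* a command line was produced, which
makes runs hard to reproduce or audit. guiforge separates the two
concerns declaratively: one XML document describes **what to ask the
user** (a window model: text inputs, file dialogs, checkable group
boxes, combo boxes) and **how to turn the answers into a command** (an
execution model: a dataflow graph of `const`/`add`/`env`/`if`/`script`
nodes feeding `execute` nodes). The library is fully headless — the
window model is exported as a neutral form schema, values are bound
programmatically or from the CLI, and command assembly is a pure,
deterministic function of (template, bindings, environment). That
purity is what makes every assembled invocation reproducible and
testable string-for-string.

Around this core the package provides:

- **Execution backends** — run the assembled command natively, inside
  WSL (with automatic `C:\...` ↔ `/mnt/c/...` path translation for
  path-typed values), over ssh or a raw stream, via an HTTP POST of the
  form values, or inside a Docker container.
- **An embedded scripting dialect** — templates may compute derived
  values (e.g. stripping `genome.1.ht2` to the index basename `genome`)
  in a sandboxed Lua-style `evaluate` function with its own pattern
  matcher; no file, process or network access, bounded steps and time.
- **Template generators** — build templates mechanically from a CWL
  `CommandLineTool` description or a neutral JSON CLI spec; every input
  maps to a widget (unknown types fall back to a text input) so
  generation is total.
- **Install modules** — shell scripts with a fixed positional contract
  `script INSTALL_DIR ADD_TO_PATH SUDO_PASSWORD [EXTRA...]` that can
  ship the installed tool's template between marker lines.
- **A local template store** — register templates and modules, search
  them, save filled templates (bindings minus secrets) and reassemble
  saved runs bit-exactly later.

## Worked example

`stream.xml` asks for an input file and, via a checkable group box,
whether to stream it over the network or append it to a local file:

```xml
<template id="stream-or-save" title="Stream or save a file">
  <window>
    <label>Choose an input and a destination</label>
    <filedialog id="input" label="Input file" mode="open"/>
    <group id="os" title="Send over network" checkable="true">
      <filedialog id="output" label="Save to" mode="save"/>
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
      <param quote="shell">cat ${input} | ${sink}</param>
    </execute>
  </execution>
</template>
```

Validate it and list what must be bound:

```console
$ forge validate stream.xml
stream.xml: OK
$ forge schema stream.xml
input
os
output
```

Assemble the command in both group-box states (`--dry-run` prints the
invocation instead of executing it):

```console
$ forge run stream.xml --dry-run --set input=inputFile \
      --set os=TRUE --set output=/tmp/out.txt
sh -c "cat inputFile | netcat 192.168.1.100 55025"
$ forge run stream.xml --dry-run --set input=inputFile \
      --set os=FALSE --set output=/tmp/out.txt
sh -c "cat inputFile | tee -a /tmp/out.txt"
```

The checkbox binding renders as the string `TRUE`/`FALSE`, the `if`
node switches the sink, and the quoted parameter is substituted and
shell-quoted — the whole pipeline is a pure string computation until
the moment a backend actually executes it.

Save the filled template and replay it later, bit-exactly:

```console
$ forge save-run stream.xml --values v.json --label nightly --store .forge-store
saved run 'nightly'
$ forge rerun nightly --dry-run --store .forge-store
sh -c "cat inputFile | netcat 192.168.1.100 55025"
$ forge list --store .forge-store
stream-or-save	template	Stream or save a file
```

The same operations are available as a library (`guiforge.dsl`,
`guiforge.engine`, `guiforge.backends`, `guiforge.generators`,
`guiforge.install`, `guiforge.store`).

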