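# Methods

## Model

A *template* is a single XML document with two parts sharing one id
namespace:

- The **window model** is a tree of widgets — `label`, `input`
  (text), `checkbox`, `filedialog`, `combobox`, checkable `group`,
  `action` (run button), `streambox`/`textoutput`. Every widget with an
  `id` contributes a *binding*: the string value collected for that id.
  Booleans render exactly `TRUE`/`FALSE`; a checkable group behaves as
  a boolean whose children stay bindable regardless of its state.
  Because the package is headless, the window model is exported as a
  neutral *form schema* (ordered entries with kind, label, default,
  path-typedness) instead of being rendered; anything that can collect
  strings against that schema is a valid front-end.

- The **execution model** is a list of dataflow nodes: `const`
  (literal), `add` (ordered concatenation with an optional separator),
  `env` (injected environment lookup: OS name, IP, home, temp and
  application directories), `if` (string-exact, case-sensitive
  comparison of a probe against `equals`, with an optional `else`
  defaulting to the empty string), `script` (a sandboxed embedded
  function, below), and one or more `execute` sinks holding a program
  and ordered `param` children. Text anywhere in the execution model
  may reference ids with `${id}` (identifier grammar
  `[A-Za-z_][A-Za-z0-9_]*`; `$$` escapes a literal dollar; a lone `$`
  is literal; an unterminated `${` is an error). References may point
  at window bindings or at other nodes; the document validates only if
  the reference graph is acyclic and all ids resolve.

## Evaluation semantics

Assembly is modelled like a petri net: each identified node is a place,
and a node may fire only once all of its input places hold a token.
Operationally this is memoized topological evaluation — during one
assembly each node is evaluated exactly once and its token (a string)
is reused by every consumer. Since all node functions are pure, the
memoized result provably equals naive recursive re-evaluation; the test
suite checks that equivalence against an independent re-evaluating
oracle on randomized acyclic networks rather than trusting the
implementation. Assembly itself is a pure function: no file, process or
network side effect occurs until a backend executes the finished
invocation, and empty evaluated parameters are dropped so optional
flags vanish without leaving double spaces.

## Embedded scripting

`script` nodes supply derived values through an `evaluate(args...)`
function written in a small Lua-style dialect. The host passes the
node's `argv` (after substitution) as string arguments and takes the
function's **last** returned value, coercing booleans to
`TRUE`/`FALSE` and numbers to their canonical text. The interpreter is
implemented in-package (lexer, recursive-descent parser, tree-walking
evaluator) and supports functions, locals, `if`/`while`/`repeat`/
numeric `for`, tables, multiple return values, method-call sugar and
the string/math libraries, including the dialect's own pattern syntax
(`%d`-style classes with uppercase complements, sets and ranges,
`* + - ?` quantifiers, anchors and captures; `%b`, `%f` and
back-references are rejected up front). Sandboxing is by omission plus
denial: `io`, `os`, `require`, `dofile` and friends raise a sandbox
error, and every script runs under a step budget and a wall-clock cap
so a runaway loop cannot stall assembly.

## Backends and path translation

A backend descriptor turns an invocation into a *runnable* without
executing anything: native (`sh -c`), WSL (`wsl.exe bash -c`), remote
over ssh or a raw stream listener, HTTP (a POST form of the non-secret
bindings), or Docker (`docker run` with mounts). For the WSL backend,
values of *path-typed* bindings (file dialogs, install directories) are
rewritten between `X:\a\b` and `/mnt/x/a/b`; translation applies only
to those values, never to arbitrary text that merely looks like a
path. Execution streams stdout and stderr line-by-line with channel
tags, preserves per-channel order, and reports exit status, timeout
and not-found conditions explicitly.

## Generators

A neutral `CliSpec` (tool name, base command, typed inputs, optional
subcommands) maps mechanically to a template: booleans become
checkboxes gated by an `if` on `TRUE`; file/directory inputs become
file dialogs; enumerations become combo boxes; everything else —
including unknown types — becomes a text input, which makes generation
total. Required flags emit `flag ${value}`; optional flags are wrapped
in an `if` that collapses to nothing when the value is empty;
positionals are ordered by position; subcommands are selected by a
combo box whose value gates each subcommand's argument group. CWL
`CommandLineTool` documents (v1.x) are first normalized into a
`CliSpec` (`File`→file, `boolean`→boolean, `enum`→choice, `T?` and
`["null", T]` optional, records/arrays→unknown; `prefix` and
`position` from the input binding; `doc`/`label` as help); `Workflow`
documents are rejected, and ignored sections are reported as notes.

## Install modules and the store

An install module is a shell script invoked with the fixed positional
contract `script INSTALL_DIR ADD_TO_PATH SUDO_PASSWORD [EXTRA...]`,
where the flag renders `TRUE`/`FALSE`, the password slot stays present
(empty) when unused so extras never shift, and declared extras come
strictly last in order. The runner uses direct argv execution (not a
shell string) precisely so the empty password slot survives; the
password is additionally exported as `FORGE_SUDO_PASSWORD`, flagged
secret, and masked in all representations. A module may embed its
tool's template between `### BIOGUI-TEMPLATE-BEGIN`/`-END` markers in
its body or its output; after a successful run the template is
registered in the store.

The store is a plain directory: an ordered `manifest.json` plus
`templates/`, `modules/` and `filled/`. Registration is idempotent per
id, search is a case-insensitive substring match over name and
description, and a saved filled template records the template id, a
content hash of its canonical XML, and the non-secret bindings —
enough to reassemble the original invocation string-exactly, which the
suite verifies under randomized bindings.

## Problem sizes and limits

The randomized checks use networks of up to 30 nodes and depth 6, 50
random CLI specs, 1,000 random filenames and drive-letter paths, and
step/time budgets of 500,000 interpreter steps and 5 seconds per
script; these sizes are package choices balancing coverage against a
single-CPU test budget.

## Limitations

The scripting dialect is a subset (no coroutines, metatables, `goto`,
or `%b`/`%f`/back-reference pattern items). The CWL reader covers the
`CommandLineTool` argument-binding subset only — expressions,
requirements and outputs are noted and ignored. The HTTP and remote
backends construct requests/command lines but assume the service or
host enforces its own authentication. Serializing a hand-built
template merges adjacent literal text parts of an `add` (folding the
separator in), which preserves assembled output but may not preserve
part boundaries structurally; parse-derived templates round-trip
identically.
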