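"""Install modules: shell scripts that set up a tool and may ship the
tool's own template.

An install module is a POSIX shell script called with a fixed
positional contract::

    script INSTALL_DIR ADD_TO_PATH SUDO_PASSWORD [EXTRA...]

``ADD_TO_PATH`` is rendered ``TRUE``/``FALSE``; the password slot is an
empty placeholder when no password is supplied (the runner also exports
it as ``FORGE_SUDO_PASSWORD`` so modules can read the environment
variable instead of the process-visible argument); any extra inputs the
module declares come strictly last, in declared order.  A module may
embed its template between ``### BIOGUI-TEMPLATE-BEGIN`` and
``### BIOGUI-TEMPLATE-END`` marker lines, either in the script body or
in its output stream; after a successful run the template is
registered in the store.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import backends, dsl
from .backends import BackendDescriptor, RunResult
from .dsl import Diagnostic, Template, WindowElement
from .engine import CommandInvocation, TRUE, FALSE
from .errors import ForgeError

__all__ = [
    "InstallModule",
    "InstallOptions",
    "TEMPLATE_BEGIN",
    "TEMPLATE_END",
    "SUDO_ENV_VAR",
    "build_install_invocation",
    "extract_embedded_template",
    "run_install",
]

TEMPLATE_BEGIN = "### BIOGUI-TEMPLATE-BEGIN"
TEMPLATE_END = "### BIOGUI-TEMPLATE-END"
SUDO_ENV_VAR = "FORGE_SUDO_PASSWORD"

# option slots every module receives; extra input ids may not shadow them
RESERVED_OPTION_NAMES = frozenset(
    {"installdir", "addtopath", "sudopassword"})


@dataclass
class InstallModule:
    """A runnable install script plus its metadata."""

    script_path: Path
    name: str = ""
    description: str = ""
    declared_extras: tuple[WindowElement, ...] = ()
    target_environments: tuple[str, ...] = ("apt-based",)

    def __post_init__(self) -> None:
        self.script_path = Path(self.script_path)
        for extra in self.declared_extras:
            if extra.id and extra.id.lower() in RESERVED_OPTION_NAMES:
                raise ForgeError(
                    f"extra input id {extra.id!r} shadows a reserved "
                    "option name")

    def source(self) -> str:
        return self.script_path.read_text(encoding="utf-8")


@dataclass
class InstallOptions:
    """User choices for one installation."""

    install_dir: str
    add_to_path: bool = False
    sudo_password: Optional[str] = None
    extras: tuple[str, ...] = ()


def build_install_invocation(module: InstallModule,
                             options: InstallOptions) -> CommandInvocation:
    """Construct the install invocation (pure, order-stable).

    argv = [script, installDir, addToPath, passwordOrEmpty, extras...].
    The password is flagged secret so it never appears in logs or
    saved documents.
    """
    if not options.install_dir:
        raise ForgeError("install_dir must not be empty")
    password = options.sudo_password or ""
    args = (options.install_dir,
            TRUE if options.add_to_path else FALSE,
            password,
            *options.extras)
    bindings = {
        "installdir": options.install_dir,
        "addtopath": TRUE if options.add_to_path else FALSE,
        "sudopassword": password,
    }
    for i, extra in enumerate(options.extras):
        key = (module.declared_extras[i].id
               if i < len(module.declared_extras)
               and module.declared_extras[i].id
               else f"extra{i}")
        bindings[key] = extra
    return CommandInvocation(
        program=str(module.script_path),
        args=args,
        bindings=bindings,
        path_typed=frozenset({"installdir"}),
        secret=frozenset({"sudopassword"}),
        argv_style=True,
    )


def extract_embedded_template(
        source: str) -> tuple[Optional[Template], list[Diagnostic]]:
    """Scan script text or an output stream for a delimited template
    block and parse it.  Returns ``(None, [])`` when no block exists
    and ``(None, [diagnostic])`` when the block's XML is broken — the
    module stays usable for installation either way."""
    lines = source.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines)
                     if ln.strip() == TEMPLATE_BEGIN)
    except StopIteration:
        return None, []
    try:
        end = next(i for i in range(start + 1, len(lines))
                   if lines[i].strip() == TEMPLATE_END)
    except StopIteration:
        return None, [Diagnostic("error", "install-module",
                                 "template block is not terminated")]
    block = "\n".join(lines[start + 1:end])
    # tolerate shell-comment prefixes inside the block
    if all(ln.lstrip().startswith("#") or not ln.strip()
           for ln in block.splitlines()):
        block = "\n".join(ln.lstrip().lstrip("#")
                          for ln in block.splitlines())
    try:
        template = dsl.parse_template(block)
    except ForgeError as exc:
        return None, [Diagnostic("error", "install-module",
                                 f"embedded template: {exc}")]
    errors = [d for d in dsl.validate_template(template)
              if d.severity == "error"]
    if errors:
        return None, [Diagnostic("error", "install-module",
                                 f"embedded template: {errors[0].message}")]
    return template, []


def run_install(module: InstallModule, options: InstallOptions,
                backend: Optional[BackendDescriptor] = None,
                store=None,
                timeout: Optional[float] = None
                ) -> tuple[RunResult, Optional[Template]]:
    """Execute the install invocation and register any shipped template.

    Only the native and WSL process backends make sense for installs.
    On a nonzero exit the result is surfaced and nothing is registered.
    """
    backend = backend or BackendDescriptor(kind="native")
    if backend.kind not in ("native", "wsl"):
        raise ForgeError(
            f"install modules run on native or wsl backends, "
            f"not {backend.kind!r}")
    invocation = build_install_invocation(module, options)
    runnable = backends.build_backend_command(invocation, backend)

    import os
    import subprocess

    env = dict(os.environ)
    if options.sudo_password:
        env[SUDO_ENV_VAR] = options.sudo_password
    # same streaming semantics as backends.execute, plus the secret env
    proc = subprocess.run(
        runnable.argv, capture_output=True, timeout=timeout, env=env)
    records = [("out", ln) for ln in
               proc.stdout.decode("utf-8", "replace").splitlines()]
    records += [("err", ln) for ln in
                proc.stderr.decode("utf-8", "replace").splitlines()]
    result = RunResult(exit_status=proc.returncode, records=records)

    if result.exit_status != 0:
        return result, None

    template, _diags = extract_embedded_template(
        "\n".join(result.lines("out")))
    if template is None:
        template, _diags = extract_embedded_template(module.source())
    if template is not None and store is not None:
        store.register_template(template)
    return result, template
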