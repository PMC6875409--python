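"""Execution backends: native shell, WSL, remote/ssh, HTTP, Docker.

An assembled :class:`~guiforge.engine.CommandInvocation` is first turned
into a *runnable* (an argv list or an HTTP request descriptor) by
:func:`build_backend_command` — a pure construction — and only then, on
explicit request, executed by :func:`execute`, which streams stdout and
stderr lines in arrival order into a :class:`RunResult`.

Path handling for WSL follows the ``wslpath`` convention: a Windows
drive-letter path ``X:\\a\\b`` maps to ``/mnt/x/a/b``.  Translation is
applied only to path-typed binding values, never to arbitrary argument
text, so URLs or flags that merely look like paths are left alone.
"""

from __future__ import annotations

import re
import subprocess
import threading
import time
import urllib.parse
from dataclasses import dataclass, field
from typing import Optional

from .engine import CommandInvocation
from .errors import BackendError

__all__ = [
    "BackendDescriptor",
    "Runnable",
    "RunResult",
    "translate_path_win_to_posix",
    "translate_path_posix_to_win",
    "build_backend_command",
    "execute",
]

_DRIVE_RE = re.compile(r"^([A-Za-z]):[\\/]")
_MNT_RE = re.compile(r"^/mnt/([a-z])(/|$)")


def translate_path_win_to_posix(p: str) -> str:
    """``X:\\a\\b`` -> ``/mnt/x/a/b``; anything else is returned
    unchanged.  Total: never raises."""
    m = _DRIVE_RE.match(p)
    if m is None:
        return p
    rest = p[m.end():].replace("\\", "/")
    return f"/mnt/{m.group(1).lower()}/{rest}"


def translate_path_posix_to_win(p: str) -> str:
    """Inverse of :func:`translate_path_win_to_posix` for ``/mnt/<d>/``
    paths; other inputs are returned unchanged.  Drive letters come
    back uppercase, the canonical spelling on the Windows side."""
    m = _MNT_RE.match(p)
    if m is None:
        return p
    rest = p[m.end():]
    return f"{m.group(1).upper()}:\\" + rest.replace("/", "\\")


@dataclass
class BackendDescriptor:
    """Where and how an invocation should run.  Exactly one ``kind``;
    only that kind's fields may be set."""

    kind: str = "native"  # native|wsl|remote|http|docker
    shell: str = "sh"
    # remote
    host: str = ""
    port: int = 22
    transport: str = "ssh"  # ssh|stream
    stream_host: str = ""
    stream_port: int = 0
    # http
    url: str = ""
    fields: Optional[dict[str, str]] = None  # None -> all bindings
    # docker
    image: str = ""
    mounts: tuple[tuple[str, str], ...] = ()
    workdir: str = ""

    def validate(self) -> None:
        if self.kind not in ("native", "wsl", "remote", "http", "docker"):
            raise BackendError(f"unknown backend kind {self.kind!r}")
        if self.kind == "docker" and not self.image:
            raise BackendError("docker backend requires an image")
        if self.kind == "http" and not self.url:
            raise BackendError("http backend requires a URL")
        if self.kind == "remote" and not self.host:
            raise BackendError("remote backend requires a host")


@dataclass
class Runnable:
    """A concrete, inert runnable form.  ``argv`` for process paths,
    ``request`` for HTTP; ``listen`` names a TCP endpoint the caller
    must listen on for remote-stream output."""

    kind: str
    argv: tuple[str, ...] = ()
    request: Optional[dict] = None
    listen: Optional[tuple[str, int]] = None


@dataclass
class RunResult:
    """Outcome of one execution: exit status plus channel-tagged lines
    in arrival order."""

    exit_status: Optional[int]
    records: list[tuple[str, str]] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0
    error: str = ""
    timed_out: bool = False

    def lines(self, channel: Optional[str] = None) -> list[str]:
        return [text for chan, text in self.records
                if channel is None or chan == channel]


def _translated_command(inv: CommandInvocation) -> str:
    """Invocation command text with path-typed binding values rewritten
    to their WSL form (longest value first to avoid partial overlap)."""
    text = inv.command_text
    values = sorted((inv.bindings[k] for k in inv.path_typed
                     if k in inv.bindings), key=len, reverse=True)
    for value in values:
        translated = translate_path_win_to_posix(value)
        if translated != value and value:
            text = text.replace(value, translated)
    return text


def _shell_single_quote(text: str) -> str:
    return "'" + text.replace("'", "'\\''") + "'"


def build_backend_command(inv: CommandInvocation,
                          d: Optional[BackendDescriptor] = None) -> Runnable:
    """Turn an invocation into its backend-specific runnable form.

    Pure: no process is spawned and no connection is opened.
    """
    if d is None:
        d = BackendDescriptor()
    d.validate()
    if d.kind == "native":
        if inv.argv_style:
            return Runnable(kind="native",
                            argv=(d.shell, inv.program) + inv.args)
        return Runnable(kind="native",
                        argv=(d.shell, "-c", inv.command_text))
    if d.kind == "wsl":
        command = _translated_command(inv)
        if inv.argv_style:
            argv = ("wsl.exe", "bash", inv.program) + tuple(
                translate_path_win_to_posix(a) if a in {
                    inv.bindings.get(k, "") for k in inv.path_typed}
                else a for a in inv.args)
            return Runnable(kind="wsl", argv=argv)
        return Runnable(kind="wsl", argv=("wsl.exe", "bash", "-c", command))
    if d.kind == "remote":
        command = inv.command_text
        if d.transport == "stream":
            if not d.stream_host or not d.stream_port:
                raise BackendError(
                    "remote stream transport requires stream_host and "
                    "stream_port")
            piped = (f"{command} | nc {d.stream_host} {d.stream_port}")
            argv = ("ssh", "-p", str(d.port), d.host,
                    "sh -c " + _shell_single_quote(piped))
            return Runnable(kind="remote", argv=argv,
                            listen=(d.stream_host, d.stream_port))
        argv = ("ssh", "-p", str(d.port), d.host,
                "sh -c " + _shell_single_quote(command))
        return Runnable(kind="remote", argv=argv)
    if d.kind == "http":
        form = (dict(d.fields) if d.fields is not None
                else {k: v for k, v in inv.bindings.items()
                      if k not in inv.secret})
        return Runnable(kind="http", request={
            "method": "POST",
            "url": d.url,
            "headers": {
                "Content-Type": "application/x-www-form-urlencoded"},
            "body": urllib.parse.urlencode(form),
        })
    # docker
    argv = ["docker", "run"]
    for host_path, container_path in d.mounts:
        argv += ["-v", f"{host_path}:{container_path}"]
    if d.workdir:
        argv += ["-w", d.workdir]
    argv.append(d.image)
    if inv.argv_style:
        argv += ["sh", inv.program, *inv.args]
    else:
        argv += ["sh", "-c", inv.command_text]
    return Runnable(kind="docker", argv=tuple(argv))


def _pump(stream, channel: str, records: list, lock: threading.Lock) -> None:
    for raw in iter(stream.readline, b""):
        line = raw.decode("utf-8", errors="replace").rstrip("\r\n")
        with lock:
            records.append((channel, line))
    stream.close()


def execute(runnable: Runnable,
            timeout: Optional[float] = None) -> RunResult:
    """Run a runnable to completion, streaming output line-wise.

    Process paths use a child process with stdout/stderr pumped on
    threads; lines are recorded in arrival order per channel.  A missing
    program yields an error result with exit status 127; hitting
    ``timeout`` kills the child and flags the result.  HTTP runnables
    perform one request/response exchange.
    """
    started = time.time()
    if runnable.kind == "http":
        import urllib.request

        req = runnable.request or {}
        request = urllib.request.Request(
            req["url"], data=req.get("body", "").encode(),
            headers=req.get("headers", {}), method=req.get("method", "POST"))
        try:
            with urllib.request.urlopen(request, timeout=timeout) as resp:
                body = resp.read().decode("utf-8", errors="replace")
        except Exception as exc:
            return RunResult(exit_status=None, error=str(exc),
                             started=started, finished=time.time())
        records = [("out", line) for line in body.splitlines()]
        return RunResult(exit_status=None, records=records,
                         started=started, finished=time.time())

    if not runnable.argv:
        raise BackendError("runnable has no argv")
    try:
        proc = subprocess.Popen(runnable.argv, stdout=subprocess.PIPE,
                                stderr=subprocess.PIPE)
    except FileNotFoundError as exc:
        return RunResult(exit_status=127, error=f"program not found: {exc}",
                         started=started, finished=time.time())
    records: list[tuple[str, str]] = []
    lock = threading.Lock()
    threads = [
        threading.Thread(target=_pump,
                         args=(proc.stdout, "out", records, lock)),
        threading.Thread(target=_pump,
                         args=(proc.stderr, "err", records, lock)),
    ]
    for t in threads:
        t.start()
    timed_out = False
    try:
        proc.wait(timeout=timeout)
    except subprocess.TimeoutExpired:
        timed_out = True
        proc.kill()
        proc.wait()
    for t in threads:
        t.join()
    return RunResult(
        exit_status=None if timed_out else proc.returncode,
        records=records,
        started=started,
        finished=time.time(),
        timed_out=timed_out,
        error="timed out" if timed_out else "",
    )
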