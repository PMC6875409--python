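"""Exception hierarchy shared across the package."""


class ForgeError(Exception):
    """Base class for all guiforge errors."""


class TemplateParseError(ForgeError):
    """Raised when a template document cannot be parsed into a Template."""


class SubstitutionError(ForgeError):
    """Raised when ``${ref}`` substitution fails (unknown id, bad syntax)."""


class EvaluationError(ForgeError):
    """Raised when an execution node cannot be evaluated."""


class BindingError(ForgeError):
    """Raised when user input cannot be collected into total bindings."""


class ScriptError(ForgeError):
    """Raised when a script node's embedded program fails."""


class SandboxError(ScriptError):
    """Raised when an embedded script attempts a forbidden operation."""


class PatternError(ScriptError):
    """Raised for malformed patterns in the embedded dialect."""


class BackendError(ForgeError):
    """Raised when a backend descriptor is invalid or execution setup fails."""


class GeneratorError(ForgeError):
    """Raised when template generation from a CLI spec or CWL document fails."""


class StoreError(ForgeError):
    """Raised for template-store failures (unknown ids, bad manifests)."""
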