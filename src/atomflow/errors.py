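"""Exception hierarchy shared across the package."""


class AtomflowError(Exception):
    """Base class for all package errors."""


class ValidationError(AtomflowError):
    """An object violates a structural invariant."""


class StoreError(AtomflowError):
    """A persistence file is unreadable, corrupt or foreign."""


class TypingError(AtomflowError):
    """Force-field atom typing could not cover every atom."""


class PackingError(AtomflowError):
    """Random packing failed to place every molecule."""


class FlowchartError(AtomflowError):
    """A flowchart file or plug-in registration is invalid."""
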