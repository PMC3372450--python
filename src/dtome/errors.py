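"""Exception hierarchy shared across the package.

Validation failures (bad vocabulary tokens, inconsistent parameters,
namespace clashes) and input failures (missing or malformed files) are
kept distinct so the command-line layer can map them onto its exit-code
contract (2 = validation, 3 = I/O, 4 = internal).
"""


class DtomeError(Exception):
    """Base class for all package errors."""


class ValidationError(DtomeError):
    """Input content violates a documented contract or vocabulary."""


class InputError(DtomeError):
    """A required file is missing, unreadable, or structurally broken."""
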