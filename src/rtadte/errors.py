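"""Exception hierarchy.

All data-level failures raise :class:`DataError` so the CLI can map them to
exit code 1, distinct from usage errors (exit code 2, handled by click).
"""


class RtadteError(Exception):
    """Base class for all package errors."""


class DataError(RtadteError):
    """Malformed, inconsistent or missing input data."""
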