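"""Exception hierarchy for the screening pipeline.

Every error raised on bad input derives from :class:`StimscreenError`, so
callers (and the CLI) can catch one base class.
"""


class StimscreenError(Exception):
    """Base class for all stimscreen errors."""


class FormatError(StimscreenError):
    """A plate table or matrix file does not have the expected layout."""


class ValidationError(StimscreenError):
    """Parsed data violate a data-model invariant."""


class LookupError_(StimscreenError):
    """A requested plate, stimulus, signal or sample does not exist."""


class DegenerateBaselineError(StimscreenError):
    """A control-well median is zero (or negative), so fold changes are undefined."""


class MissingMeasurementError(StimscreenError):
    """No well measures the requested (stimulus, signal) combination."""


class EmptyMatrixError(StimscreenError):
    """An operation produced or received a matrix with no rows or columns."""


class IncomparablePairError(StimscreenError):
    """Two activation profiles share no comparable signal, so their
    dissimilarity is undefined."""


class InsufficientSamplesError(StimscreenError):
    """A statistical routine needs more observations per group than supplied."""
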