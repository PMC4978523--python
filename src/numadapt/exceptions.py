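"""Exception hierarchy shared across the package.

Every error raised by numadapt derives from :class:`NumadaptError`, so
callers (notably the CLI) can map failures onto exit codes: validation
problems are :class:`InvalidParameterError` subclasses, data problems are
:class:`DegenerateDataError` subclasses.
"""


class NumadaptError(Exception):
    """Base class for all numadapt errors."""


class InvalidParameterError(NumadaptError, ValueError):
    """A parameter violates a precondition (wrong range, wrong shape)."""


class FeasibilityError(InvalidParameterError):
    """A stimulus cannot be generated because the constraints cannot all hold."""


class PackingError(NumadaptError, RuntimeError):
    """Rejection sampling of dot positions exceeded its iteration cap."""


class DegenerateDataError(NumadaptError, ValueError):
    """Data admit no finite estimate (e.g. all-identical choices, zero variance)."""


class MissingCellError(DegenerateDataError):
    """A required design cell has no trials; message lists the offending cells."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(f"empty design cells: {self.cells}")
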