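"""Exception hierarchy shared across the package."""


class BehavoscError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BehavoscError, ValueError):
    """A function argument violates a documented precondition."""


class MissingDelayError(BehavoscError):
    """A grid delay has no trials to aggregate."""

    def __init__(self, delay_ms: float, subject=None, session=None):
        self.delay_ms = delay_ms
        self.subject = subject
        self.session = session
        super().__init__(
            f"no threshold-SOA trials at delay {delay_ms:g} ms"
            + (f" (subject={subject}, session={session})" if subject is not None else "")
        )


class SchemaError(BehavoscError):
    """A trial table does not match the expected CSV schema."""


class TrialParseError(BehavoscError):
    """A row of a trial table could not be parsed."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class DegenerateSeriesError(BehavoscError):
    """An operation received a (near-)constant series it cannot fit."""


class NonstationaryModelError(BehavoscError):
    """An AR model with |phi| >= 1 cannot be simulated as a stationary process."""
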