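"""Exception hierarchy shared by all rdisc modules."""


class RdiscError(Exception):
    """Base class for all rdisc errors."""


class FormatError(RdiscError):
    """A file does not conform to its expected grammar."""


class DataError(RdiscError):
    """Parsed data violates a model invariant (e.g. duplicate shifts)."""


class ConfigError(RdiscError):
    """A configuration value is inconsistent with the input it is applied to."""


class DegenerateInputError(RdiscError):
    """The input is valid but the operation is undefined on it (e.g. constant spectrum)."""


class StageError(RdiscError):
    """A pipeline stage failed; carries the stage name.

    ``stage`` names the step of the QC chain that raised, so callers can
    report *where* a spectrum failed without parsing the message.
    """

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
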