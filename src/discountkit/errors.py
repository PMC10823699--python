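"""Exception hierarchy shared across the package."""


class DiscountKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DiscountKitError, ValueError):
    """Invalid task, agent, or cohort configuration."""


class InvalidStepError(DiscountKitError, ValueError):
    """Titration step index outside the legal range for the series."""


class CorruptedSessionError(DiscountKitError, ValueError):
    """A session offer fell outside the open interval (0, future_amount)."""


class ProtocolError(DiscountKitError, ValueError):
    """An agent returned a choice token the task does not understand."""


class MalformedSessionError(DiscountKitError, ValueError):
    """A session record is incomplete or structurally inconsistent."""


class EstimationError(DiscountKitError, ValueError):
    """A statistical model could not be fitted (singular/rank-deficient design)."""


class ParseError(DiscountKitError, ValueError):
    """A CSV/JSON input file does not match the expected schema."""
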