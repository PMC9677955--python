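"""Exception hierarchy shared across the package."""


class LdmrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LdmrError):
    """Input file is missing mandatory columns or is otherwise unreadable."""


class EmptyInputError(LdmrError):
    """No valid rows survived validation."""


class EmptyOverlapError(LdmrError):
    """Two summary-statistics sets share no variant identifiers."""


class ConfigError(LdmrError):
    """Simulation or analysis configuration is internally inconsistent."""


class RankDeficiencyError(LdmrError):
    """Regression design is rank-deficient (e.g. all LD scores identical)."""


class UndefinedRgError(LdmrError):
    """Genetic correlation is undefined because a component heritability
    estimate is non-positive."""


class InsufficientInstrumentsError(LdmrError):
    """An estimator was called with fewer instruments than it requires."""


class EmptyInstrumentError(LdmrError):
    """Instrument selection eliminated every candidate.

    ``step`` names the quality-control step at which the set became empty.
    """

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"step {step}: {message}")
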