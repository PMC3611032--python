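"""Exception taxonomy for the diagnosis pipeline.

Every anticipated failure raises a subclass of :class:`AhpdxError` so the
command-line layer can report it without a traceback and map it to exit
code 1.
"""


class AhpdxError(Exception):
    """Base class for all anticipated errors."""


class InvalidProfileError(AhpdxError):
    """A condition profile violates its structural invariants."""


class IncompleteJudgmentsError(AhpdxError):
    """Pairwise judgments do not cover every unordered factor pair."""

    def __init__(self, missing_pairs):
        self.missing_pairs = list(missing_pairs)
        pairs = ", ".join(f"({a}, {b})" for a, b in self.missing_pairs)
        super().__init__(f"missing pairwise judgments for: {pairs}")


class DuplicateJudgmentError(AhpdxError):
    """The same unordered factor pair was judged more than once."""


class InvalidRatioError(AhpdxError):
    """A pairwise importance ratio is not a positive number."""


class NumericFailureError(AhpdxError):
    """Matrix squaring produced NaN or overflow."""


class UnsupportedSizeError(AhpdxError):
    """Matrix size outside the random-index table (3..10 factors)."""


class MissingRangeError(AhpdxError):
    """No reference range matches a factor for the given demographics."""


class UnitMismatchError(AhpdxError):
    """Panel analyte units disagree with the profile's declared units."""


class ProfileInconsistencyError(AhpdxError):
    """Weight vector and activation map cover different factor sets."""


class PanelParseError(AhpdxError):
    """A panel document is not well-formed XML."""


class PanelSchemaError(AhpdxError):
    """A well-formed panel document violates the panel dialect."""


class NotFoundError(AhpdxError):
    """A requested patient or panel does not exist in the store."""


class ConflictError(AhpdxError):
    """Re-insert of an existing key with different content."""


class ConfigError(AhpdxError):
    """A configuration value (profile file, cohort spec) is invalid."""
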