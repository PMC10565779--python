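"""Exception hierarchy shared across the package."""


class HippoquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HippoquantError):
    """A sweep file or sidecar violates the delimited+JSON dialect."""


class ProtocolError(HippoquantError):
    """A protocol descriptor is incomplete or inconsistent."""


class SimulationError(HippoquantError):
    """Forward integration diverged or was mis-specified."""


class ContaminatedBaselineError(HippoquantError):
    """A baseline window contains spikes or stimulus current."""


class ThresholdUndefinedError(HippoquantError):
    """The phase-plane curve is degenerate (no identifiable threshold)."""


class FitError(HippoquantError):
    """A curve fit failed to converge or is ill-posed."""


class UndefinedRatioError(HippoquantError):
    """A ratio's denominator is zero, negative, or below the noise floor."""


class TooFewGroupsError(HippoquantError):
    """ANOVA requested with fewer than three groups; use a t test instead."""


class ManifestError(HippoquantError):
    """An experiment manifest is empty or inconsistent."""


class UnstableBaselineWarning(UserWarning):
    """Baseline epoch drifts beyond the configured tolerance."""


class TruncatedSweepWarning(UserWarning):
    """A response window was cut short by the following stimulus."""
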