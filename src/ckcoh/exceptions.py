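"""Exception hierarchy for the ckcoh pipeline.

All domain errors derive from :class:`CkcohError` so callers can trap the
whole family; argument-contract violations raise plain ``ValueError``.
"""


class CkcohError(Exception):
    """Base class for all domain-specific errors."""


class NoPeaksDetectedError(CkcohError):
    """R-peak detector found no threshold crossings (empty/constant ECG)."""


class InsufficientBeatsError(CkcohError):
    """Fewer beat onsets than the minimum needed to build a beat series."""


class UnrepairableSeriesError(CkcohError):
    """Every heart period is outside the validity range; nothing to anchor on."""


class SeriesTooShortError(CkcohError):
    """Beat series shorter than the requested analysis segment."""

    def __init__(self, required: int, available: int):
        self.required = required
        self.available = available
        super().__init__(
            f"series too short: {required} beats required, {available} available"
        )


class DegenerateSeriesError(CkcohError):
    """Zero-variance series (after detrending) cannot be modelled."""


class UnstableARModelError(CkcohError):
    """Autoregressive model has poles on/outside the unit circle."""


class SpectralSingularityError(CkcohError):
    """Cross-spectral matrix singular or PSD vanishes on the frequency grid."""


class IdentificationError(CkcohError):
    """Least-squares identification failed (rank-deficient regressors)."""


class EmptyBandError(CkcohError):
    """No frequency-grid point falls inside the requested band."""


class NoRespiratoryComponentError(CkcohError):
    """No spectral component of the respiration series lies in the HF band."""


class UnreliableNullError(CkcohError):
    """Too many surrogate fits were unstable to trust the null distribution."""

    def __init__(self, n_failed: int, n_total: int):
        self.n_failed = n_failed
        self.n_total = n_total
        super().__init__(
            f"unreliable null: {n_failed}/{n_total} surrogate fits unstable"
        )
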