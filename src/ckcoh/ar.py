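"""Univariate autoregressive spectral analysis of beat-to-beat series.

The series is modelled as x(n) = sum_k a_k x(n-k) + w(n).  Coefficients are
obtained from the biased autocorrelation estimate via the Levinson-Durbin
recursion; the order is chosen by the Akaike information criterion over a
configured range (default 8-14).  The AR power spectral density is factorised
into components associated with real poles or complex-conjugate pole pairs,
and the power of each component is computed with the residue theorem, so the
component powers sum to the modelled process variance.

All AR mathematics lives on the dimensionless beat-frequency axis
(cycles/beat).  Conversion to Hz divides by the mean heart period of the
segment in seconds: f_Hz = f_cpb / mu_HP[s].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from sklearn.base import BaseEstimator

from .bands import DEFAULT_BANDS, BandDefinition
from .exceptions import (
    DegenerateSeriesError,
    NoRespiratoryComponentError,
    UnstableARModelError,
)

_logger = logging.getLogger(__name__)

DEFAULT_AR_ORDER_RANGE: tuple[int, int] = (8, 14)

_POLE_REAL_TOL = 1e-8


def time_domain_markers(series: np.ndarray) -> tuple[float, float]:
    """Mean and population variance of a beat series (units, units^2)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must contain at least 2 values")
    return float(x.mean()), float(x.var())


@dataclass
class ARModel:
    """Fitted univariate AR model.

    ``a`` are the prediction coefficients in x(n) = sum a_k x(n-k) + w(n),
    ``sigma2_w`` the prediction-error variance.  ``mean_hp_s`` carries the
    segment's mean heart period (s) used to convert cycles/beat to Hz.
    """

    a: np.ndarray
    order: int
    sigma2_w: float
    series_mean: float
    series_variance: float
    mean_hp_s: float = 1.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if len(self.a) != self.order:
            raise ValueError("coefficient vector length must equal order")
        if self.sigma2_w <= 0:
            raise ValueError("prediction-error variance must be positive")
        if self.mean_hp_s <= 0:
            raise ValueError("mean_hp_s must be positive")

    def poles(self) -> np.ndarray:
        """Roots of z^p - a_1 z^{p-1} - ... - a_p."""
        return np.roots(np.concatenate([[1.0], -self.a]))

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0))

    def psd(self, f_cpb: np.ndarray) -> np.ndarray:
        """AR power spectral density at frequencies in cycles/beat."""
        f = np.atleast_1d(np.asarray(f_cpb, dtype=float))
        z = np.exp(-2j * np.pi * f)
        az = 1.0 - np.polyval(self.a[::-1], z) * z  # 1 - sum a_k z^{-k}... see below
        # np.polyval(a[::-1], z)*z = a_1 z + a_2 z^2 + ...; with z = e^{-i2pi f}
        # this equals sum a_k e^{-i2pi f k}, i.e. A(f) evaluated on lags.
        return self.sigma2_w / np.abs(az) ** 2


@dataclass(frozen=True)
class SpectralComponent:
    """One pole-associated term of the AR spectral factorisation.

    ``power`` is rectified at zero for marker use; ``raw_power`` keeps the
    signed residue, whose sum over all components equals the process
    variance exactly (individual residues of near-cancelling poles can be
    legitimately negative).
    """

    frequency_cpb: float
    central_frequency_hz: float
    power: float
    pole_modulus: float
    is_real_pole: bool
    clipped: bool = False
    raw_power: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw_power is None:
            object.__setattr__(self, "raw_power", self.power)


def levinson_durbin(r: np.ndarray, max_order: int):
    """Levinson-Durbin recursion on an autocorrelation sequence.

    Returns ``(coeffs, sigma2s)`` where ``coeffs[p]`` is the length-``p``
    prediction-coefficient vector of the order-``p`` model (positive
    convention, x(n) = sum a_k x(n-k) + w) and ``sigma2s[p]`` the matching
    prediction-error variance; entries for p = 0..max_order.
    """
    r = np.asarray(r, dtype=float)
    if len(r) < max_order + 1:
        raise ValueError("need max_order+1 autocorrelation lags")
    if r[0] <= 0:
        raise DegenerateSeriesError("degenerate series: zero lag-0 autocorrelation")
    coeffs: list[np.ndarray] = [np.empty(0)]
    sigma2s = [float(r[0])]
    a = np.empty(0)
    err = float(r[0])
    for p in range(1, max_order + 1):
        acc = r[p] - (a * r[1:p][::-1]).sum() if p > 1 else r[1]
        k = acc / err
        a_new = np.empty(p)
        a_new[: p - 1] = a - k * a[::-1]
        a_new[p - 1] = k
        a = a_new
        err *= 1.0 - k * k
        if err <= 0:
            err = np.finfo(float).tiny
        coeffs.append(a.copy())
        sigma2s.append(float(err))
    return coeffs, sigma2s


def biased_autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide-by-n) autocorrelation estimate, lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    return full / n


def fit_ar(
    series: np.ndarray,
    order_range: tuple[int, int] = DEFAULT_AR_ORDER_RANGE,
    mean_hp_s: float = 1.0,
    detrend: bool = True,
) -> ARModel:
    """Fit an AR model with AIC order selection over ``order_range``.

    The series is linearly detrended (mean removed as part of the trend)
    before the biased autocorrelation is formed; Levinson-Durbin then yields
    every order up to the range maximum in one pass and AIC
    n*ln(sigma2_w) + 2p picks the order.
    """
    x = np.asarray(series, dtype=float)
    p_lo, p_hi = order_range
    if not 1 <= p_lo <= p_hi:
        raise ValueError("order_range must satisfy 1 <= lo <= hi")
    n = len(x)
    if n <= p_hi + 1:
        raise ValueError(f"series length {n} too short for order {p_hi}")
    mean = float(x.mean())
    x = _sig.detrend(x, type="linear") if detrend else x - mean
    variance = float(x.var())
    if variance <= 1e-12 * max(1.0, mean * mean):
        raise DegenerateSeriesError("degenerate series: zero variance")

    r = biased_autocorrelation(x, p_hi)
    coeffs, sigma2s = levinson_durbin(r, p_hi)
    orders = np.arange(p_lo, p_hi + 1)
    aic = np.array([n * np.log(sigma2s[p]) + 2 * p for p in orders])
    p = int(orders[int(np.argmin(aic))])
    return ARModel(
        a=coeffs[p],
        order=p,
        sigma2_w=sigma2s[p],
        series_mean=mean,
        series_variance=variance,
        mean_hp_s=mean_hp_s,
    )


def decompose_spectrum(model: ARModel) -> list[SpectralComponent]:
    """Residue-theorem factorisation of the AR PSD into pole components.

    For pole p_k of the AR polynomial the residue of S(z)/z at p_k is

        g_k = sigma2_w * p_k^{p-1} / (prod_{j!=k}(p_k - p_j)
                                      * prod_j (1 - conj(p_j) p_k)),

    and the component power is Re(g_k) for a real pole or 2*Re(g_k) for a
    complex-conjugate pair.  Powers sum to the modelled process variance.
    Components with numerically negative power (near-cancelling poles) are
    clipped at zero with a warning.
    """
    poles = model.poles()
    if np.any(np.abs(poles) >= 1.0):
        raise UnstableARModelError("unstable AR model: pole on/outside unit circle")
    p = model.order
    comps: list[SpectralComponent] = []
    for k, pk in enumerate(poles):
        if pk.imag < -_POLE_REAL_TOL:
            continue  # lower-half pole handled with its conjugate
        others = np.delete(poles, k)
        denom = np.prod(pk - others) * np.prod(1.0 - np.conj(poles) * pk)
        g = model.sigma2_w * pk ** (p - 1) / denom
        is_real = abs(pk.imag) <= _POLE_REAL_TOL
        raw_power = float(g.real) if is_real else float(2.0 * g.real)
        freq_cpb = float(np.abs(np.angle(pk)) / (2.0 * np.pi))
        power, clipped = raw_power, False
        if power < 0:
            _logger.debug(
                "negative residue power clipped to zero (pole %s, power %.3e)",
                pk, power,
            )
            power, clipped = 0.0, True
        comps.append(
            SpectralComponent(
                frequency_cpb=freq_cpb,
                central_frequency_hz=freq_cpb / model.mean_hp_s,
                power=power,
                pole_modulus=float(abs(pk)),
                is_real_pole=is_real,
                clipped=clipped,
                raw_power=raw_power,
            )
        )
    return sorted(comps, key=lambda c: c.frequency_cpb)


def band_power(
    components: list[SpectralComponent],
    band: str | tuple[float, float],
    bands: BandDefinition = DEFAULT_BANDS,
) -> float:
    """Total power of components whose central frequency (Hz) is in [lo, hi)."""
    lo, hi = bands.edges(band) if isinstance(band, str) else band
    return float(
        sum(c.power for c in components if lo <= c.central_frequency_hz < hi)
    )


def resp_frequency(
    components: list[SpectralComponent],
    bands: BandDefinition = DEFAULT_BANDS,
) -> float:
    """Respiratory rate (breaths/min) from the dominant HF component.

    The dominant component is the largest-power component with central
    frequency inside the HF band; ties break toward the lower frequency.
    """
    lo, hi = bands.edges("hf")
    hf = [c for c in components if lo <= c.central_frequency_hz < hi]
    if not hf:
        raise NoRespiratoryComponentError("no respiratory component in HF band")
    best = max(hf, key=lambda c: (c.power, -c.central_frequency_hz))
    return 60.0 * best.central_frequency_hz


class ARSpectrum(BaseEstimator):
    """Estimator wrapper: AR spectral decomposition of one beat series.

    Parameters
    ----------
    order_range : (int, int)
        AIC model-order search range, default (8, 14).
    mean_hp_s : float
        Mean heart period in seconds used to convert cycles/beat to Hz;
        1.0 leaves the frequency axis in cycles/beat.
    detrend : bool
        Remove a linear trend before fitting (default True).
    bands : BandDefinition
        LF/HF band edges in Hz.

    Attributes (after ``fit``)
    --------------------------
    model_ : ARModel
    components_ : list of SpectralComponent
    order_ : int, coef_ : ndarray, sigma2_ : float
    mean_ : float, variance_ : float
    """

    def __init__(
        self,
        order_range: tuple[int, int] = DEFAULT_AR_ORDER_RANGE,
        mean_hp_s: float = 1.0,
        detrend: bool = True,
        bands: BandDefinition = DEFAULT_BANDS,
    ):
        self.order_range = order_range
        self.mean_hp_s = mean_hp_s
        self.detrend = detrend
        self.bands = bands

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        self.model_ = fit_ar(
            x,
            order_range=self.order_range,
            mean_hp_s=self.mean_hp_s,
            detrend=self.detrend,
        )
        self.components_ = decompose_spectrum(self.model_)
        self.order_ = self.model_.order
        self.coef_ = self.model_.a
        self.sigma2_ = self.model_.sigma2_w
        self.mean_ = self.model_.series_mean
        self.variance_ = self.model_.series_variance
        return self

    def band_power(self, band: str) -> float:
        return band_power(self.components_, band, self.bands)

    def respiratory_rate_bpm(self) -> float:
        return resp_frequency(self.components_, self.bands)

    def psd(self, f_cpb: np.ndarray) -> np.ndarray:
        return self.model_.psd(f_cpb)
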