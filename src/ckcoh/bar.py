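"""Bivariate AR identification and causal squared coherence (CK2).

A pair of beat series is described by a bivariate autoregressive (BAR) model
with a direction-specific latency structure: the pathway with latency 0
contributes an instantaneous (lag-0) regressor in the effect equation, while
the reverse pathway starts at lag 1.  At most one pathway may be
instantaneous, which keeps the structural model recursive and lets the
innovation covariance be taken diagonal (the lag-0 coefficient absorbs the
instantaneous correlation).

From the fitted model the cross-spectral matrix S(f) = H(f) L H(f)^H with
H(f) = [I - A(f)]^{-1} yields

* squared coherence      K2(f) = |S12|^2 / (S11 S22), symmetric in the
  channels, and
* causal squared coherence CK2(f), obtained by zeroing every coefficient of
  the reverse (effect -> cause) pathway and recomputing the coherence of the
  modified model - directional by construction.

Band markers are arithmetic means of these functions over the LF or HF band
on a uniform cycles/beat grid converted to Hz through the mean heart period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg as _la
from scipy import signal as _sig
from sklearn.base import BaseEstimator

from .bands import DEFAULT_BANDS, BandDefinition
from .exceptions import (
    DegenerateSeriesError,
    EmptyBandError,
    IdentificationError,
    SpectralSingularityError,
    UnstableARModelError,
)

DEFAULT_BAR_ORDER_RANGE: tuple[int, int] = (5, 14)
DEFAULT_N_FREQ: int = 1025

_ALLOWED_LATENCIES = {(0, 1), (1, 0), (1, 1)}


def normalize_and_detrend(series: np.ndarray) -> np.ndarray:
    """Remove a linear least-squares trend, then z-score (population SD)."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("series must contain at least 3 values")
    resid = _sig.detrend(x, type="linear")
    var = resid.var()
    if var <= 1e-12 * max(x.var(), 1.0):
        raise DegenerateSeriesError("degenerate series: zero variance after detrend")
    out = (resid - resid.mean()) / np.sqrt(var)
    return out


@dataclass
class BARModel:
    """Fitted bivariate AR model.

    ``coef[k]`` is the 2x2 coefficient matrix at lag k (k = 0..order), with
    ``coef[k][i, j]`` the effect of channel j on channel i.  ``coef[0]``
    carries only the single allowed instantaneous cross term.  ``latency``
    is ``(k_xy, k_yx)``: the minimum lag of the channel-1 -> channel-2
    pathway and of the reverse one.  ``lambdas`` are the innovation
    variances (diagonal innovation covariance).
    """

    order: int
    coef: np.ndarray  # (order+1, 2, 2)
    lambdas: tuple[float, float]
    latency: tuple[int, int]
    n_samples: int
    stable: bool
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (self.order + 1, 2, 2):
            raise ValueError("coef must have shape (order+1, 2, 2)")
        if min(self.lambdas) <= 0:
            raise ValueError("innovation variances must be positive")

    def reduced_form(self) -> np.ndarray:
        """Reduced-form lag matrices (order, 2, 2) with lag-0 terms absorbed."""
        a0 = self.coef[0]
        inv0 = np.linalg.inv(np.eye(2) - a0)
        return np.einsum("ij,kjl->kil", inv0, self.coef[1:])

    def companion_eigenvalues(self) -> np.ndarray:
        p = self.order
        red = self.reduced_form()
        comp = np.zeros((2 * p, 2 * p))
        for k in range(p):
            comp[0:2, 2 * k : 2 * k + 2] = red[k]
        comp[2:, :-2] = np.eye(2 * (p - 1))
        return np.linalg.eigvals(comp)


def _lag_matrix(x: np.ndarray, max_lag: int, n0: int) -> np.ndarray:
    """Columns x[n-k] for k = 0..max_lag, rows n = n0..N-1."""
    n = len(x)
    return np.column_stack([x[n0 - k : n - k] for k in range(max_lag + 1)])


def _cholesky_ls(X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares via Cholesky on the normal equations.

    Falls back to a pivoted (SVD-based) solve with a warning when the Gram
    matrix is numerically near-singular; raises IdentificationError when the
    regressor matrix is rank deficient.
    """
    gram = X.T @ X
    rhs = X.T @ t
    try:
        cf = _la.cho_factor(gram, lower=True, check_finite=False)
        diag = np.diag(cf[0])
        if (diag.max() / max(diag.min(), np.finfo(float).tiny)) ** 2 > 1e12:
            raise _la.LinAlgError("near-singular Gram matrix")
        beta = _la.cho_solve(cf, rhs, check_finite=False)
    except (_la.LinAlgError, np.linalg.LinAlgError):
        beta, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
        if rank < X.shape[1]:
            raise IdentificationError(
                f"identification failure: rank {rank} < {X.shape[1]} regressors"
            ) from None
        warnings.warn(
            "near-singular normal equations; used pivoted least squares",
            RuntimeWarning,
            stacklevel=3,
        )
    resid = t - X @ beta
    return beta, float(resid @ resid / len(t))


def fit_bar(
    x: np.ndarray,
    y: np.ndarray,
    order_range: tuple[int, int] = DEFAULT_BAR_ORDER_RANGE,
    latency: tuple[int, int] = (0, 1),
    labels: tuple[str, str] = ("x", "y"),
) -> BARModel:
    """Identify the BAR model of (x, y) with per-direction minimum lags.

    ``latency = (k_xy, k_yx)`` sets the minimum lag of x in the y equation
    and of y in the x equation; allowed values (0,1), (1,0), (1,1).  Each
    equation is solved by least squares via Cholesky factorisation of its
    normal equations; the order minimises the multivariate Akaike figure of
    merit n*ln(lambda1*lambda2) + 2*(number of coefficients) over
    ``order_range`` on a common estimation sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if tuple(latency) not in _ALLOWED_LATENCIES:
        raise ValueError(f"latency must be one of {sorted(_ALLOWED_LATENCIES)}")
    k_xy, k_yx = latency
    p_lo, p_hi = order_range
    if not 1 <= p_lo <= p_hi:
        raise ValueError("order_range must satisfy 1 <= lo <= hi")
    n = len(x)
    if n < 4 * p_hi:
        raise ValueError(f"series length {n} < 4 * max order {p_hi}")

    n0 = p_hi  # common estimation sample across candidate orders
    lx = _lag_matrix(x, p_hi, n0)
    ly = _lag_matrix(y, p_hi, n0)
    n_rows = lx.shape[0]

    best = None
    for p in range(p_lo, p_hi + 1):
        # channel-1 (x) equation: own lags 1..p, cross y lags k_yx..p
        X1 = np.hstack([lx[:, 1 : p + 1], ly[:, k_yx : p + 1]])
        b1, lam1 = _cholesky_ls(X1, lx[:, 0])
        # channel-2 (y) equation: own lags 1..p, cross x lags k_xy..p
        X2 = np.hstack([ly[:, 1 : p + 1], lx[:, k_xy : p + 1]])
        b2, lam2 = _cholesky_ls(X2, ly[:, 0])
        lam1 = max(lam1, np.finfo(float).tiny)
        lam2 = max(lam2, np.finfo(float).tiny)
        n_coef = len(b1) + len(b2)
        aic = n_rows * np.log(lam1 * lam2) + 2.0 * n_coef
        if best is None or aic < best[0]:
            best = (aic, p, b1, b2, lam1, lam2)

    _, p, b1, b2, lam1, lam2 = best
    coef = np.zeros((p + 1, 2, 2))
    coef[1 : p + 1, 0, 0] = b1[:p]
    coef[k_yx : p + 1, 0, 1] = b1[p:]
    coef[1 : p + 1, 1, 1] = b2[:p]
    coef[k_xy : p + 1, 1, 0] = b2[p:]

    model = BARModel(
        order=p,
        coef=coef,
        lambdas=(lam1, lam2),
        latency=(k_xy, k_yx),
        n_samples=n,
        stable=True,
        labels=tuple(labels),
    )
    model.stable = bool(np.all(np.abs(model.companion_eigenvalues()) < 1.0))
    return model


def _require_stable(model: BARModel) -> None:
    if not model.stable:
        raise UnstableARModelError("unstable BAR model; refusing spectral analysis")


def _spectral_matrix_nocheck(model: BARModel, n_freq: int) -> tuple[np.ndarray, np.ndarray]:
    f = np.linspace(0.0, 0.5, n_freq)
    k = np.arange(model.order + 1)
    e = np.exp(-2j * np.pi * np.outer(f, k))  # (n_freq, order+1)
    af = np.einsum("fk,kij->fij", e, model.coef.astype(complex))
    m = np.eye(2)[None, :, :] - af
    det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
    if np.any(np.abs(det) < 1e-12):
        raise SpectralSingularityError("spectral singularity: det[I - A(f)] ~ 0")
    h = np.empty_like(m)
    h[:, 0, 0] = m[:, 1, 1] / det
    h[:, 0, 1] = -m[:, 0, 1] / det
    h[:, 1, 0] = -m[:, 1, 0] / det
    h[:, 1, 1] = m[:, 0, 0] / det
    lam = np.asarray(model.lambdas)
    s = np.einsum("fic,c,fjc->fij", h, lam, h.conj())
    return f, s


def spectral_matrix(model: BARModel, n_freq: int = DEFAULT_N_FREQ) -> tuple[np.ndarray, np.ndarray]:
    """Parametric cross-spectral matrix S(f) = H(f) L H(f)^H on [0, 0.5] cpb.

    Returns ``(f_cpb, S)`` with ``S`` of shape (n_freq, 2, 2); S11 and S22
    are real non-negative up to roundoff.
    """
    _require_stable(model)
    return _spectral_matrix_nocheck(model, n_freq)


def _coherence_from_spectra(s: np.ndarray) -> np.ndarray:
    s11 = s[:, 0, 0].real
    s22 = s[:, 1, 1].real
    if np.any(s11 <= 0) or np.any(s22 <= 0):
        raise SpectralSingularityError("spectral singularity: vanishing PSD")
    k2 = np.abs(s[:, 0, 1]) ** 2 / (s11 * s22)
    if k2.max() > 1.0 + 1e-9:
        raise SpectralSingularityError(
            f"coherence exceeded 1 by {k2.max() - 1.0:.3e}; ill-conditioned spectrum"
        )
    return np.clip(k2, 0.0, 1.0)


def squared_coherence(model: BARModel, n_freq: int = DEFAULT_N_FREQ) -> tuple[np.ndarray, np.ndarray]:
    """K2(f) = |S12|^2/(S11 S22) on the uniform cycles/beat grid."""
    f, s = spectral_matrix(model, n_freq)
    return f, _coherence_from_spectra(s)


def causal_squared_coherence(
    model: BARModel,
    direction: str,
    n_freq: int = DEFAULT_N_FREQ,
) -> tuple[np.ndarray, np.ndarray]:
    """CK2(f): coherence after zeroing the reverse (effect->cause) pathway.

    ``direction`` is ``"xy"`` (channel 1 causes channel 2) or ``"yx"``.
    For direction x->y the y->x coefficients (effect of channel 2 on
    channel 1) are forced to zero; innovation variances are unchanged.
    """
    _require_stable(model)
    if direction not in ("xy", "yx"):
        raise ValueError("direction must be 'xy' or 'yx'")
    coef = model.coef.copy()
    if direction == "xy":
        coef[:, 0, 1] = 0.0  # remove y -> x feedback
    else:
        coef[:, 1, 0] = 0.0  # remove x -> y feedback
    # The pathway-zeroed model need not be dynamically stable; CK2 only
    # evaluates its transfer function on the unit circle, and the modified
    # spectral matrix stays positive semidefinite, so CK2 remains in [0, 1].
    mod = replace(model, coef=coef)
    f, s = _spectral_matrix_nocheck(mod, n_freq)
    return f, _coherence_from_spectra(s)


def band_average(
    values: np.ndarray,
    freq_hz: np.ndarray,
    band: str | tuple[float, float],
    bands: BandDefinition = DEFAULT_BANDS,
) -> float:
    """Arithmetic mean of a frequency function over grid points in [lo, hi)."""
    lo, hi = bands.edges(band) if isinstance(band, str) else band
    mask = (freq_hz >= lo) & (freq_hz < hi)
    if not mask.any():
        raise EmptyBandError(f"empty band: no grid point in [{lo}, {hi}) Hz")
    return float(np.mean(np.asarray(values)[mask]))


class CausalCoherence(BaseEstimator):
    """Estimator wrapper: BAR identification plus K2/CK2 band markers.

    ``fit`` expects ``X`` of shape (n_beats, 2); column 0 is the channel
    whose pathway toward column 1 may act at lag 0 (e.g. RESP or SAP),
    column 1 the effect channel (e.g. HP).  Series are linearly detrended
    and z-scored before identification unless ``normalize=False``.

    Parameters
    ----------
    order_range : (int, int), default (5, 14)
        Multivariate-Akaike order search range.
    latency : (int, int), default (0, 1)
        Minimum lags (k_xy, k_yx) of the two pathways.
    n_freq : int, default 1025
        Uniform frequency-grid size on [0, 0.5] cycles/beat.
    mean_hp_s : float, default 1.0
        Mean heart period (s) converting cycles/beat to Hz; 1.0 keeps the
        grid in cycles/beat.
    bands : BandDefinition
        LF/HF edges in Hz.

    Attributes
    ----------
    model_ : BARModel;  order_ : int;  stable_ : bool
    freq_cpb_, freq_hz_ : ndarray
    k2_, ck2_xy_, ck2_yx_ : ndarray on the grid (None when unstable)
    """

    MARKERS = ("k2_lf", "k2_hf", "ck2_xy_lf", "ck2_xy_hf", "ck2_yx_lf", "ck2_yx_hf")

    def __init__(
        self,
        order_range: tuple[int, int] = DEFAULT_BAR_ORDER_RANGE,
        latency: tuple[int, int] = (0, 1),
        n_freq: int = DEFAULT_N_FREQ,
        mean_hp_s: float = 1.0,
        normalize: bool = True,
        bands: BandDefinition = DEFAULT_BANDS,
        labels: tuple[str, str] = ("x", "y"),
    ):
        self.order_range = order_range
        self.latency = latency
        self.n_freq = n_freq
        self.mean_hp_s = mean_hp_s
        self.normalize = normalize
        self.bands = bands
        self.labels = labels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_beats, 2)")
        a, b = X[:, 0], X[:, 1]
        if self.normalize:
            a = normalize_and_detrend(a)
            b = normalize_and_detrend(b)
        self.model_ = fit_bar(
            a, b, order_range=self.order_range, latency=self.latency,
            labels=self.labels,
        )
        self.order_ = self.model_.order
        self.stable_ = self.model_.stable
        self.freq_cpb_ = np.linspace(0.0, 0.5, self.n_freq)
        self.freq_hz_ = self.freq_cpb_ / self.mean_hp_s
        if self.stable_:
            _, s = spectral_matrix(self.model_, self.n_freq)
            self.k2_ = _coherence_from_spectra(s)
            _, self.ck2_xy_ = causal_squared_coherence(self.model_, "xy", self.n_freq)
            _, self.ck2_yx_ = causal_squared_coherence(self.model_, "yx", self.n_freq)
        else:
            self.k2_ = self.ck2_xy_ = self.ck2_yx_ = None
        return self

    def band_markers(self) -> dict[str, float]:
        """The six band-averaged markers of the fitted pair."""
        if not self.stable_:
            raise UnstableARModelError("unstable BAR fit; markers unavailable")
        out: dict[str, float] = {}
        for name, fn in (("k2", self.k2_), ("ck2_xy", self.ck2_xy_), ("ck2_yx", self.ck2_yx_)):
            for band in ("lf", "hf"):
                out[f"{name}_{band}"] = band_average(fn, self.freq_hz_, band, self.bands)
        return out

    def marker(self, name: str) -> float:
        return self.band_markers()[name]
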