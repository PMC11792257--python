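"""IAAFT surrogate generation and the uncoupling significance test.

Surrogate pairs preserve each series' value distribution exactly and its
amplitude spectrum approximately while destroying the cross-correlation
between the channels: each channel is phase-randomised independently
(uniform phases on [0, 2pi)) and iteratively refined by alternating a
spectrum-adjustment step and an amplitude-adjustment (rank-ordering) step.
The final step is the amplitude adjustment, so the surrogate's sorted values
equal the original's bit-exactly.

The uncoupling test recomputes a K2/CK2 band marker over ``n_pairs``
surrogate pairs with the full identification pipeline (detrend, z-score,
order selection re-run per pair by default); the null hypothesis of
uncoupling is rejected when the original marker lies strictly above the
nearest-rank 95th percentile of the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .bands import DEFAULT_BANDS, BandDefinition
from .bar import (
    DEFAULT_BAR_ORDER_RANGE,
    DEFAULT_N_FREQ,
    CausalCoherence,
)
from .exceptions import DegenerateSeriesError, UnreliableNullError

DEFAULT_N_ITER = 100
DEFAULT_N_PAIRS = 100
DEFAULT_PERCENTILE = 95.0


def _iaaft_batch(x: np.ndarray, n_iter: int, seeds) -> np.ndarray:
    """IAAFT surrogates of one series for several seeds, vectorised.

    Returns an (n, len(seeds)) array; column j is the surrogate obtained
    with ``seeds[j]``.  Each column's random phases come from that seed's
    own generator, so a batch of one reproduces the scalar routine exactly.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 32:
        raise ValueError("series must contain at least 32 values")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if x.std() == 0:
        raise DegenerateSeriesError("degenerate series: constant input")

    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))[:, None]  # (n_freq, 1)
    n_freq = target_amp.shape[0]

    phases = np.empty((n_freq, len(seeds)))
    for j, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        phases[:, j] = rng.uniform(0.0, 2.0 * np.pi, size=n_freq)
    phases[0, :] = 0.0  # keep DC real
    if n % 2 == 0:
        phases[-1, :] = 0.0  # keep Nyquist bin real

    s = np.fft.irfft(target_amp * np.exp(1j * phases), n=n, axis=0)
    for _ in range(n_iter):
        ft = np.fft.rfft(s, axis=0)
        s = np.fft.irfft(target_amp * np.exp(1j * np.angle(ft)), n=n, axis=0)
        ranks = np.argsort(np.argsort(s, axis=0), axis=0)
        s = sorted_x[ranks]
    return s


def iaaft_surrogate(series: np.ndarray, n_iter: int = DEFAULT_N_ITER, seed: int = 0) -> np.ndarray:
    """One IAAFT surrogate; deterministic given ``seed``.

    The surrogate's sorted values are bit-identical to the original's, and
    its amplitude spectrum approximates the original's, the approximation
    improving with ``n_iter`` (default 100).
    """
    return _iaaft_batch(series, n_iter, [seed])[:, 0]


def surrogate_pair(
    x: np.ndarray,
    y: np.ndarray,
    seed_x: int,
    seed_y: int,
    n_iter: int = DEFAULT_N_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Independently phase-randomised surrogate pair (uncoupled by design)."""
    if seed_x == seed_y:
        raise ValueError("seed_x and seed_y must differ to guarantee uncoupling")
    return (
        iaaft_surrogate(x, n_iter=n_iter, seed=seed_x),
        iaaft_surrogate(y, n_iter=n_iter, seed=seed_y),
    )


@dataclass
class SurrogateTestResult:
    """Outcome of one marker's uncoupling test."""

    marker: str
    original: float
    null_distribution: np.ndarray
    threshold: float
    reject: bool
    seeds: np.ndarray
    n_unstable: int = 0

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "original": self.original,
            "threshold": self.threshold,
            "reject": bool(self.reject),
            "n_unstable": self.n_unstable,
            "null_distribution": list(map(float, self.null_distribution)),
            "seeds": list(map(int, self.seeds)),
        }


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * m)-th sorted value."""
    v = np.sort(np.asarray(values, dtype=float))
    m = len(v)
    if m == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(percentile / 100.0 * m))
    return float(v[min(max(rank, 1), m) - 1])


def _derive_seeds(master_seed: int, n_pairs: int) -> np.ndarray:
    """2*n_pairs distinct uint32 seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(2 * n_pairs + 16)
    seeds = np.array(sorted(set(state.tolist()))[: 2 * n_pairs], dtype=np.uint64)
    if len(seeds) < 2 * n_pairs:  # astronomically unlikely
        seeds = np.arange(2 * n_pairs, dtype=np.uint64) + np.uint64(master_seed)
    rng = np.random.default_rng(master_seed)
    return rng.permutation(seeds)


def uncoupling_test_multi(
    x: np.ndarray,
    y: np.ndarray,
    markers: tuple[str, ...],
    n_pairs: int = DEFAULT_N_PAIRS,
    n_iter: int = DEFAULT_N_ITER,
    percentile: float = DEFAULT_PERCENTILE,
    master_seed: int = 0,
    order_range: tuple[int, int] = DEFAULT_BAR_ORDER_RANGE,
    latency: tuple[int, int] = (0, 1),
    n_freq: int = DEFAULT_N_FREQ,
    mean_hp_s: float = 1.0,
    refit_order: bool = True,
    bands: BandDefinition = DEFAULT_BANDS,
    max_unstable_fraction: float = 0.2,
) -> dict[str, SurrogateTestResult]:
    """Uncoupling tests for several band markers sharing one surrogate set.

    All markers of the (x, y) pair are evaluated on the same ``n_pairs``
    surrogate pairs, each re-identified with the full pipeline.  Marker
    names follow :attr:`CausalCoherence.MARKERS` (e.g. ``"ck2_xy_hf"``).
    """
    est = CausalCoherence(
        order_range=order_range, latency=latency, n_freq=n_freq,
        mean_hp_s=mean_hp_s, bands=bands,
    ).fit(np.column_stack([x, y]))
    originals = est.band_markers()
    unknown = set(markers) - set(originals)
    if unknown:
        raise ValueError(f"unknown markers: {sorted(unknown)}")

    surrogate_range = order_range if refit_order else (est.order_, est.order_)
    seeds = _derive_seeds(master_seed, n_pairs)
    xs = _iaaft_batch(x, n_iter, seeds[:n_pairs])
    ys = _iaaft_batch(y, n_iter, seeds[n_pairs:])

    null: dict[str, list[float]] = {m: [] for m in markers}
    n_unstable = 0
    sur = CausalCoherence(
        order_range=surrogate_range, latency=latency, n_freq=n_freq,
        mean_hp_s=mean_hp_s, bands=bands,
    )
    for j in range(n_pairs):
        sur.fit(np.column_stack([xs[:, j], ys[:, j]]))
        if not sur.stable_:
            n_unstable += 1
            continue
        vals = sur.band_markers()
        for m in markers:
            null[m].append(vals[m])
    if n_unstable > max_unstable_fraction * n_pairs:
        raise UnreliableNullError(n_unstable, n_pairs)

    out: dict[str, SurrogateTestResult] = {}
    for m in markers:
        dist = np.asarray(null[m])
        thr = nearest_rank_percentile(dist, percentile)
        out[m] = SurrogateTestResult(
            marker=m,
            original=float(originals[m]),
            null_distribution=dist,
            threshold=thr,
            reject=bool(originals[m] > thr),  # strictly above the percentile
            seeds=seeds,
            n_unstable=n_unstable,
        )
    return out


def uncoupling_test(
    x: np.ndarray,
    y: np.ndarray,
    marker: str,
    n_pairs: int = DEFAULT_N_PAIRS,
    n_iter: int = DEFAULT_N_ITER,
    percentile: float = DEFAULT_PERCENTILE,
    master_seed: int = 0,
    **kwargs,
) -> SurrogateTestResult:
    """Uncoupling test of a single K2/CK2 band marker (see multi version)."""
    return uncoupling_test_multi(
        x, y, (marker,), n_pairs=n_pairs, n_iter=n_iter,
        percentile=percentile, master_seed=master_seed, **kwargs,
    )[marker]


def rejection_proportion(results) -> float:
    """Percentage of tests rejecting the uncoupling null (the %K2/%CK2 index)."""
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    rejected = sum(
        bool(r.reject if isinstance(r, SurrogateTestResult) else r) for r in results
    )
    return 100.0 * rejected / len(results)


class UncouplingTest(BaseEstimator):
    """Estimator wrapper for the surrogate uncoupling test of one marker.

    ``fit(X)`` with X of shape (n_beats, 2) runs the full test; fitted
    attributes mirror :class:`SurrogateTestResult` (``original_``,
    ``null_distribution_``, ``threshold_``, ``reject_``).
    """

    def __init__(
        self,
        marker: str = "k2_hf",
        n_pairs: int = DEFAULT_N_PAIRS,
        n_iter: int = DEFAULT_N_ITER,
        percentile: float = DEFAULT_PERCENTILE,
        order_range: tuple[int, int] = DEFAULT_BAR_ORDER_RANGE,
        latency: tuple[int, int] = (0, 1),
        n_freq: int = DEFAULT_N_FREQ,
        mean_hp_s: float = 1.0,
        refit_order: bool = True,
        random_state: int = 0,
    ):
        self.marker = marker
        self.n_pairs = n_pairs
        self.n_iter = n_iter
        self.percentile = percentile
        self.order_range = order_range
        self.latency = latency
        self.n_freq = n_freq
        self.mean_hp_s = mean_hp_s
        self.refit_order = refit_order
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_beats, 2)")
        res = uncoupling_test(
            X[:, 0], X[:, 1], self.marker,
            n_pairs=self.n_pairs, n_iter=self.n_iter,
            percentile=self.percentile, master_seed=self.random_state,
            order_range=self.order_range, latency=self.latency,
            n_freq=self.n_freq, mean_hp_s=self.mean_hp_s,
            refit_order=self.refit_order,
        )
        self.result_ = res
        self.original_ = res.original
        self.null_distribution_ = res.null_distribution
        self.threshold_ = res.threshold
        self.reject_ = res.reject
        return self
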