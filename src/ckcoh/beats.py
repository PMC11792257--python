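"""Beat-to-beat variability series extraction from raw physiological signals.

Raw 400 Hz ECG / arterial pressure / respiration recordings are reduced to
per-beat series following the standard conventions of cardiovascular
variability analysis:

* the n-th heart period (HP, ms) is the interval between consecutive ECG
  R-wave peaks;
* the n-th systolic arterial pressure (SAP, mmHg) is the maximum of the AP
  waveform within the n-th heart period;
* the n-th respiration value (RESP, a.u.) is the respiratory signal sampled
  at the R-wave peak opening the n-th heart period.

Out-of-range heart periods (missed detections, ectopic beats) are repaired by
linear interpolation in the beat domain, and fixed-length segments of
consecutive beats are drawn for stationary spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientBeatsError,
    NoPeaksDetectedError,
    SeriesTooShortError,
    UnrepairableSeriesError,
)

DEFAULT_HP_RANGE: tuple[float, float] = (300.0, 2000.0)  # ms


@dataclass
class RawRecording:
    """Uniformly sampled ECG / arterial pressure / respiration channels."""

    ecg: np.ndarray
    ap: np.ndarray
    resp: np.ndarray
    fs: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        n = len(self.ecg)
        if len(self.ap) != n or len(self.resp) != n:
            raise ValueError("all channels must have the same length")
        if n < 2 * self.fs:
            raise ValueError("recording must span at least 2 s")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs


@dataclass
class BeatSeries:
    """Aligned per-beat HP [ms], SAP [mmHg] and RESP [a.u.] series.

    ``r_peak_times`` holds the onset time (s) of each beat, i.e. the R peak
    opening the corresponding heart period.  ``interpolated_mask`` flags
    beats whose values were repaired by interpolation.
    """

    hp: np.ndarray
    sap: np.ndarray
    resp: np.ndarray
    r_peak_times: np.ndarray
    interpolated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.hp = np.asarray(self.hp, dtype=float)
        self.sap = np.asarray(self.sap, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        n = len(self.hp)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(n, dtype=bool)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        for name in ("sap", "resp", "r_peak_times", "interpolated_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal hp length {n}")
        if np.any(self.hp <= 0):
            raise ValueError("all heart periods must be positive")

    @property
    def n_beats(self) -> int:
        return len(self.hp)

    @property
    def interpolated_fraction(self) -> float:
        return float(self.interpolated_mask.mean()) if self.n_beats else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_index": np.arange(self.n_beats),
                "t_r_peak_s": self.r_peak_times,
                "hp_ms": self.hp,
                "sap_mmhg": self.sap,
                "resp_au": self.resp,
                "interpolated": self.interpolated_mask.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition_label: str = "") -> "BeatSeries":
        return cls(
            hp=df["hp_ms"].to_numpy(float),
            sap=df["sap_mmhg"].to_numpy(float),
            resp=df["resp_au"].to_numpy(float),
            r_peak_times=df["t_r_peak_s"].to_numpy(float)
            if "t_r_peak_s" in df
            else np.concatenate([[0.0], np.cumsum(df["hp_ms"].to_numpy(float))[:-1] / 1e3]),
            interpolated_mask=df["interpolated"].to_numpy(bool)
            if "interpolated" in df
            else None,
            condition_label=condition_label,
        )

    @classmethod
    def read_csv(cls, path, condition_label: str = "") -> "BeatSeries":
        return cls.from_frame(pd.read_csv(path), condition_label=condition_label)


@dataclass(frozen=True)
class RepairReport:
    """Outcome of out-of-range beat repair."""

    n_interpolated: int
    interpolated_fraction: float
    warning: bool  # set when more than 5% of beats needed interpolation


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    threshold_factor: float = 0.4,
    refractory: float = 0.25,
) -> np.ndarray:
    """Detect R-wave peak times with a threshold on the ECG first derivative.

    A candidate beat is a sample where the positive first derivative exceeds
    ``threshold_factor`` times its rolling maximum over the preceding 2 s
    (adaptive to slow amplitude drift).  Each crossing is refined to the
    argmax of the raw ECG within the following 100 ms, and refined peaks
    closer than ``refractory`` seconds to the previous accepted peak are
    discarded.

    Returns strictly increasing peak times in seconds.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0.0 < threshold_factor < 1.0:
        raise ValueError("threshold_factor must be in (0, 1)")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    if len(ecg) < 2:
        raise NoPeaksDetectedError("no peaks detected: signal too short")

    deriv = np.diff(ecg) * fs
    dpos = np.clip(deriv, 0.0, None)
    peak_slope = float(dpos.max())
    if peak_slope <= 0.0:
        raise NoPeaksDetectedError("no peaks detected: derivative never positive")

    window = max(int(round(2.0 * fs)), 1)
    rolling_max = (
        pd.Series(dpos).rolling(window, min_periods=1).max().to_numpy()
    )
    # Global floor keeps micro-wiggles in flat stretches from triggering.
    threshold = np.maximum(threshold_factor * rolling_max, 0.05 * peak_slope)

    candidates = np.flatnonzero(dpos > threshold)
    if candidates.size == 0:
        raise NoPeaksDetectedError("no peaks detected: no threshold crossing")

    refine = max(int(round(0.100 * fs)), 1)
    peaks: list[int] = []
    last_time = -np.inf
    for idx in candidates:
        t_cross = idx / fs
        if t_cross - last_time < refractory:
            continue
        seg = ecg[idx : min(idx + refine + 1, len(ecg))]
        peak_idx = idx + int(np.argmax(seg))
        t_peak = peak_idx / fs
        if t_peak - last_time < refractory:
            continue
        peaks.append(peak_idx)
        last_time = t_peak

    if not peaks:
        raise NoPeaksDetectedError("no peaks detected")
    return np.asarray(peaks, dtype=float) / fs


def build_beat_series(
    r_peak_times: np.ndarray,
    ap: np.ndarray,
    resp: np.ndarray,
    fs: float,
    condition_label: str = "",
) -> BeatSeries:
    """Assemble the per-beat HP/SAP/RESP series from R-peak times.

    The n-th beat spans [t[n], t[n+1}); HP is the span in ms, SAP the maximum
    AP sample within the half-open span, RESP the sample nearest to t[n].
    """
    t = np.asarray(r_peak_times, dtype=float)
    ap = np.asarray(ap, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if len(t) < 3:
        raise InsufficientBeatsError(
            f"insufficient beats: need at least 3 R peaks, got {len(t)}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError("r_peak_times must be strictly increasing")
    n_samples = len(ap)
    if t[-1] * fs > n_samples:
        raise ValueError("beat times extend beyond the signal duration")

    hp = 1000.0 * np.diff(t)
    n_beats = len(hp)

    # sample index k lies in beat n iff t[n] <= k/fs < t[n+1]
    bounds = np.ceil(t * fs - 1e-9).astype(int)
    bounds = np.clip(bounds, 0, n_samples)
    sap = np.empty(n_beats)
    for n in range(n_beats):
        lo, hi = bounds[n], bounds[n + 1]
        if hi <= lo:
            raise ValueError("heart period shorter than one sample")
        sap[n] = ap[lo:hi].max()

    resp_idx = np.clip(np.round(t[:-1] * fs).astype(int), 0, n_samples - 1)
    return BeatSeries(
        hp=hp,
        sap=sap,
        resp=resp[resp_idx],
        r_peak_times=t[:-1],
        condition_label=condition_label,
    )


def repair_series(
    series: BeatSeries,
    hp_range: tuple[float, float] = DEFAULT_HP_RANGE,
) -> tuple[BeatSeries, RepairReport]:
    """Replace out-of-range heart periods by beat-domain linear interpolation.

    HP, SAP and RESP values at the flagged beats are interpolated between the
    nearest in-range neighbours, using the beat index as abscissa.  Leading or
    trailing out-of-range beats take the nearest in-range value.  The repaired
    series keeps its length; a warning flag is raised when more than 5% of
    beats required interpolation.
    """
    lo, hi = hp_range
    if lo <= 0:
        raise ValueError("hp_range lower bound must be positive")
    if hi <= lo:
        raise ValueError("hp_range must satisfy lo < hi")

    bad = (series.hp < lo) | (series.hp > hi)
    n = series.n_beats
    if bad.all():
        raise UnrepairableSeriesError("unrepairable series: all beats out of range")
    if not bad.any():
        report = RepairReport(0, 0.0, False)
        return series, report

    good_idx = np.flatnonzero(~bad)
    idx = np.arange(n)

    def _interp(values: np.ndarray) -> np.ndarray:
        out = values.copy()
        # np.interp clamps outside good_idx -> nearest in-range value at edges
        out[bad] = np.interp(idx[bad], good_idx, values[good_idx])
        return out

    repaired = BeatSeries(
        hp=_interp(series.hp),
        sap=_interp(series.sap),
        resp=_interp(series.resp),
        r_peak_times=series.r_peak_times.copy(),
        interpolated_mask=series.interpolated_mask | bad,
        condition_label=series.condition_label,
    )
    frac = float(bad.mean())
    return repaired, RepairReport(int(bad.sum()), frac, frac > 0.05)


def select_segment(series: BeatSeries, length: int = 256, seed: int = 0) -> BeatSeries:
    """Draw ``length`` consecutive beats, start index uniform given ``seed``."""
    if length < 1:
        raise ValueError("length must be positive")
    if series.n_beats < length:
        raise SeriesTooShortError(required=length, available=series.n_beats)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, series.n_beats - length + 1))
    sl = slice(start, start + length)
    return BeatSeries(
        hp=series.hp[sl].copy(),
        sap=series.sap[sl].copy(),
        resp=series.resp[sl].copy(),
        r_peak_times=series.r_peak_times[sl].copy(),
        interpolated_mask=series.interpolated_mask[sl].copy(),
        condition_label=series.condition_label,
    )
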