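"""Synthetic closed-loop cardiovascular beat-series generators.

These generators provide ground truth for every pipeline stage.  The
trivariate subject model emulates the physiological pathways probed by the
analysis with the same latency conventions (0/1 beats):

* RESP: autonomous narrow-band oscillator (AR(2) resonance at the breathing
  frequency) - the respiratory drive;
* HP: mild own dynamics plus RESP at lag 0 (respiratory sinus arrhythmia)
  and SAP at lag 0 (cardiac baroreflex);
* SAP: low-frequency resonance (Mayer waves) plus HP at lag 1 (mechanical
  feedforward through ventricular filling);
* an optional HP -> RESP lag-1 pathway (cardioventilatory coupling).

Channels are rescaled to configured means/SDs (defaults follow resting
values typical of a post-COVID cohort: mean HP 884 ms, HP variance
~750 ms^2, mean SAP 138 mmHg, breathing rate ~16 breaths/min).  Frequencies
are specified in Hz and mapped to cycles/beat through the mean heart
period.  Small additive white measurement noise is applied to RESP only.

A bivariate generator with one tunable coupling direction and a five-point
coupling-gain ladder backs the estimator-recovery and statistical-power
benches, and a raw-signal synthesiser (ECG templates, arterial pulse waves,
smooth respiration) exercises the beat-extraction stage with a round-trip
guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .beats import BeatSeries, RawRecording

#: Five-point coupling-gain ladder shared by recovery and power benches.
COUPLING_GAIN_LADDER: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic closed-loop generators.

    Frequencies are in Hz; coupling gains are dimensionless multipliers on
    z-scored internal states.  ``pair_*`` fields drive the bivariate
    generator only.
    """

    n_beats: int = 256
    seed: int = 0
    condition: str = "REST"

    # channel statistics (rescaling targets)
    mean_hp_ms: float = 884.0
    sd_hp_ms: float = 27.4  # variance ~750 ms^2
    mean_sap_mmhg: float = 138.0
    sd_sap_mmhg: float = 5.3  # variance ~28 mmHg^2

    # oscillator frequencies and sharpness
    resp_freq_hz: float = 0.268  # ~16.1 breaths/min
    lf_freq_hz: float = 0.1
    resp_pole_modulus: float = 0.94
    lf_pole_modulus: float = 0.8

    # directional coupling gains (trivariate model)
    gain_resp_to_hp: float = 1.2
    gain_hp_to_resp: float = 0.0
    gain_sap_to_hp: float = 0.4
    gain_hp_to_sap: float = 0.1
    hp_own_coef: float = 0.2

    # innovation variances
    var_resp: float = 1.0
    var_sap: float = 1.0
    var_hp: float = 1.0

    resp_noise_sd: float = 0.1  # measurement noise on RESP only
    burn_in: int = 500

    # bivariate pair generator
    pair_gain_x_to_y: float = 2.0
    pair_gain_y_to_x: float = 0.0
    pair_carrier: str = "hf"  # which oscillator the cause channel carries
    pair_coupling_lag: int = 0
    pair_y_own_coef: float = 0.5
    pair_var_y: float = 0.25

    def __post_init__(self) -> None:
        if self.n_beats < 64:
            raise ValueError("n_beats must be at least 64")
        nyq = 0.5 / self.mean_hp_s
        for f in (self.resp_freq_hz, self.lf_freq_hz):
            if not 0.0 < f < nyq:
                raise ValueError(f"frequency {f} Hz outside (0, {nyq:.3f})")
        if self.pair_carrier not in ("hf", "lf"):
            raise ValueError("pair_carrier must be 'hf' or 'lf'")
        if self.pair_coupling_lag not in (0, 1):
            raise ValueError("pair_coupling_lag must be 0 or 1")
        subject_companion_eigenvalues(self)  # raises if unstable

    @property
    def mean_hp_s(self) -> float:
        return self.mean_hp_ms / 1000.0

    @property
    def resp_freq_cpb(self) -> float:
        return self.resp_freq_hz * self.mean_hp_s

    @property
    def lf_freq_cpb(self) -> float:
        return self.lf_freq_hz * self.mean_hp_s


@dataclass
class GroundTruth:
    """Generating structure emitted alongside every synthetic data set."""

    config: SimulationConfig
    coefficients: dict
    coupling_flags: dict
    clean: dict


def _ar2_coeffs(modulus: float, freq_cpb: float) -> tuple[float, float]:
    """AR(2) coefficients of a complex pole pair (modulus, angle 2*pi*f)."""
    theta = 2.0 * np.pi * freq_cpb
    return 2.0 * modulus * np.cos(theta), -(modulus ** 2)


def _subject_lag_matrices(config: SimulationConfig) -> tuple[np.ndarray, ...]:
    """Structural lag matrices A0, A1, A2 on state (resp, sap, hp)."""
    c = config
    r1, r2 = _ar2_coeffs(c.resp_pole_modulus, c.resp_freq_cpb)
    s1, s2 = _ar2_coeffs(c.lf_pole_modulus, c.lf_freq_cpb)
    a0 = np.zeros((3, 3))
    a0[2, 0] = c.gain_resp_to_hp  # RESP -> HP, lag 0
    a0[2, 1] = c.gain_sap_to_hp  # SAP -> HP, lag 0
    a1 = np.zeros((3, 3))
    a1[0, 0] = r1
    a1[0, 2] = c.gain_hp_to_resp  # HP -> RESP, lag 1
    a1[1, 1] = s1
    a1[1, 2] = c.gain_hp_to_sap  # HP -> SAP, lag 1
    a1[2, 2] = c.hp_own_coef
    a2 = np.zeros((3, 3))
    a2[0, 0] = r2
    a2[1, 1] = s2
    return a0, a1, a2


def subject_companion_eigenvalues(config: SimulationConfig) -> np.ndarray:
    """Eigenvalues of the reduced-form companion matrix; raises if unstable."""
    a0, a1, a2 = _subject_lag_matrices(config)
    inv0 = np.linalg.inv(np.eye(3) - a0)
    red = [inv0 @ a1, inv0 @ a2]
    comp = np.zeros((6, 6))
    comp[0:3, 0:3] = red[0]
    comp[0:3, 3:6] = red[1]
    comp[3:6, 0:3] = np.eye(3)
    eig = np.linalg.eigvals(comp)
    if np.abs(eig).max() >= 1.0:
        raise ValueError(
            f"unstable generator configuration (spectral radius {np.abs(eig).max():.3f})"
        )
    return eig


def simulate_coupled_pair(config: SimulationConfig):
    """Bivariate AR realisation with one-directional tunable coupling.

    Channel x is a narrow-band oscillator at the configured carrier
    frequency (HF respiratory or LF Mayer-wave); channel y has mild own
    dynamics, receives ``pair_gain_x_to_y * x`` at ``pair_coupling_lag``
    and optionally feeds back to x at lag 1.  Returns ``(x, y, truth)``.
    """
    c = config
    freq = c.resp_freq_cpb if c.pair_carrier == "hf" else c.lf_freq_cpb
    modulus = c.resp_pole_modulus if c.pair_carrier == "hf" else c.lf_pole_modulus
    x1, x2 = _ar2_coeffs(modulus, freq)
    g_xy, g_yx, lag = c.pair_gain_x_to_y, c.pair_gain_y_to_x, c.pair_coupling_lag

    # stability of the 2-channel loop
    a0 = np.zeros((2, 2))
    a1 = np.array([[x1, g_yx], [0.0, c.pair_y_own_coef]])
    a2 = np.array([[x2, 0.0], [0.0, 0.0]])
    if lag == 0:
        a0[1, 0] = g_xy
    else:
        a1[1, 0] = g_xy
    inv0 = np.linalg.inv(np.eye(2) - a0)
    comp = np.zeros((4, 4))
    comp[0:2, 0:2] = inv0 @ a1
    comp[0:2, 2:4] = inv0 @ a2
    comp[2:4, 0:2] = np.eye(2)
    if np.abs(np.linalg.eigvals(comp)).max() >= 1.0:
        raise ValueError("unstable pair-generator configuration")

    rng = np.random.default_rng(c.seed)
    n_tot = c.n_beats + c.burn_in
    wx = rng.normal(0.0, 1.0, n_tot)
    wy = rng.normal(0.0, np.sqrt(c.pair_var_y), n_tot)
    x = np.zeros(n_tot)
    y = np.zeros(n_tot)
    for n in range(2, n_tot):
        x[n] = x1 * x[n - 1] + x2 * x[n - 2] + g_yx * y[n - 1] + wx[n]
        y[n] = c.pair_y_own_coef * y[n - 1] + g_xy * x[n - lag] + wy[n]
    x, y = x[c.burn_in :], y[c.burn_in :]
    truth = GroundTruth(
        config=c,
        coefficients={
            "x_own": (x1, x2),
            "y_own": c.pair_y_own_coef,
            "gain_x_to_y": g_xy,
            "gain_y_to_x": g_yx,
            "coupling_lag": lag,
        },
        coupling_flags={"x_to_y": g_xy != 0.0, "y_to_x": g_yx != 0.0},
        clean={"x": x.copy(), "y": y.copy()},
    )
    return x, y, truth


def simulate_subject(config: SimulationConfig):
    """Trivariate closed-loop subject realisation.

    Returns ``(BeatSeries, GroundTruth)``; HP/SAP are rescaled to the
    configured means/SDs (sample standardisation) and RESP is z-scored
    after adding measurement noise.
    """
    c = config
    a0, a1, a2 = _subject_lag_matrices(c)
    rng = np.random.default_rng(c.seed)
    n_tot = c.n_beats + c.burn_in
    w = np.column_stack(
        [
            rng.normal(0.0, np.sqrt(c.var_resp), n_tot),
            rng.normal(0.0, np.sqrt(c.var_sap), n_tot),
            rng.normal(0.0, np.sqrt(c.var_hp), n_tot),
        ]
    )
    state = np.zeros((n_tot, 3))  # columns: resp, sap, hp
    for n in range(2, n_tot):
        # recursive order: RESP and SAP need only lagged values, HP needs both at lag 0
        prev = a1 @ state[n - 1] + a2 @ state[n - 2] + w[n]
        resp_n = prev[0]
        sap_n = prev[1]
        hp_n = prev[2] + a0[2, 0] * resp_n + a0[2, 1] * sap_n
        state[n] = (resp_n, sap_n, hp_n)
    state = state[c.burn_in :]
    r_clean, s_clean, h_clean = state.T

    def _rescale(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
        return mean + sd * (z - z.mean()) / z.std()

    hp = _rescale(h_clean, c.mean_hp_ms, c.sd_hp_ms)
    sap = _rescale(s_clean, c.mean_sap_mmhg, c.sd_sap_mmhg)
    resp_noisy = r_clean + rng.normal(0.0, c.resp_noise_sd * r_clean.std(), c.n_beats)
    resp = (resp_noisy - resp_noisy.mean()) / resp_noisy.std()

    t = np.concatenate([[0.0], np.cumsum(hp[:-1]) / 1000.0])
    series = BeatSeries(
        hp=hp, sap=sap, resp=resp, r_peak_times=t, condition_label=c.condition
    )
    truth = GroundTruth(
        config=c,
        coefficients={"a0": a0, "a1": a1, "a2": a2},
        coupling_flags={
            "resp_to_hp": c.gain_resp_to_hp != 0.0,
            "hp_to_resp": c.gain_hp_to_resp != 0.0,
            "sap_to_hp": c.gain_sap_to_hp != 0.0,
            "hp_to_sap": c.gain_hp_to_sap != 0.0,
        },
        clean={"resp": r_clean, "sap": s_clean, "hp": h_clean},
    )
    return series, truth


def simulate_raw_signals(
    beat_series: BeatSeries,
    fs: float = 400.0,
    qrs_width_s: float = 0.008,
    diastolic_mmhg: float = 80.0,
    pad_s: float = 0.25,
) -> RawRecording:
    """Synthesise 400 Hz ECG/AP/RESP waveforms realising a beat series.

    ECG is a train of Gaussian QRS templates at the beat onsets (plus the
    closing R peak), AP a per-beat raised-sine pulse whose maximum equals
    the SAP value, RESP a cubic spline through the per-beat samples.  The
    recording starts ``pad_s`` seconds before the first beat onset so the
    first QRS has a complete rising edge.  The beat-extraction stage
    recovers HP within two samples and SAP at the pulse maxima.
    """
    hp_s = beat_series.hp / 1000.0
    if hp_s.min() < 8.0 / fs:
        raise ValueError("fs too low to resolve the shortest heart period")
    onsets = beat_series.r_peak_times + pad_s
    peaks = np.concatenate([onsets, [onsets[-1] + hp_s[-1]]])
    duration = peaks[-1] + pad_s
    n_samples = int(np.ceil(duration * fs)) + 1
    t = np.arange(n_samples) / fs

    ecg = np.zeros(n_samples)
    half = int(np.ceil(6 * qrs_width_s * fs))
    for tp in peaks:
        k = int(round(tp * fs))
        lo, hi = max(k - half, 0), min(k + half + 1, n_samples)
        ecg[lo:hi] += np.exp(-((t[lo:hi] - tp) ** 2) / (2.0 * qrs_width_s ** 2))

    ap = np.full(n_samples, diastolic_mmhg)
    bounds = np.ceil(peaks * fs - 1e-9).astype(int)
    for n in range(beat_series.n_beats):
        lo, hi = bounds[n], min(bounds[n + 1], n_samples)
        tau = (t[lo:hi] - peaks[n]) / hp_s[n]
        ap[lo:hi] = diastolic_mmhg + (beat_series.sap[n] - diastolic_mmhg) * np.sin(
            np.pi * tau
        ) ** 2

    spline = CubicSpline(onsets, beat_series.resp, bc_type="natural")
    resp = spline(np.clip(t, onsets[0], onsets[-1]))

    return RawRecording(
        ecg=ecg, ap=ap, resp=resp, fs=fs,
        condition_label=beat_series.condition_label,
    )


def _preset_configs() -> dict[str, SimulationConfig]:
    base = SimulationConfig()
    presets = {
        "HEALTHY_REST": replace(
            base,
            condition="REST",
            gain_resp_to_hp=1.5,
            gain_sap_to_hp=0.25,
        ),
        "HEALTHY_STAND": replace(
            base,
            condition="STAND",
            mean_hp_ms=798.0,
            sd_hp_ms=26.1,
            resp_freq_hz=0.273,
            gain_resp_to_hp=0.25,
            gain_sap_to_hp=1.5,
        ),
        "COVID_REST": replace(
            base,
            condition="REST",
            gain_resp_to_hp=0.8,
            gain_sap_to_hp=0.8,
        ),
        "COVID_STAND": replace(
            base,
            condition="STAND",
            mean_hp_ms=798.0,
            sd_hp_ms=26.1,
            resp_freq_hz=0.273,
            gain_resp_to_hp=0.8,
            gain_sap_to_hp=0.8,
        ),
        "UNCOUPLED": replace(
            base,
            gain_resp_to_hp=0.0,
            gain_sap_to_hp=0.0,
            gain_hp_to_sap=0.0,
            gain_hp_to_resp=0.0,
            pair_gain_x_to_y=0.0,
        ),
    }
    for i, gain in enumerate(COUPLING_GAIN_LADDER, start=1):
        presets[f"LADDER_{i}"] = replace(base, pair_gain_x_to_y=gain)
    return presets


PRESETS: dict[str, SimulationConfig] = _preset_configs()


def preset(name: str, **overrides) -> SimulationConfig:
    """Look up a named preset, optionally overriding fields (e.g. seed)."""
    try:
        cfg = PRESETS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return replace(cfg, **overrides) if overrides else cfg
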