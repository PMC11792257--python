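"""Per-subject end-to-end analysis and cohort aggregation.

``run_subject`` composes the full chain: (optional) raw-signal extraction,
out-of-range repair, 256-beat segment selection, univariate AR markers,
the two closed-loop pair analyses (HP-RESP in the HF band, HP-SAP in the
LF band) and the surrogate uncoupling tests of all six coupling markers.
Each stage failure is recorded per marker without aborting the rest.

``aggregate_cohort`` reduces a list of per-subject marker sets to the
cohort table: mean +/- SD of every continuous marker and the rejection
percentage of every surrogate verdict, per group x condition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandDefinition
from .beats import (
    DEFAULT_HP_RANGE,
    BeatSeries,
    RawRecording,
    build_beat_series,
    detect_r_peaks,
    repair_series,
    select_segment,
)
from .ar import ARSpectrum
from .bar import CausalCoherence
from .exceptions import CkcohError
from .surrogates import uncoupling_test_multi

#: (channel-1 name, marker suffix map) for the two analysed pairs.  Channel 1
#: is the pathway allowed to act at lag 0 (RESP->HP and SAP->HP), channel 2
#: is always HP.
PAIR_DEFINITIONS = {
    "resp_hp": {
        "x": "resp",
        "band": "hf",
        "markers": {
            "k2_hf": "k2_resp_hp_hf",
            "ck2_xy_hf": "ck2_resp_to_hp_hf",
            "ck2_yx_hf": "ck2_hp_to_resp_hf",
        },
    },
    "sap_hp": {
        "x": "sap",
        "band": "lf",
        "markers": {
            "k2_lf": "k2_sap_hp_lf",
            "ck2_xy_lf": "ck2_sap_to_hp_lf",
            "ck2_yx_lf": "ck2_hp_to_sap_lf",
        },
    },
}


# fixed per-pair seed offsets keep surrogate nulls independent yet reproducible
_PAIR_SEED_OFFSET = {"resp_hp": 101, "sap_hp": 202}


@dataclass(frozen=True)
class AnalysisConfig:
    """Defaults of the whole pipeline (Methods-standard values)."""

    hp_range: tuple[float, float] = DEFAULT_HP_RANGE
    segment_length: int = 256
    ar_order_range: tuple[int, int] = (8, 14)
    bar_order_range: tuple[int, int] = (5, 14)
    latency: tuple[int, int] = (0, 1)  # (cause->HP lag 0, HP->cause lag 1)
    n_freq: int = 1025
    n_surrogate_pairs: int = 100
    n_iaaft_iterations: int = 100
    percentile: float = 95.0
    refit_order: bool = True
    run_surrogates: bool = True
    bands: BandDefinition = DEFAULT_BANDS
    seed: int = 0
    detector_threshold_factor: float = 0.4
    detector_refractory_s: float = 0.25


@dataclass
class MarkerSet:
    """All scalar markers and test verdicts of one subject/condition."""

    subject_id: str
    group: str
    condition: str
    markers: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    bar_orders: dict = field(default_factory=dict)
    segment_start_time_s: float | None = None
    seed: int = 0
    interpolated_fraction: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json(indent=2))


def analyze_pair(
    x: np.ndarray,
    y: np.ndarray,
    mean_hp_s: float,
    config: AnalysisConfig = AnalysisConfig(),
    labels: tuple[str, str] = ("x", "y"),
) -> CausalCoherence:
    """Fit the BAR model of one (cause-candidate, HP) pair."""
    return CausalCoherence(
        order_range=config.bar_order_range,
        latency=config.latency,
        n_freq=config.n_freq,
        mean_hp_s=mean_hp_s,
        bands=config.bands,
        labels=labels,
    ).fit(np.column_stack([x, y]))


def run_subject(
    data: BeatSeries | RawRecording,
    config: AnalysisConfig = AnalysisConfig(),
    subject_id: str = "subject",
    group: str = "",
) -> MarkerSet:
    """Execute the full per-subject analysis; errors recorded, not raised."""
    result = MarkerSet(
        subject_id=subject_id,
        group=group,
        condition=getattr(data, "condition_label", ""),
        seed=config.seed,
    )

    try:
        if isinstance(data, RawRecording):
            peaks = detect_r_peaks(
                data.ecg,
                data.fs,
                threshold_factor=config.detector_threshold_factor,
                refractory=config.detector_refractory_s,
            )
            series = build_beat_series(
                peaks, data.ap, data.resp, data.fs,
                condition_label=data.condition_label,
            )
        else:
            series = data
        series, report = repair_series(series, config.hp_range)
        result.interpolated_fraction = report.interpolated_fraction
        segment = select_segment(series, config.segment_length, seed=config.seed)
        result.segment_start_time_s = float(segment.r_peak_times[0])
    except (CkcohError, ValueError) as exc:
        result.errors["extraction"] = str(exc)
        return result

    mean_hp_s = float(segment.hp.mean()) / 1000.0

    # univariate markers
    for name, values, band_marker in (
        ("hp", segment.hp, ("hf", "hf_hp")),
        ("sap", segment.sap, ("lf", "lf_sap")),
    ):
        result.markers[f"mu_{name}"] = float(values.mean())
        result.markers[f"var_{name}"] = float(values.var())
        try:
            spec = ARSpectrum(
                order_range=config.ar_order_range,
                mean_hp_s=mean_hp_s,
                bands=config.bands,
            ).fit(values)
            band, marker_name = band_marker
            result.markers[marker_name] = spec.band_power(band)
        except (CkcohError, ValueError) as exc:
            result.errors[f"ar_{name}"] = str(exc)
    try:
        resp_spec = ARSpectrum(
            order_range=config.ar_order_range,
            mean_hp_s=mean_hp_s,
            bands=config.bands,
        ).fit(segment.resp)
        result.markers["f_resp_bpm"] = resp_spec.respiratory_rate_bpm()
    except (CkcohError, ValueError) as exc:
        result.errors["ar_resp"] = str(exc)

    # closed-loop pair analyses + surrogate verdicts
    channels = {"hp": segment.hp, "sap": segment.sap, "resp": segment.resp}
    for pair_name, spec_def in PAIR_DEFINITIONS.items():
        x = channels[spec_def["x"]]
        y = channels["hp"]
        try:
            est = analyze_pair(
                x, y, mean_hp_s, config, labels=(spec_def["x"], "hp")
            )
            result.bar_orders[pair_name] = int(est.order_)
            band_markers = est.band_markers()
            for key, out_name in spec_def["markers"].items():
                result.markers[out_name] = band_markers[key]
        except (CkcohError, ValueError) as exc:
            result.errors[pair_name] = str(exc)
            continue
        if not config.run_surrogates:
            continue
        try:
            tests = uncoupling_test_multi(
                x, y,
                tuple(spec_def["markers"].keys()),
                n_pairs=config.n_surrogate_pairs,
                n_iter=config.n_iaaft_iterations,
                percentile=config.percentile,
                master_seed=config.seed + _PAIR_SEED_OFFSET[pair_name],
                order_range=config.bar_order_range,
                latency=config.latency,
                n_freq=config.n_freq,
                mean_hp_s=mean_hp_s,
                refit_order=config.refit_order,
                bands=config.bands,
            )
            for key, out_name in spec_def["markers"].items():
                result.verdicts[out_name] = bool(tests[key].reject)
        except (CkcohError, ValueError) as exc:
            result.errors[f"surrogates_{pair_name}"] = str(exc)
    return result


CONTINUOUS_MARKERS = (
    "mu_hp", "var_hp", "hf_hp", "mu_sap", "var_sap", "lf_sap", "f_resp_bpm",
    "k2_resp_hp_hf", "ck2_resp_to_hp_hf", "ck2_hp_to_resp_hf",
    "k2_sap_hp_lf", "ck2_sap_to_hp_lf", "ck2_hp_to_sap_lf",
)


def aggregate_cohort(marker_sets) -> pd.DataFrame:
    """Cohort table: mean +/- SD per marker and % rejections per verdict."""
    marker_sets = list(marker_sets)
    if not marker_sets:
        raise ValueError("at least one MarkerSet required")
    missing = [m.subject_id for m in marker_sets if not m.condition]
    if missing:
        raise ValueError(f"missing condition labels for subjects: {missing}")

    rows = []
    for m in marker_sets:
        row = {"subject_id": m.subject_id, "group": m.group, "condition": m.condition}
        row.update({k: m.markers.get(k, np.nan) for k in CONTINUOUS_MARKERS})
        row.update({f"reject_{k}": m.verdicts.get(k, np.nan) for k in m.verdicts})
        rows.append(row)
    df = pd.DataFrame(rows)

    out = []
    for (group, condition), sub in df.groupby(["group", "condition"], dropna=False):
        rec: dict = {"group": group, "condition": condition, "n": len(sub)}
        for k in CONTINUOUS_MARKERS:
            vals = sub[k].dropna()
            rec[f"{k}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{k}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        for col in sub.columns:
            if col.startswith("reject_"):
                vals = sub[col].dropna()
                if len(vals):
                    rec[f"pct_{col[len('reject_'):]}"] = 100.0 * vals.mean()
        out.append(rec)
    return pd.DataFrame(out)
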