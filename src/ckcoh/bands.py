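"""Standard spectral bands of cardiovascular variability.

The low-frequency (LF) band, 0.04-0.15 Hz, collects baroreflex/sympathetic
rhythms (Mayer waves); the high-frequency (HF) band, 0.15-0.4 Hz, collects
respiration-driven (vagal) rhythms.  Band membership is evaluated on the
closed-open interval [lo, hi), so 0.15 Hz belongs to HF only.
"""

from __future__ import annotations

from dataclasses import dataclass

LF_BAND: tuple[float, float] = (0.04, 0.15)
HF_BAND: tuple[float, float] = (0.15, 0.40)


@dataclass(frozen=True)
class BandDefinition:
    """LF/HF band edges in Hz; non-overlapping and ordered."""

    lf: tuple[float, float] = LF_BAND
    hf: tuple[float, float] = HF_BAND

    def __post_init__(self) -> None:
        for lo, hi in (self.lf, self.hf):
            if not lo < hi:
                raise ValueError("band edges must satisfy lo < hi")
        if self.lf[1] > self.hf[0]:
            raise ValueError("LF and HF bands must not overlap and be ordered")

    def edges(self, name: str) -> tuple[float, float]:
        try:
            return {"lf": self.lf, "hf": self.hf}[name.lower()]
        except KeyError:
            raise ValueError(f"unknown band {name!r}; expected 'lf' or 'hf'") from None

    def contains(self, name: str, freq_hz: float) -> bool:
        lo, hi = self.edges(name)
        return lo <= freq_hz < hi


DEFAULT_BANDS = BandDefinition()
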