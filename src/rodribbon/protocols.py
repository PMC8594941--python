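"""Voltage-command protocols for capacitance and I-V recordings.

A protocol is an ordered list of segments (sine probe, step, hold) plus
sampling metadata.  Segment durations are kept commensurate with the sine
cycle (0.5 ms at 2 kHz) so that lock-in estimation bins never straddle a
segment boundary.

The nominal inter-stimulus interval of the experiments (8 s for the step
series, 3 s for the I-V family) is carried as metadata; since pool refill
is instantaneous on that timescale, the rendered command compresses the
dead time between episodes to a short hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .lockin import SinewaveSpec


@dataclass(frozen=True)
class Segment:
    kind: str  # "sine" | "step" | "hold"
    duration_ms: float
    level_mV: float | None = None  # for step/hold

    def __post_init__(self) -> None:
        if self.kind not in ("sine", "step", "hold"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind != "sine" and self.level_mV is None:
            raise ValueError(f"{self.kind} segment needs a level")


@dataclass
class VoltageProtocol:
    """An ordered segment list with sampling metadata."""

    segments: list[Segment]
    sample_rate_Hz: float = 20000.0
    inter_stimulus_s: float = 8.0
    sine: SinewaveSpec = field(default_factory=SinewaveSpec)
    holding_mV: float = -70.0
    online_filter_Hz: float | None = None
    label: str = ""

    @property
    def total_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    def render(self, dt_ms: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Sample the command voltage; returns (times_ms, v_mV).

        ``dt_ms`` defaults to the protocol sampling interval; a finer value
        may be requested (the sine is evaluated analytically, so rendering
        is exact at any rate).
        """
        if dt_ms is None:
            dt_ms = 1e3 / self.sample_rate_Hz
        n = int(round(self.total_ms / dt_ms))
        t = np.arange(n) * dt_ms
        v = np.full(n, self.holding_mV)
        t0 = 0.0
        for seg in self.segments:
            sel = slice(int(round(t0 / dt_ms)),
                        int(round((t0 + seg.duration_ms) / dt_ms)))
            if seg.kind == "sine":
                # sine phase restarts at each segment so segment boundaries
                # always fall on cycle boundaries
                v[sel] = self.sine.waveform(t[sel] - t0)
            else:
                v[sel] = seg.level_mV
            t0 += seg.duration_ms
        return t, v

    def step_episodes(self) -> list[dict]:
        """Start/end times and levels of the step segments, in order."""
        episodes, t0 = [], 0.0
        for seg in self.segments:
            if seg.kind == "step":
                episodes.append({"t_start_ms": t0,
                                 "t_end_ms": t0 + seg.duration_ms,
                                 "duration_ms": seg.duration_ms,
                                 "v_step_mV": seg.level_mV})
            t0 += seg.duration_ms
        return episodes

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "label": self.label,
            "sample_rate_Hz": self.sample_rate_Hz,
            "inter_stimulus_s": self.inter_stimulus_s,
            "holding_mV": self.holding_mV,
            "online_filter_Hz": self.online_filter_Hz,
            "sine": {
                "frequency_Hz": self.sine.frequency_Hz,
                "amplitude_pp_mV": self.sine.amplitude_pp_mV,
                "offset_mV": self.sine.offset_mV,
                "segment_ms": self.sine.segment_ms,
                "sample_rate_Hz": self.sine.sample_rate_Hz,
                "output_corner_Hz": self.sine.output_corner_Hz,
            },
            "segments": [
                {"kind": s.kind, "duration_ms": s.duration_ms,
                 "level_mV": s.level_mV} for s in self.segments],
        }, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "VoltageProtocol":
        raw = yaml.safe_load(text)
        return cls(
            segments=[Segment(s["kind"], s["duration_ms"], s.get("level_mV"))
                      for s in raw["segments"]],
            sample_rate_Hz=raw.get("sample_rate_Hz", 20000.0),
            inter_stimulus_s=raw.get("inter_stimulus_s", 8.0),
            sine=SinewaveSpec(**raw.get("sine", {})),
            holding_mV=raw.get("holding_mV", -70.0),
            online_filter_Hz=raw.get("online_filter_Hz"),
            label=raw.get("label", ""),
        )


STEP_DURATIONS_MS = (0.5, 1.0, 3.0, 9.0, 15.0, 30.0)


def build_step_series_protocol(durations_ms=STEP_DURATIONS_MS,
                               v_step_mV: float = -18.0,
                               interval_s: float = 8.0,
                               sine: SinewaveSpec | None = None,
                               gap_hold_ms: float = 50.0,
                               ascending_required: bool = True
                               ) -> VoltageProtocol:
    """Capacitance step-series protocol: sine segments bracket each step.

    Each episode is [100 ms sine][step][200 ms sine]; episodes are
    separated by a hold (the nominal 8 s rest lives in the metadata).
    Default durations follow the ascending experimental ordering.
    """
    durations = tuple(float(d) for d in durations_ms)
    if ascending_required and list(durations) != sorted(durations):
        raise ValueError("step durations must be ascending (pass "
                         "ascending_required=False to override)")
    sine = sine or SinewaveSpec()
    segs: list[Segment] = []
    for d in durations:
        if abs(d / sine.cycle_ms - round(d / sine.cycle_ms)) > 1e-9:
            raise ValueError("step durations must be whole sine cycles")
        segs.append(Segment("sine", sine.segment_ms))
        segs.append(Segment("step", d, v_step_mV))
        segs.append(Segment("sine", 2 * sine.segment_ms))
        segs.append(Segment("hold", gap_hold_ms, -70.0))
    return VoltageProtocol(segments=segs, sample_rate_Hz=sine.sample_rate_Hz,
                           inter_stimulus_s=interval_s, sine=sine,
                           label="step-series")


def build_iv_protocol(v_start_mV: float = 30.0, v_stop_mV: float = -80.0,
                      increment_mV: float = -10.0, duration_ms: float = 10.0,
                      interval_s: float = 3.0,
                      sample_rate_Hz: float = 50000.0,
                      pre_hold_ms: float = 20.0,
                      post_hold_ms: float = 40.0) -> VoltageProtocol:
    """I-V family: 10 ms steps delivered in descending order of voltage."""
    if increment_mV >= 0:
        raise ValueError("increment must be negative (descending order)")
    levels = np.arange(v_start_mV, v_stop_mV + increment_mV / 2, increment_mV)
    segs: list[Segment] = []
    for v in levels:
        segs.append(Segment("hold", pre_hold_ms, -70.0))
        segs.append(Segment("step", duration_ms, float(v)))
        segs.append(Segment("hold", post_hold_ms, -70.0))
    return VoltageProtocol(segments=segs, sample_rate_Hz=sample_rate_Hz,
                           inter_stimulus_s=interval_s,
                           online_filter_Hz=10000.0, label="iv-series")
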