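"""Sine+dc decomposition of clamp current into C_m, G_m and G_s.

A sinusoidal command superimposed on the holding potential probes the
cell's complex admittance Y(omega); together with the DC conductance this
over-determines the three-element circuit, which is inverted in closed
form per estimation bin (one sine cycle):

    G_s = (A^2 + B^2 - A G_t) / (A - G_t)
    G_m = G_s G_t / (G_s - G_t)
    C_m = G_s^2 B / (omega ((G_s - A)^2 + B^2))

with Y = A + iB the admittance at the sine frequency and G_t the DC
conductance.  Bins whose command does not match the sine template (step
depolarisations, plain holds) are flagged as stimulation segments; bins
whose inversion turns non-physical are flagged invalid rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


@dataclass(frozen=True)
class SinewaveSpec:
    """Probe-sine parameters of the capacitance protocol."""

    frequency_Hz: float = 2000.0
    amplitude_pp_mV: float = 50.0
    offset_mV: float = -70.0
    segment_ms: float = 100.0
    sample_rate_Hz: float = 20000.0
    output_corner_Hz: float = 2900.0

    @property
    def samples_per_cycle(self) -> int:
        spc = self.sample_rate_Hz / self.frequency_Hz
        if abs(spc - round(spc)) > 1e-9:
            raise ValueError("sample rate must be an integer multiple of the "
                             "sine frequency")
        return int(round(spc))

    @property
    def cycle_ms(self) -> float:
        return 1e3 / self.frequency_Hz

    def waveform(self, t_ms) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        return self.offset_mV + 0.5 * self.amplitude_pp_mV * np.sin(
            2e-3 * np.pi * self.frequency_Hz * t)


@dataclass
class LockinTrace:
    """Per-bin circuit estimates from the sine+dc decomposition."""

    times_ms: np.ndarray
    c_m_fF: np.ndarray
    g_m_nS: np.ndarray
    g_s_nS: np.ndarray
    valid: np.ndarray
    stimulation: np.ndarray
    spec: SinewaveSpec = field(default_factory=SinewaveSpec)

    def __post_init__(self) -> None:
        n = self.times_ms.size
        for name in ("c_m_fF", "g_m_nS", "g_s_nS", "valid", "stimulation"):
            if getattr(self, name).size != n:
                raise ValueError("channel length mismatch")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.times_ms,
            "c_m_fF": self.c_m_fF,
            "g_m_nS": self.g_m_nS,
            "g_s_nS": self.g_s_nS,
            "valid": self.valid,
            "stimulation": self.stimulation,
        })


def invert_admittance(a_nS: float, b_nS: float, g_dc_nS: float,
                      frequency_Hz: float) -> tuple[float, float, float]:
    """Closed-form three-element inversion of (Re Y, Im Y, G_dc).

    Returns (c_m_pF, g_m_nS, g_s_nS); raises ValueError when the inputs do
    not correspond to a physical circuit.
    """
    omega = 2e-3 * np.pi * frequency_Hz  # rad/ms
    denom = a_nS - g_dc_nS
    if denom <= 0 or b_nS <= 0 or g_dc_nS < 0:
        raise ValueError("non-physical admittance input")
    g_s = (a_nS ** 2 + b_nS ** 2 - a_nS * g_dc_nS) / denom
    if g_s <= g_dc_nS or g_s <= 0:
        raise ValueError("non-physical series conductance")
    g_m = g_s * g_dc_nS / (g_s - g_dc_nS)
    c_m = g_s ** 2 * b_nS / (omega * ((g_s - a_nS) ** 2 + b_nS ** 2))
    if c_m <= 0 or g_m < 0:
        raise ValueError("non-physical inversion result")
    return c_m, g_m, g_s


def sine_dc_decompose(current_pA, voltage_mV, spec: SinewaveSpec | None = None,
                      e_leak_mV: float = 0.0,
                      phase_offset_rad: float = 0.0) -> LockinTrace:
    """Decompose a recording into binned C_m / G_m / G_s time courses.

    Bins are one sine cycle long.  The admittance is the ratio of the
    current to the command Fourier coefficient at the sine frequency, so a
    common clock is assumed; ``phase_offset_rad`` rotates the admittance
    for imported data with instrumentation delay.
    """
    spec = spec or SinewaveSpec()
    i = np.asarray(current_pA, dtype=float)
    v = np.asarray(voltage_mV, dtype=float)
    if i.shape != v.shape:
        raise ValueError("current and voltage must have the same shape")
    npc = spec.samples_per_cycle
    nbins = i.size // npc
    if nbins < 1:
        raise ValueError("trace shorter than one sine cycle")
    dt_ms = 1e3 / spec.sample_rate_Hz

    iv = i[:nbins * npc].reshape(nbins, npc)
    vv = v[:nbins * npc].reshape(nbins, npc)
    phase = np.exp(-2j * np.pi * np.arange(npc) / npc)

    v_mean = vv.mean(axis=1)
    i_mean = iv.mean(axis=1)
    v_cplx = (vv * phase).mean(axis=1) * 2
    i_cplx = (iv * phase).mean(axis=1) * 2

    # a bin is a sine bin when its command matches the probe template
    amp = np.abs(v_cplx)
    is_sine = (np.abs(v_mean - spec.offset_mV) < 0.02 * spec.amplitude_pp_mV) \
        & (np.abs(amp - 0.5 * spec.amplitude_pp_mV) < 0.05 * spec.amplitude_pp_mV)

    times = (np.arange(nbins) + 0.5) * npc * dt_ms
    c_m = np.full(nbins, np.nan)
    g_m = np.full(nbins, np.nan)
    g_s = np.full(nbins, np.nan)
    valid = np.zeros(nbins, dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(is_sine, i_cplx / np.where(v_cplx == 0, np.nan, v_cplx), np.nan)
    y = y * np.exp(-1j * phase_offset_rad)
    dv = v_mean - e_leak_mV
    g_dc = np.where(np.abs(dv) > 1e-9, i_mean / dv, np.nan)

    for k in np.flatnonzero(is_sine):
        try:
            cm_k, gm_k, gs_k = invert_admittance(
                y[k].real, y[k].imag, max(g_dc[k], 0.0), spec.frequency_Hz)
        except ValueError:
            continue
        c_m[k], g_m[k], g_s[k] = cm_k * 1e3, gm_k, gs_k  # pF -> fF
        valid[k] = True

    return LockinTrace(times_ms=times, c_m_fF=c_m, g_m_nS=g_m, g_s_nS=g_s,
                       valid=valid, stimulation=~is_sine, spec=spec)


def lowpass(x, sample_rate_Hz: float, corner_Hz: float,
            method: str = "bessel") -> np.ndarray:
    """Low-pass filter a trace with unit DC gain.

    ``bessel``: 4-pole Bessel (smooth, monotone step response), applied
    causally — the analog-style display filter for lock-in outputs.
    ``fft``: brick-wall spectral cut (used for ERG sweeps).
    """
    x = np.asarray(x, dtype=float)
    nyq = sample_rate_Hz / 2
    if corner_Hz >= nyq:
        raise ValueError("corner frequency must be below Nyquist")
    if corner_Hz <= 0:
        raise ValueError("corner frequency must be positive")
    if method == "bessel":
        sos = signal.bessel(4, corner_Hz, fs=sample_rate_Hz, output="sos",
                            norm="mag")
        # prepend a reflected ramp so the filter starts from the trace level
        pad = min(x.size - 1, int(4 * sample_rate_Hz / corner_Hz))
        xp = np.concatenate([np.full(pad, x[0]), x])
        return signal.sosfilt(sos, xp)[pad:]
    if method == "fft":
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate_Hz)
        spec[freqs > corner_Hz] = 0.0
        return np.fft.irfft(spec, n=x.size)
    raise ValueError(f"unknown method {method!r}")
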