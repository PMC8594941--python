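"""Synthetic whole-cell recordings: the generator behind the analysis chain.

``synthesize_recording`` renders a protocol on a fine internal time base,
drives the channel and fusion models, folds the fused capacitance and the
Cl(Ca) conductance into the passive-circuit ODE (so the lock-in
decomposition is exercised honestly rather than fed its own answer), and
decimates to the protocol sampling rate before adding measurement noise.

Bundles carry ground-truth channels (clean Ca2+ current, the true dC_m
trajectory) and a compensated current — total minus the passive-only
response — standing in for the amplifier's capacitance/leak compensation
that real kinetic analyses rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .channels import clca_conductance, simulate_ica
from .circuit import simulate_clamp_current
from .presets import GenotypePreset, get_preset
from .protocols import VoltageProtocol, build_iv_protocol, \
    build_step_series_protocol
from .release import simulate_fusion

#: internal integration step, ms — well below the charging time of even a
#: low-R_a cell (5 us), keeping the piecewise-linear sine error < 0.5%
INTERNAL_DT_MS = 0.001


@dataclass
class RecordingBundle:
    """A synthetic (or imported) voltage-clamp experiment."""

    protocol: VoltageProtocol
    times_ms: np.ndarray
    v_cmd_mV: np.ndarray
    i_total_pA: np.ndarray
    genotype: str = "wt"
    egta_mM: float = 10.0
    noise_sd_pA: float = 0.0
    seed: int | None = None
    #: amplifier-style compensated current (total minus passive response)
    i_compensated_pA: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])

    @property
    def sample_rate_Hz(self) -> float:
        return 1e3 / self.dt_ms

    def episodes(self) -> list[dict]:
        return self.protocol.step_episodes()

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.times_ms, "v_mV": self.v_cmd_mV,
                "i_pA": self.i_total_pA}
        if self.i_compensated_pA is not None:
            cols["i_comp_pA"] = self.i_compensated_pA
        for key in ("i_ca_pA", "delta_cm_fF"):
            if key in self.ground_truth:
                cols[key] = self.ground_truth[key]
        return pd.DataFrame(cols)


def synthesize_recording(preset: GenotypePreset | str,
                         protocol: VoltageProtocol,
                         egta_mM: float = 10.0,
                         noise_sd_pA: float = 0.0,
                         seed: int = 0,
                         internal_dt_ms: float = INTERNAL_DT_MS
                         ) -> RecordingBundle:
    """Compose circuit, channel and release models into a full recording."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    dt = 1e3 / protocol.sample_rate_Hz
    oversample = max(1, int(round(dt / internal_dt_ms)))
    dt_f = dt / oversample

    t_f, v_f = protocol.render(dt_f)

    i_ca = simulate_ica(v_f, dt_f, preset.cav, egta_mM,
                        v_rest_mV=protocol.holding_mV)

    clca = dataclasses.replace(preset.clca, enabled=egta_mM <= 0.5)
    g_cl = clca_conductance(v_f, dt_f, clca, preset.cav)

    # per-episode fusion with instantaneous pool refill; the drive is the
    # evoked charge (step plus 5 ms of tail) — the standing dark current at
    # rest is balanced by refill and does not deplete the pool
    delta_cm = np.zeros_like(t_f)
    episodes = protocol.step_episodes()
    bounds = [int(round(ep["t_start_ms"] / dt_f)) for ep in episodes]
    bounds.append(t_f.size)
    base = 0.0
    for k, ep in enumerate(episodes):
        a, b = bounds[k], bounds[k + 1]
        drive = i_ca[a:b].copy()
        cut = min(int(round((ep["t_end_ms"] + 5.0 - ep["t_start_ms"]) / dt_f)),
                  b - a)
        drive[cut:] = 0.0
        delta_cm[a:b] = base + simulate_fusion(drive, dt_f, preset.release)
        base = delta_cm[b - 1] if b > a else base
    c_m_t = preset.circuit.c_m_pF + delta_cm * 1e-3  # fF -> pF

    common = dict(dt_ms=dt_f, oversample=1)
    i_full = simulate_clamp_current(preset.circuit, v_f, c_m=c_m_t,
                                    g_extra=g_cl, e_extra_mV=clca.e_cl_mV,
                                    i_inj=i_ca, **common)
    # compensation reference shares the capacitance trajectory (an amplifier
    # tracking C-slow) so the compensated current isolates I_Ca + I_Cl(Ca)
    i_passive = simulate_clamp_current(preset.circuit, v_f, c_m=c_m_t, **common)

    sl = slice(None, None, oversample)
    t, v = t_f[sl], v_f[sl]
    i_total = i_full[sl].copy()
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        i_total = i_total + rng.normal(0.0, noise_sd_pA, i_total.size)

    return RecordingBundle(
        protocol=protocol, times_ms=t, v_cmd_mV=v, i_total_pA=i_total,
        genotype=preset.label, egta_mM=egta_mM, noise_sd_pA=noise_sd_pA,
        seed=seed, i_compensated_pA=(i_full - i_passive)[sl],
        ground_truth={
            "i_ca_pA": i_ca[sl], "delta_cm_fF": delta_cm[sl],
            "episodes": episodes,
        })


def synthesize_step_series(genotype: str = "wt", egta_mM: float = 10.0,
                           durations_ms=None, noise_sd_pA: float = 0.0,
                           seed: int = 0) -> RecordingBundle:
    """Convenience wrapper: the default capacitance step-series experiment."""
    kwargs = {} if durations_ms is None else {"durations_ms": durations_ms}
    return synthesize_recording(get_preset(genotype),
                                build_step_series_protocol(**kwargs),
                                egta_mM=egta_mM, noise_sd_pA=noise_sd_pA,
                                seed=seed)


def synthesize_iv_series(genotype: str = "wt", egta_mM: float = 10.0,
                         noise_sd_pA: float = 0.0, seed: int = 0,
                         **protocol_kw) -> RecordingBundle:
    """Convenience wrapper: the 10 ms I-V family at 50 kHz."""
    return synthesize_recording(get_preset(genotype),
                                build_iv_protocol(**protocol_kw),
                                egta_mM=egta_mM, noise_sd_pA=noise_sd_pA,
                                seed=seed)


# ---------------------------------------------------------------------------
# I/O: columnar text and HDF5 containers


def save_bundle_tsv(bundle: RecordingBundle, path: str) -> None:
    bundle.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def save_bundle_h5(bundle: RecordingBundle, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs.update({"genotype": bundle.genotype,
                         "egta_mM": bundle.egta_mM,
                         "noise_sd_pA": bundle.noise_sd_pA,
                         "seed": -1 if bundle.seed is None else bundle.seed,
                         "protocol_yaml": bundle.protocol.to_yaml()})
        fh.create_dataset("times_ms", data=bundle.times_ms)
        fh.create_dataset("v_cmd_mV", data=bundle.v_cmd_mV)
        fh.create_dataset("i_total_pA", data=bundle.i_total_pA)
        if bundle.i_compensated_pA is not None:
            fh.create_dataset("i_compensated_pA", data=bundle.i_compensated_pA)
        gt = fh.create_group("ground_truth")
        for key in ("i_ca_pA", "delta_cm_fF"):
            if key in bundle.ground_truth:
                gt.create_dataset(key, data=bundle.ground_truth[key])


def load_bundle_h5(path: str) -> RecordingBundle:
    with h5py.File(path, "r") as fh:
        protocol = VoltageProtocol.from_yaml(fh.attrs["protocol_yaml"])
        seed = int(fh.attrs["seed"])
        gt = {k: fh["ground_truth"][k][...] for k in fh["ground_truth"]}
        gt["episodes"] = protocol.step_episodes()
        return RecordingBundle(
            protocol=protocol,
            times_ms=fh["times_ms"][...],
            v_cmd_mV=fh["v_cmd_mV"][...],
            i_total_pA=fh["i_total_pA"][...],
            genotype=str(fh.attrs["genotype"]),
            egta_mM=float(fh.attrs["egta_mM"]),
            noise_sd_pA=float(fh.attrs["noise_sd_pA"]),
            seed=None if seed < 0 else seed,
            i_compensated_pA=(fh["i_compensated_pA"][...]
                              if "i_compensated_pA" in fh else None),
            ground_truth=gt,
        )
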