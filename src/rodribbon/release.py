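"""Charge-driven depletion of the readily releasable pool (RRP).

Release is driven by the cumulative Ca2+ charge Q(t): each e-fold of
Q_e depletes the remaining pool, so the fused capacitance is

    dC_m(t) = c_sv * N_rrp * (1 - exp(-Q(t - offset) / Q_e))

where the offset carries the residual fusion latency beyond the channel
activation delay.  Pool refill between stimulations (8 s apart) is treated
as instantaneous, so each episode starts from a full pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ReleaseParams:
    """Releasable-pool parameters (wild-type defaults)."""

    n_rrp: int = 87
    c_sv_aF: float = 37.6
    q_e_fC: float = 4.66
    fusion_delay_ms: float = 0.2

    def __post_init__(self) -> None:
        if self.n_rrp < 0 or int(self.n_rrp) != self.n_rrp:
            raise ValueError("N_rrp must be a non-negative integer")
        if self.c_sv_aF <= 0 or self.q_e_fC <= 0:
            raise ValueError("c_sv and Q_e must be positive")

    @property
    def c_sv_fF(self) -> float:
        return self.c_sv_aF * 1e-3

    @property
    def max_delta_cm_fF(self) -> float:
        return self.n_rrp * self.c_sv_fF


def pool_survival(cumulative_charge_fC, params: ReleaseParams | None = None):
    """Vesicles remaining (real-valued) after a cumulative Ca2+ charge."""
    params = params or ReleaseParams()
    q = np.asarray(cumulative_charge_fC, dtype=float)
    if np.any(q < 0):
        raise ValueError("cumulative charge must be non-negative")
    out = params.n_rrp * np.exp(-q / params.q_e_fC)
    return float(out) if np.ndim(cumulative_charge_fC) == 0 else out


def pool_released(cumulative_charge_fC, params: ReleaseParams | None = None):
    """Vesicles released; N_rrp minus :func:`pool_survival`."""
    params = params or ReleaseParams()
    return params.n_rrp - pool_survival(cumulative_charge_fC, params)


def simulate_fusion(i_ca_pA, dt_ms: float,
                    params: ReleaseParams | None = None) -> np.ndarray:
    """Cumulative evoked dC_m (fF) time course driven by a Ca2+ current.

    The running charge integral is time-shifted by the fusion latency, so
    the capacitance rise lags Ca2+ entry but its asymptote depends only on
    the total charge.  Monotone non-decreasing, bounded by N_rrp * c_sv.
    """
    params = params or ReleaseParams()
    i = np.abs(np.asarray(i_ca_pA, dtype=float))
    # trapezoidal running integral, fC
    q = np.concatenate(([0.0], np.cumsum(0.5 * (i[1:] + i[:-1]) * dt_ms)))
    shift = min(int(round(params.fusion_delay_ms / dt_ms)), q.size)
    if shift > 0:
        shifted = np.zeros_like(q)
        shifted[shift:] = q[:q.size - shift]
        q = shifted
    return params.max_delta_cm_fF * (1.0 - np.exp(-q / params.q_e_fC))


def dcm_to_sv(delta_cm_fF: float, params: ReleaseParams | None = None) -> int:
    """Convert an evoked capacitance jump to a synaptic-vesicle count."""
    params = params or ReleaseParams()
    if delta_cm_fF < 0:
        raise ValueError("dC_m must be non-negative (endocytosis not counted)")
    return int(round(delta_cm_fF / params.c_sv_fF))
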