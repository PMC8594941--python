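"""Phenomenological Ca_v1.4 and Ca2+-activated Cl- current models.

The calcium current is described the way the recordings are analysed in
practice: an ohmic driving force (V - V_rev) gated by a Boltzmann
activation curve, a single-exponential activation time course with a fixed
onset delay, a slow partial inactivation gate, and first-order deactivation
on repolarisation.  Activation speed depends on voltage and on the cytosolic
Ca2+ buffer (EGTA): weak buffering accelerates channel opening
(facilitation), which the model carries as two sets of tau_activ anchor
points interpolated log-linearly in voltage.

The Cl(Ca) current is a conductance that develops in proportion to the
calcium influx, with slow activation during the step and a multi-ms inward
tail at rest; it is enabled only under weak (<= 0.5 mM EGTA) buffering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import CA_ION_CHARGE_C

#: tau_activ anchor points, ms, keyed by EGTA (mM) then step voltage (mV).
TAU_ACTIV_ANCHORS = {
    10.0: {-30.0: 1.09, -20.0: 0.489, 0.0: 0.18},
    0.5: {-30.0: 0.55, -20.0: 0.310, 0.0: 0.16},
}

_V_RANGE = (-40.0, 30.0)


@dataclass
class CavParams:
    """Ca_v1.4 model parameters (wild-type defaults, 2 mM external Ca)."""

    g_max_pA_per_mV: float = 0.30
    v_rev_mV: float = 44.6
    v_half_mV: float = -24.0
    slope_mV: float = -6.2
    activation_delay_ms: float = 0.25
    inact_fraction: float = 0.31
    tau_inact_ms: float = 19.46
    #: inactivation engages only after the current has peaked; the fitted
    #: peaks then sit at the fully-activated level, as in the recordings
    inact_onset_ms: float = 3.5
    tau_deactiv_ms: float = 0.20
    #: weak-buffer facilitation of activation kinetics; when False the
    #: low-EGTA anchor set is used for every condition (ribbonless rods).
    facilitation: bool = True
    tau_activ_anchors: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in TAU_ACTIV_ANCHORS.items()})

    def __post_init__(self) -> None:
        if self.g_max_pA_per_mV <= 0:
            raise ValueError("G_max must be positive")
        if not 0 <= self.inact_fraction < 1:
            raise ValueError("inact_fraction must be in [0, 1)")
        if min(self.tau_inact_ms, self.tau_deactiv_ms) <= 0:
            raise ValueError("time constants must be positive")

    def activation(self, v_mV) -> np.ndarray | float:
        """Steady-state open fraction (Boltzmann).

        With the conventional negative slope factor the curve rises with
        depolarisation: m_inf = 1 / (1 + exp((V - V_half) / k)).
        """
        return 1.0 / (1.0 + np.exp((np.asarray(v_mV, dtype=float)
                                    - self.v_half_mV) / self.slope_mV))

    def i_inf(self, v_mV) -> np.ndarray | float:
        """Fully-activated current (pA) before inactivation."""
        v = np.asarray(v_mV, dtype=float)
        return self.g_max_pA_per_mV * (v - self.v_rev_mV) * self.activation(v)


def boltzmann_iv(v_mV, params, form: str = "modified",
                 i_min: float | None = None, i_max: float | None = None):
    """Evaluate the Boltzmann I-V closed forms used to fit peak currents.

    ``modified``: I = G_max (V - V_rev) / (1 + exp((V - V_half)/k)) — the
    conductance form covering the full voltage range.
    ``simple``: I = I_max + (I_min - I_max) / (1 + exp((V - V_half)/k)) — a
    plain sigmoid between two current levels (foot of the I-V curve).
    """
    v = np.asarray(v_mV, dtype=float)
    if params.slope_mV == 0:
        raise ValueError("slope factor k must be non-zero")
    gate = 1.0 / (1.0 + np.exp((v - params.v_half_mV) / params.slope_mV))
    if form == "modified":
        out = params.g_max_pA_per_mV * (v - params.v_rev_mV) * gate
    elif form == "simple":
        if i_min is None or i_max is None:
            raise ValueError("simple form needs i_min and i_max")
        out = i_max + (i_min - i_max) * gate
    else:
        raise ValueError(f"unknown form {form!r}")
    return float(out) if np.ndim(v_mV) == 0 else out


def tau_activation(v_mV: float, egta_mM: float,
                   params: CavParams | None = None) -> float:
    """Activation time constant (ms) at a step voltage and EGTA level.

    Anchor values are returned exactly; between anchors tau is interpolated
    linearly in log(tau) (order-preserving, no overshoot), and outside the
    anchor span the edge segment's log-slope is extended.
    """
    if not _V_RANGE[0] <= v_mV <= _V_RANGE[1]:
        raise ValueError(f"step voltage {v_mV} mV outside {_V_RANGE}")
    params = params or CavParams()
    anchors = params.tau_activ_anchors
    if egta_mM not in anchors:
        raise ValueError(f"egta_mM must be one of {sorted(anchors)}")
    key = egta_mM if params.facilitation else min(anchors)
    table = anchors[key]
    vs = np.array(sorted(table))
    logt = np.log([table[v] for v in vs])
    if v_mV <= vs[0]:
        slope = (logt[1] - logt[0]) / (vs[1] - vs[0])
        return float(np.exp(logt[0] + slope * (v_mV - vs[0])))
    if v_mV >= vs[-1]:
        slope = (logt[-1] - logt[-2]) / (vs[-1] - vs[-2])
        return float(max(np.exp(logt[-1] + slope * (v_mV - vs[-1])), 0.05))
    return float(np.exp(np.interp(v_mV, vs, logt)))


def _command_spans(v: np.ndarray, min_plateau: int,
                   threshold_mV: float) -> list[tuple[int, int, float | None]]:
    """Split a command into depolarising plateaus and rest spans.

    A plateau is a maximal constant run of at least ``min_plateau`` samples
    above ``threshold_mV``; everything else (holds, sine segments, sub-
    resolution glitches) is coalesced into rest spans with level None.
    """
    edges = np.flatnonzero(np.diff(v) != 0) + 1
    bounds = np.concatenate(([0], edges, [v.size]))
    spans: list[tuple[int, int, float | None]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        level = float(v[a])
        if b - a >= min_plateau and level > threshold_mV:
            spans.append((int(a), int(b), level))
        elif spans and spans[-1][2] is None:
            spans[-1] = (spans[-1][0], int(b), None)
        else:
            spans.append((int(a), int(b), None))
    return spans


def simulate_ica(v_cmd, dt_ms: float, params: CavParams | None = None,
                 egta_mM: float = 10.0, v_rest_mV: float = -70.0,
                 activation_threshold_mV: float = -60.0) -> np.ndarray:
    """Ca2+ current (pA) for a piecewise-constant command voltage.

    Depolarising plateaus above ``activation_threshold_mV`` engage the
    activation gate after a fixed onset delay, with the EGTA-dependent
    tau_activ(V); repolarisation relaxes the gate with tau_deactiv through
    the instantaneous driving force (the tail current).  The inactivation
    gate h(t) = 1 - f (1 - exp(-t/tau_inact)) runs while depolarised and
    resets between stimulation episodes.
    """
    params = params or CavParams()
    v = np.asarray(v_cmd, dtype=float)
    n = v.size
    m = np.zeros(n)  # open fraction trace
    h = np.ones(n)
    m_state = float(params.activation(v_rest_mV))
    min_plateau = max(2, int(round(0.1 / dt_ms)))  # ignore sub-0.1 ms "runs"

    for start, stop, level in _command_spans(v, min_plateau,
                                             activation_threshold_mV):
        t_loc = np.arange(stop - start) * dt_ms
        if level is not None:
            tau = tau_activation(min(max(level, _V_RANGE[0]), _V_RANGE[1]),
                                 egta_mM, params)
            m_inf = float(params.activation(level))
            gate = np.where(
                t_loc < params.activation_delay_ms, m_state,
                m_inf - (m_inf - m_state)
                * np.exp(-(t_loc - params.activation_delay_ms) / tau))
            m[start:stop] = gate
            t_in = np.maximum(t_loc - params.inact_onset_ms, 0.0)
            h[start:stop] = 1.0 - params.inact_fraction * (
                1.0 - np.exp(-t_in / params.tau_inact_ms))
            m_state = float(gate[-1])
        else:
            m_rest = float(params.activation(v_rest_mV))
            m[start:stop] = m_rest + (m_state - m_rest) * np.exp(
                -t_loc / params.tau_deactiv_ms)
            m_state = float(m[stop - 1])
            # h recovers between episodes (inter-stimulus interval >> tau)
    return params.g_max_pA_per_mV * m * h * (v - params.v_rev_mV)


@dataclass
class ClCaParams:
    """Ca2+-activated (TMEM16-type) Cl- conductance parameters."""

    enabled: bool = True
    e_cl_mV: float = -51.0
    #: tail conductance per unit peak Ca2+ current, nS/pA
    coupling_nS_per_pA: float = 0.17
    #: outward rectification: fraction of the tail conductance available
    #: during the depolarising step (TMEM16 currents rectify strongly)
    depol_gain: float = 0.05
    tau_act_ms: float = 4.0
    tau_deact_ms: float = 5.0
    #: gate cooperativity; >1 gives the sigmoidal onset expected when the
    #: channels respond to slowly accumulating bulk Ca2+
    act_power: int = 2
    # empirical tail I-V descriptors (fit reference values)
    v_half_mV: float = -20.4
    slope_mV: float = -5.6
    v_rev_mV: float = 35.8
    g_max_pA_per_mV: float = 1.41

    @classmethod
    def for_egta(cls, egta_mM: float, **kw) -> "ClCaParams":
        """Conductance is blocked by strong buffering (10 mM EGTA)."""
        return cls(enabled=egta_mM <= 0.5, **kw)


def clca_conductance(v_cmd, dt_ms: float, cl_params: ClCaParams,
                     cav_params: CavParams | None = None,
                     activation_threshold_mV: float = -60.0) -> np.ndarray:
    """Cl(Ca) conductance waveform g(t) in nS for a piecewise-constant command.

    The target conductance during a step scales with the normalised peak
    Ca2+ current at that voltage; it develops with tau_act and relaxes with
    tau_deact after repolarisation.
    """
    v = np.asarray(v_cmd, dtype=float)
    n = v.size
    g = np.zeros(n)
    if not cl_params.enabled:
        return g
    cav = cav_params or CavParams()
    power = max(int(cl_params.act_power), 1)
    # internal gate a in [0, 1]; g = g_inf * a^power, so the onset is
    # sigmoidal while the tail still relaxes with tau_deact
    a_state, ginf_state = 0.0, 0.0
    min_plateau = max(2, int(round(0.1 / dt_ms)))
    for start, stop, level in _command_spans(v, min_plateau,
                                             activation_threshold_mV):
        t_loc = np.arange(stop - start) * dt_ms
        if level is not None:
            ginf_state = cl_params.coupling_nS_per_pA * abs(float(cav.i_inf(level)))
            a = 1.0 - (1.0 - a_state) * np.exp(-t_loc / cl_params.tau_act_ms)
        else:
            a = a_state * np.exp(-t_loc / (power * cl_params.tau_deact_ms))
        g[start:stop] = ginf_state * a ** power
        a_state = float(a[-1])
    # outward rectification: only a fraction of the conductance is
    # available when the driving force is outward (V above E_Cl)
    return g * np.where(v > cl_params.e_cl_mV, cl_params.depol_gain, 1.0)


def simulate_icl(v_cmd, dt_ms: float, cl_params: ClCaParams,
                 cav_params: CavParams | None = None) -> np.ndarray:
    """Cl(Ca) current (pA): outward during the step, inward tail at rest.

    Zero everywhere when the conductance is disabled (10 mM EGTA) or when
    no Ca2+ enters (steps below the activation range).
    """
    v = np.asarray(v_cmd, dtype=float)
    g = clca_conductance(v_cmd, dt_ms, cl_params, cav_params)
    return g * (v - cl_params.e_cl_mV)


def integrate_qca(current_pA, dt_ms: float | None = None,
                  times_ms=None, window_ms: tuple[float, float] | None = None
                  ) -> float:
    """Net charge magnitude (fC) carried by a current over a time window.

    Trapezoidal integration; pA * ms = fC.
    """
    i = np.asarray(current_pA, dtype=float)
    if times_ms is None:
        if dt_ms is None:
            raise ValueError("need dt_ms or times_ms")
        times_ms = np.arange(i.size) * dt_ms
    t = np.asarray(times_ms, dtype=float)
    if window_ms is not None:
        lo, hi = window_ms
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ValueError("integration window outside trace")
        sel = (t >= lo) & (t <= hi)
        t, i = t[sel], i[sel]
    return float(abs(np.trapezoid(i, t)))


def charge_to_ions(charge_fC: float,
                   ion_charge_C: float = CA_ION_CHARGE_C) -> int:
    """Number of divalent Ca2+ ions carrying a given charge (rounded)."""
    if charge_fC < 0:
        raise ValueError("charge must be non-negative")
    return int(round(charge_fC * 1e-15 / ion_charge_C))
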