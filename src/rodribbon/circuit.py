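"""Three-element equivalent circuit of a voltage-clamped cell.

The model is the standard patch-clamp circuit: a pipette series conductance
G_s (1/R_a) in series with the membrane, which is a capacitance C_m in
parallel with a leak conductance G_m (reversal E_leak).  Units follow the
package convention (mV, pA, nS, pF, ms), so tau = C_m / (G_s + G_m) is in ms.

The integrator treats the command voltage as piecewise linear between
samples and the circuit coefficients as constant per step, for which the
one-step update is exact.  Because the update is a first-order linear
recurrence it is evaluated with a vectorised IIR filter when the
coefficients are constant, falling back to a python loop on spans where
C_m(t) or an extra conductance varies (vesicle fusion, Cl(Ca) tails).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter


@dataclass
class CircuitState:
    """Passive cell + pipette parameters.

    C_m in pF, conductances in nS, potentials in mV.  G_s = 1/R_a; a 30 MOhm
    access resistance is G_s ~ 33.7 nS.
    """

    c_m_pF: float = 1.02
    g_s_nS: float = 1e3 / 29.7
    g_m_nS: float = 0.5
    e_leak_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.c_m_pF <= 0 or self.g_s_nS <= 0 or self.g_m_nS < 0:
            raise ValueError("require C_m > 0, G_s > 0, G_m >= 0")

    @property
    def r_a_MOhm(self) -> float:
        return 1e3 / self.g_s_nS

    @property
    def tau_ms(self) -> float:
        """Clamp charging time constant C_m / (G_s + G_m)."""
        return self.c_m_pF / (self.g_s_nS + self.g_m_nS)


def rc_time_constant(r_a_MOhm: float, c_m_pF: float) -> float:
    """Membrane charging time constant R_a * C_m, in microseconds."""
    if r_a_MOhm <= 0 or c_m_pF <= 0:
        raise ValueError("R_a and C_m must be positive")
    return r_a_MOhm * c_m_pF  # MOhm * pF = us


def circuit_admittance(circuit: CircuitState, frequency_Hz: float) -> complex:
    """Complex admittance (in nS) seen by the amplifier at a given frequency.

    Y(w) = G_s (G_m + i w C_m) / (G_s + G_m + i w C_m); the DC limit is the
    series combination G_s G_m / (G_s + G_m).
    """
    if frequency_Hz < 0:
        raise ValueError("frequency must be >= 0")
    omega = 2e-3 * np.pi * frequency_Hz  # rad/ms
    gs, gm, cm = circuit.g_s_nS, circuit.g_m_nS, circuit.c_m_pF
    y_mem = gm + 1j * omega * cm
    return gs * y_mem / (gs + y_mem)


def _exact_step_coeffs(lam: float, dt: float) -> tuple[float, float, float]:
    """Coefficients of the exact one-step update for dv/dt = -lam v + f(t).

    With f linear on the step, v[k+1] = a v[k] + c0 f[k] + c1 f[k+1].
    """
    x = lam * dt
    a = np.exp(-x)
    if x > 1e-4:
        phi1 = (1.0 - a) / lam           # int e^{-lam(dt-s)} ds
        phi2 = (dt - phi1) / (lam * dt)  # weight of the linear ramp
    else:  # series expansion for lam -> 0
        phi1 = dt * (1 - x / 2 + x * x / 6)
        phi2 = dt * (0.5 - x / 3 + x * x / 8)
    c1 = phi2
    c0 = phi1 - phi2
    return a, c0, c1


def _integrate_vm(v_cmd: np.ndarray, dt_ms: float, circuit: CircuitState,
                  c_m: np.ndarray | None = None,
                  g_extra: np.ndarray | None = None,
                  e_extra_mV: float = 0.0,
                  i_inj: np.ndarray | None = None,
                  v0: float | None = None) -> np.ndarray:
    """Membrane potential time course under clamp.

    C(t) dVm/dt = G_s (Vc - Vm) - G_m (Vm - E_leak)
                  - g_x(t) (Vm - E_x) - I_inj(t)

    ``c_m``/``g_extra``/``i_inj`` may be arrays (same length as v_cmd) for
    time-varying membrane properties; scalars/None select the fast path.
    """
    v_cmd = np.asarray(v_cmd, dtype=float)
    n = v_cmd.size
    gs, gm, e_l = circuit.g_s_nS, circuit.g_m_nS, circuit.e_leak_mV
    if v0 is None:
        # steady state for the first command sample
        g_x0 = 0.0 if g_extra is None else float(np.asarray(g_extra).flat[0])
        i0 = 0.0 if i_inj is None else float(np.asarray(i_inj).flat[0])
        v0 = (gs * v_cmd[0] + gm * e_l + g_x0 * e_extra_mV - i0) / (gs + gm + g_x0)

    varying = (
        (c_m is not None and np.ndim(c_m) > 0 and np.ptp(c_m) > 0)
        or (g_extra is not None and np.ndim(g_extra) > 0 and np.ptp(g_extra) > 0)
    )
    cm_arr = np.broadcast_to(
        np.asarray(circuit.c_m_pF if c_m is None else c_m, dtype=float), (n,))
    gx_arr = np.broadcast_to(
        np.asarray(0.0 if g_extra is None else g_extra, dtype=float), (n,))
    ii_arr = np.broadcast_to(
        np.asarray(0.0 if i_inj is None else i_inj, dtype=float), (n,))

    f = (gs * v_cmd + gm * e_l + gx_arr * e_extra_mV - ii_arr) / cm_arr

    if not varying:
        lam = (gs + gm + gx_arr[0]) / cm_arr[0]
        a, c0, c1 = _exact_step_coeffs(lam, dt_ms)
        # v[k] = a v[k-1] + c1 f[k] + c0 f[k-1]  -> IIR filter
        zi = np.array([a * v0 + c0 * f[0]])
        out, _ = lfilter([c1, c0], [1.0, -a], f, zi=zi)
        out[0] = v0
        return out

    # time-varying coefficients: first-order linear scan, evaluated in
    # renormalised blocks (cumulative products stay in exp range)
    lam = (gs + gm + gx_arr) / cm_arr
    x = lam * dt_ms
    a = np.exp(-x)
    phi1 = (1.0 - a) / lam
    phi2 = (dt_ms - phi1) / x
    b = (phi1 - phi2) * np.concatenate(([f[0]], f[:-1])) + phi2 * f
    loga = -x

    v = np.empty(n)
    v[0] = v0
    block = max(16, min(1024, int(np.ceil(20.0 / max(float(np.mean(x)), 1e-12)))))
    prev = v0
    for s in range(1, n, block):
        e = min(s + block, n)
        logp = np.cumsum(loga[s:e])
        p = np.exp(logp)
        w = b[s:e] * np.exp(-logp)
        v[s:e] = p * (prev + np.cumsum(w))
        prev = v[e - 1]
    return v


def simulate_clamp_current(circuit: CircuitState, v_cmd, dt_ms: float,
                           c_m=None, g_extra=None, e_extra_mV: float = 0.0,
                           i_inj=None, oversample: int = 1,
                           times_ms: np.ndarray | None = None) -> np.ndarray:
    """Pipette current (pA) in response to a command voltage series.

    The measured current is I = G_s (Vc - Vm).  ``oversample`` refines the
    internal time base (linear command interpolation) and decimates back,
    which is needed when the command has curvature between samples (sine
    segments) relative to the ~30 us charging time.

    ``times_ms`` may be passed for validation; it must be uniform with
    spacing ``dt_ms``.
    """
    v_cmd = np.asarray(v_cmd, dtype=float)
    if times_ms is not None:
        dts = np.diff(np.asarray(times_ms, dtype=float))
        if dts.size and (np.ptp(dts) > 1e-9 or abs(dts[0] - dt_ms) > 1e-9):
            raise ValueError("non-uniform time base")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")

    def _up(x):
        if x is None or np.ndim(x) == 0:
            return x
        n = np.asarray(x).size
        idx = np.arange((n - 1) * oversample + 1) / oversample
        return np.interp(idx, np.arange(n), np.asarray(x, dtype=float))

    if oversample == 1:
        vm = _integrate_vm(v_cmd, dt_ms, circuit, c_m, g_extra, e_extra_mV, i_inj)
        return circuit.g_s_nS * (v_cmd - vm)
    vm_f = _integrate_vm(_up(v_cmd), dt_ms / oversample, circuit,
                         _up(c_m), _up(g_extra), e_extra_mV, _up(i_inj))
    vm = vm_f[::oversample]
    return circuit.g_s_nS * (v_cmd - vm)
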