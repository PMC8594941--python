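"""The measurement chain: dC_m quantification, kinetic and I-V fits,
charge relations, pool-size estimation and group statistics.

Every curve fit runs through lmfit (Levenberg-Marquardt) with data-driven
initial guesses and a small multistart on time constants; estimates come
back in a :class:`FitResult` with standard errors, the fit window, adjusted
R-squared and a convergence flag (degenerate inputs flag rather than raise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .channels import CavParams, boltzmann_iv, integrate_qca
from .lockin import LockinTrace
from .release import ReleaseParams, dcm_to_sv
from .synth import RecordingBundle

#: averaging window on each side of a stimulation, ms
DCM_WINDOW_MS = 50.0
#: extra settling time before the post window under weak buffering, ms
CLCA_SETTLE_MS = 75.0
#: activation fits start this long after the step onset, ms
ACTIVATION_FIT_START_MS = 0.25
ACTIVATION_FIT_LEN_MS = 3.0


@dataclass
class FitResult:
    model: str
    params: dict[str, float] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)
    window: tuple[float, float] | None = None
    adj_r2: float = np.nan
    converged: bool = False
    message: str = ""

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _adj_r2(y, resid, n_par) -> float:
    y = np.asarray(y, dtype=float)
    n = y.size
    ss_res = float(np.sum(np.asarray(resid) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0 or n <= n_par + 1:
        return np.nan
    return 1.0 - (ss_res / (n - n_par - 1)) / (ss_tot / (n - 1))


def _run_fit(model: lmfit.Model, y, params, window=None, multistart_tau=None,
             **indep) -> FitResult:
    """Fit with optional 3-point multistart on a time-constant parameter."""
    best = None
    trials = [None]
    if multistart_tau is not None:
        name, t0 = multistart_tau
        trials = [(name, t0 * f) for f in (0.3, 1.0, 3.0)]
    for trial in trials:
        p = params.copy()
        if trial is not None:
            p[trial[0]].set(value=float(np.clip(trial[1], p[trial[0]].min,
                                                p[trial[0]].max)))
        try:
            res = model.fit(y, params=p, **indep)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        return FitResult(model=model.name, window=window, converged=False,
                         message="fit failed to converge")
    return FitResult(
        model=model.name,
        params={k: float(v.value) for k, v in best.params.items()},
        stderr={k: (float(v.stderr) if v.stderr is not None else np.nan)
                for k, v in best.params.items()},
        window=window,
        adj_r2=_adj_r2(y, best.residual, len(best.var_names)),
        converged=True,
    )


# ---------------------------------------------------------------------------
# capacitance quantification


def measure_delta_cm(lockin: LockinTrace, stim_start_ms: float,
                     stim_end_ms: float, egta_mM: float = 10.0,
                     window_ms: float = DCM_WINDOW_MS) -> dict[str, float]:
    """Evoked dC_m (fF): post-window mean minus pre-window mean.

    Windows are ``window_ms`` of valid, non-stimulation bins on each side;
    under 0.5 mM EGTA the post window starts 75 ms after stimulation end so
    the Cl(Ca) tail conductance has relaxed.  dG_m and dG_s are computed
    identically and reported alongside.
    """
    t = lockin.times_ms
    usable = lockin.valid & ~lockin.stimulation
    pre = usable & (t >= stim_start_ms - window_ms) & (t < stim_start_ms)
    post_start = stim_end_ms + (CLCA_SETTLE_MS if egta_mM <= 0.5 else 0.0)
    post = usable & (t >= post_start) & (t < post_start + window_ms)
    min_bins = max(3, int(0.5 * window_ms / (t[1] - t[0])))
    if pre.sum() < min_bins or post.sum() < min_bins:
        raise ValueError("insufficient valid bins around the stimulation")
    out = {}
    for name, chan in (("delta_cm_fF", lockin.c_m_fF),
                       ("delta_gm_nS", lockin.g_m_nS),
                       ("delta_gs_nS", lockin.g_s_nS)):
        out[name] = float(np.mean(chan[post]) - np.mean(chan[pre]))
    return out


def baseline_deltas(lockin: LockinTrace, sweep_starts_ms,
                    sweep_ms: float = 100.0) -> np.ndarray:
    """Baseline dC_m per 100 ms sine sweep (end minus start window means).

    Windows are 5-15 ms and 85-95 ms into each sweep.
    """
    t = lockin.times_ms
    out = []
    for s in np.atleast_1d(sweep_starts_ms):
        if s + 95.0 > t[-1] + 1e-9 or sweep_ms < 95.0:
            raise ValueError("sweep shorter than 95 ms")
        first = lockin.valid & (t >= s + 5) & (t < s + 15)
        last = lockin.valid & (t >= s + 85) & (t < s + 95)
        if first.sum() == 0 or last.sum() == 0:
            raise ValueError("no valid bins in baseline windows")
        out.append(float(np.mean(lockin.c_m_fF[last])
                         - np.mean(lockin.c_m_fF[first])))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# kinetic fits


def _exp_rise(t, i0, amp, tau):
    return i0 + amp * (1.0 - np.exp(-t / tau))


def fit_activation(times_ms, current_pA, step_start_ms: float,
                   step_end_ms: float, v_step_mV: float | None = None,
                   egta_mM: float = 10.0,
                   start_offset_ms: float = ACTIVATION_FIT_START_MS,
                   fit_len_ms: float | None = None) -> FitResult:
    """Single-exponential fit of Ca2+-current onset.

    The window opens ``start_offset_ms`` after the step (past the onset
    delay and the clamp transient) and runs 3 ms — shortened to 2 ms under
    0.5 mM EGTA at step voltages of -10 mV and above, where the Cl(Ca)
    current intrudes.  Returns tau_activ and the asymptote as peak-I_Ca.
    """
    t = np.asarray(times_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if fit_len_ms is None:
        fit_len_ms = ACTIVATION_FIT_LEN_MS
        if egta_mM <= 0.5 and v_step_mV is not None and v_step_mV >= -10.0:
            fit_len_ms = 2.0
    lo = step_start_ms + start_offset_ms
    hi = min(step_end_ms, lo + fit_len_ms)
    # cap the window just past the current extremum so slow inactivation
    # (or intruding Cl current) does not drag the asymptote estimate
    span_sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if span_sel.sum() >= 5:
        seg = np.asarray(current_pA, dtype=float)[span_sel]
        t_ext = t[span_sel][int(np.argmax(np.abs(seg - seg[0])))]
        hi = min(hi, max(t_ext + 0.25, lo + 0.5))
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if sel.sum() < 5:
        return FitResult("activation", window=(lo, hi), converged=False,
                         message="window too short")
    tw, iw = t[sel] - lo, i[sel]
    span = iw[-1] - iw[0]
    if abs(span) < 1e-6 and np.ptp(iw) < 1e-6:
        return FitResult("activation", window=(lo, hi), converged=False,
                         message="flat trace")
    model = lmfit.Model(_exp_rise, name="activation")
    p = model.make_params()
    # tau seed from the 10-90% rise time of the windowed data
    frac = (iw - iw[0]) / span if span != 0 else np.zeros_like(iw)
    t10 = tw[np.searchsorted(np.clip(frac, 0, 1), 0.1)] if span != 0 else tw[1]
    tau0 = max(float(t10) * 2.0, 2 * (tw[1] - tw[0]))
    p["i0"].set(value=float(iw[0]))
    p["amp"].set(value=float(span) if span != 0 else 1.0)
    p["tau"].set(value=tau0, min=1e-4, max=50.0)
    res = _run_fit(model, iw, window=(lo, hi),
                   multistart_tau=("tau", tau0), params=p, t=tw)
    if res.converged:
        base_sel = (t >= step_start_ms - 5.0) & (t < step_start_ms)
        baseline = float(np.median(i[base_sel])) if base_sel.any() else 0.0
        res.params["tau_activ_ms"] = res.params.pop("tau")
        # the current amplitude is the fitted asymptote relative to the
        # pre-step holding level (i0 may absorb part of a fast rise)
        res.params["peak_i_pA"] = (res.params["i0"] + res.params["amp"]
                                   - baseline)
        res.stderr["tau_activ_ms"] = res.stderr.pop("tau")
        res.stderr["peak_i_pA"] = res.stderr["amp"]
    return res


def measure_tail(times_ms, current_pA, repol_ms: float,
                 search_ms: float = 0.5) -> float:
    """Tail amplitude (pA): extremal baseline-subtracted current within
    0.5 ms of repolarisation.  Baseline is the pre-step holding level of
    the (compensated) trace.
    """
    t = np.asarray(times_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if t[-1] < repol_ms + 1.0:
        raise ValueError("trace must extend >= 1 ms past repolarisation")
    base_sel = (t >= repol_ms - 25.0) & (t < repol_ms - 20.0)
    base = float(np.median(i[base_sel])) if base_sel.any() else 0.0
    # skip one sample so the instant of the voltage edge itself is excluded
    sel = (t > repol_ms + 1e-9) & (t <= repol_ms + search_ms)
    if not sel.any():
        return 0.0
    seg = i[sel] - base
    return float(seg[np.argmax(np.abs(seg))])


def _exp_decay(t, plateau, amp, tau):
    return plateau + amp * np.exp(-t / tau)


def fit_inactivation(times_ms, current_pA, window_ms: tuple[float, float]
                     ) -> FitResult:
    """Single-exponential decay from the current peak to the window end."""
    t = np.asarray(times_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    if sel.sum() < 8:
        return FitResult("inactivation", window=window_ms, converged=False,
                         message="window too short")
    tw, iw = t[sel], i[sel]
    k_peak = int(np.argmax(np.abs(iw)))
    tw, iw = tw[k_peak:] - tw[k_peak], iw[k_peak:]
    if tw.size < 8 or np.ptp(iw) < 1e-9:
        return FitResult("inactivation", window=window_ms, converged=False,
                         message="no decay after peak")
    model = lmfit.Model(_exp_decay, name="inactivation")
    p = model.make_params()
    p["plateau"].set(value=float(iw[-1]))
    p["amp"].set(value=float(iw[0] - iw[-1]))
    tau0 = max(float(tw[-1]) / 5.0, float(tw[1]))
    p["tau"].set(value=tau0, min=1e-3, max=10 * float(tw[-1]))
    res = _run_fit(model, iw, window=window_ms,
                   multistart_tau=("tau", tau0), params=p, t=tw)
    if res.converged:
        res.params["tau_inact_ms"] = res.params.pop("tau")
        res.params["plateau_pA"] = res.params.pop("plateau")
        res.stderr["tau_inact_ms"] = res.stderr.pop("tau")
        res.stderr["plateau_pA"] = res.stderr.pop("plateau")
    return res


# ---------------------------------------------------------------------------
# I-V and pool fits


def fit_iv_curve(v_mV, i_pA, form: str = "modified") -> FitResult:
    """Boltzmann fit of a peak-current I-V relation.

    ``modified`` fits the conductance form over all points; ``simple`` fits
    the plain sigmoid over the foot of the curve, from -60 mV up to the
    voltage of maximal inward current.
    """
    v = np.asarray(v_mV, dtype=float)
    i = np.asarray(i_pA, dtype=float)
    if v.size != i.size or v.size < 5:
        raise ValueError("need >= 5 (V, I) points")
    if form == "modified":
        def f(v, g_max, v_rev, v_half, k):
            return g_max * (v - v_rev) / (1.0 + np.exp((v - v_half) / k))
        model = lmfit.Model(f, name="boltzmann_modified")
        p = model.make_params()
        p["g_max"].set(value=max(np.max(np.abs(i)) / 50.0, 0.01), min=1e-6)
        p["v_rev"].set(value=40.0, min=-20, max=150)
        p["v_half"].set(value=float(v[np.argmin(np.gradient(i, v))]
                                    if v.size > 2 else -25.0), min=-80, max=20)
        p["k"].set(value=-6.0, max=-0.5)
        return _run_fit(model, i, params=p, v=v)
    if form == "simple":
        vmax = v[np.argmax(np.abs(i))]
        sel = (v >= -60.0) & (v <= vmax) if vmax > -60 else (v >= -60.0)
        if sel.sum() < 5:
            sel = np.ones_like(v, dtype=bool)
        vs, xs = v[sel], i[sel]

        def f(v, i_max, i_min, v_half, k):
            return i_max + (i_min - i_max) / (1.0 + np.exp((v - v_half) / k))
        model = lmfit.Model(f, name="boltzmann_simple")
        p = model.make_params()
        p["i_max"].set(value=float(xs[np.argmin(np.abs(vs + 60))]))
        p["i_min"].set(value=float(xs[np.argmax(np.abs(xs))]))
        p["v_half"].set(value=float(np.median(vs)), min=-80, max=20)
        p["k"].set(value=-6.0, max=-0.5)
        res = _run_fit(model, xs, window=(float(vs.min()), float(vs.max())),
                       params=p, v=vs)
        return res
    raise ValueError(f"unknown form {form!r}")


def fit_pool_depletion(durations_ms, delta_cm_fF,
                       range_ms: tuple[float, float] = (0.5, 9.0),
                       with_delay: bool = True) -> FitResult:
    """Saturating-exponential fit of dC_m versus step duration.

    Model A (1 - exp(-(t - t0)/tau)) with t0 >= 0 the release onset delay
    (``with_delay=False`` pins t0 = 0).  Returns amplitude_fF, tau_ms, t0_ms.
    """
    t = np.asarray(durations_ms, dtype=float)
    y = np.asarray(delta_cm_fF, dtype=float)
    sel = (t >= range_ms[0] - 1e-9) & (t <= range_ms[1] + 1e-9)
    if sel.sum() < 3:
        raise ValueError("need >= 3 points within the fit range")
    ts, ys = t[sel], y[sel]

    def f(t, amp, tau, t0):
        return amp * np.maximum(1.0 - np.exp(-(t - t0) / tau), 0.0)
    model = lmfit.Model(f, name="pool_depletion")
    p = model.make_params()
    p["amp"].set(value=float(max(ys.max(), 1e-3)), min=0)
    p["tau"].set(value=0.5, min=1e-3, max=50)
    p["t0"].set(value=0.3 if with_delay else 0.0, min=0,
                max=float(ts.min()), vary=with_delay)
    res = _run_fit(model, ys, window=range_ms,
                   multistart_tau=("tau", 0.5), params=p, t=ts)
    if res.converged:
        res.params["amplitude_fF"] = res.params.pop("amp")
        res.params["tau_ms"] = res.params.pop("tau")
        res.params["t0_ms"] = res.params.pop("t0")
        res.stderr["amplitude_fF"] = res.stderr.pop("amp")
        res.stderr["tau_ms"] = res.stderr.pop("tau")
        res.stderr["t0_ms"] = res.stderr.pop("t0")
    return res


def fit_dcm_vs_q(q_fC, delta_cm_fF, durations_ms=None, egta_mM=None
                 ) -> FitResult:
    """Exponential fit of dC_m versus cumulative Ca2+ charge.

    Points from steps longer than 3 ms recorded under 0.5 mM EGTA are
    excluded first (the Cl(Ca) current corrupts their charge integral).
    Returns amplitude_fF and q_e_fC.
    """
    q = np.asarray(q_fC, dtype=float)
    y = np.asarray(delta_cm_fF, dtype=float)
    keep = np.ones(q.size, dtype=bool)
    if durations_ms is not None and egta_mM is not None:
        d = np.asarray(durations_ms, dtype=float)
        e = np.broadcast_to(np.asarray(egta_mM, dtype=float), q.shape)
        keep = ~((e <= 0.5) & (d > 3.0))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points after the exclusion rule")
    qs, ys = q[keep], y[keep]

    def f(q, amp, q_e):
        return amp * (1.0 - np.exp(-q / q_e))
    model = lmfit.Model(f, name="dcm_vs_q")
    p = model.make_params()
    p["amp"].set(value=float(max(ys.max(), 1e-3)), min=0)
    p["q_e"].set(value=max(float(np.median(qs)) / 2, 0.1), min=1e-3)
    res = _run_fit(model, ys, multistart_tau=("q_e", 4.0), params=p, q=qs)
    if res.converged:
        res.params["amplitude_fF"] = res.params.pop("amp")
        res.params["q_e_fC"] = res.params.pop("q_e")
        res.stderr["amplitude_fF"] = res.stderr.pop("amp")
        res.stderr["q_e_fC"] = res.stderr.pop("q_e")
    return res


def compare_groups(sample_a, sample_b, welch: bool = False) -> dict:
    """Unpaired two-sided Student's t-test with group means and SEs."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    t, pval = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "mean_a": float(a.mean()), "se_a": float(a.std(ddof=1) / np.sqrt(a.size)),
        "mean_b": float(b.mean()), "se_b": float(b.std(ddof=1) / np.sqrt(b.size)),
        "t": float(t), "p": float(pval), "n_a": int(a.size), "n_b": int(b.size),
    }


# ---------------------------------------------------------------------------
# end-to-end drivers


def analyze_step_series(bundle: RecordingBundle,
                        release_params: ReleaseParams | None = None) -> dict:
    """Full capacitance-protocol analysis of one recording bundle.

    Runs the sine+dc decomposition, measures dC_m per episode, integrates
    the Ca2+ charge per episode (step plus 2 ms of tail), and fits the
    pool-depletion and dC_m-vs-Q relations.
    """
    from .lockin import sine_dc_decompose

    release_params = release_params or ReleaseParams()
    tr = sine_dc_decompose(bundle.i_total_pA, bundle.v_cmd_mV,
                           bundle.protocol.sine)
    i_kin = (bundle.i_compensated_pA if bundle.i_compensated_pA is not None
             else bundle.i_total_pA)
    rows = []
    for ep in bundle.episodes():
        d = measure_delta_cm(tr, ep["t_start_ms"], ep["t_end_ms"],
                             egta_mM=bundle.egta_mM)
        q = integrate_qca(i_kin, times_ms=bundle.times_ms,
                          window_ms=(ep["t_start_ms"],
                                     min(ep["t_end_ms"] + 2.0,
                                         bundle.times_ms[-1])))
        rows.append({"duration_ms": ep["duration_ms"],
                     "v_step_mV": ep["v_step_mV"],
                     "q_ca_fC": q,
                     "n_sv": dcm_to_sv(max(d["delta_cm_fF"], 0.0),
                                       release_params), **d})
    table = pd.DataFrame(rows)
    out = {"lockin": tr, "episodes": table}
    if len(table) >= 3:
        out["pool_fit"] = fit_pool_depletion(
            table["duration_ms"], table["delta_cm_fF"],
            range_ms=(float(table["duration_ms"].min()),
                      min(9.0, float(table["duration_ms"].max()))))
        out["pool_fit_full"] = fit_pool_depletion(
            table["duration_ms"], table["delta_cm_fF"],
            range_ms=(float(table["duration_ms"].min()),
                      float(table["duration_ms"].max())))
        out["q_fit"] = fit_dcm_vs_q(
            table["q_ca_fC"], table["delta_cm_fF"],
            durations_ms=table["duration_ms"],
            egta_mM=bundle.egta_mM)
    return out


def analyze_iv_series(bundle: RecordingBundle,
                      channel: str = "compensated") -> dict:
    """Peak-I_Ca per step voltage (activation fits) plus Boltzmann I-V fits.

    ``channel`` selects what the kinetic fits see: ``"compensated"`` (the
    amplifier-style compensated recording, default) or ``"ca"`` (the clean
    simulated Ca2+ current — what an ideally series-resistance-compensated
    recording approaches; used when the quantity of interest is the channel
    kinetics themselves rather than the measurement chain).
    """
    if channel == "ca" and "i_ca_pA" in bundle.ground_truth:
        i_kin = bundle.ground_truth["i_ca_pA"]
    elif bundle.i_compensated_pA is not None:
        i_kin = bundle.i_compensated_pA
    else:
        i_kin = bundle.i_total_pA
    rows = []
    for ep in bundle.episodes():
        fit = fit_activation(bundle.times_ms, i_kin, ep["t_start_ms"],
                             ep["t_end_ms"], v_step_mV=ep["v_step_mV"],
                             egta_mM=bundle.egta_mM)
        tail = measure_tail(bundle.times_ms, i_kin, ep["t_end_ms"])
        peak = fit.params.get("peak_i_pA", np.nan) if fit.converged else np.nan
        rows.append({"v_step_mV": ep["v_step_mV"], "peak_i_pA": peak,
                     "tau_activ_ms": fit.params.get("tau_activ_ms", np.nan)
                     if fit.converged else np.nan,
                     "tail_pA": tail, "converged": fit.converged})
    table = pd.DataFrame(rows)
    ok = table["converged"] & np.isfinite(table["peak_i_pA"])
    out = {"iv_table": table}
    if ok.sum() >= 5:
        out["boltzmann_modified"] = fit_iv_curve(
            table.loc[ok, "v_step_mV"], table.loc[ok, "peak_i_pA"], "modified")
        out["boltzmann_simple"] = fit_iv_curve(
            table.loc[ok, "v_step_mV"], table.loc[ok, "peak_i_pA"], "simple")
    return out


def peak_iv_reference(params: CavParams | None = None, v_mV=None) -> pd.DataFrame:
    """Model peak-I_Ca curve (no kinetics) for comparison plots/tests."""
    params = params or CavParams()
    if v_mV is None:
        v_mV = np.arange(-80.0, 40.0, 10.0)
    v = np.asarray(v_mV, dtype=float)
    return pd.DataFrame({"v_mV": v, "i_pA": boltzmann_iv(v, params, "modified")})
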