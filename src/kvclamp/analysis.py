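"""Whole-cell characterization pipeline: raw sweeps to biophysical parameters.

The pipeline mirrors standard patch-clamp practice for delayed-rectifier
potassium currents:

1. IV table: steady current per step, baseline-subtracted.
2. Activation curve: normalized peak tail currents vs prepulse potential,
   fitted with the Boltzmann ``I = 1/(1 + exp(-(V - V_half)/k))``.
3. Activation/deactivation kinetics: single-exponential fits per sweep,
   then the tau-voltage law ``tau(V) = tau_Vhalf * exp((V - V_half)/k_tau)``
   fitted on log(tau) (exactly linear under the model).
4. C-type inactivation: double-exponential fit of the 90 s decay at +40 mV
   (fast/slow time constants and the fast amplitude fraction).
5. Recovery from inactivation: probe/conditioning peak ratios vs interpulse
   interval, fitted with ``R(dt) = 1 - (1 - R0) * exp(-dt / tau)``.
6. Cohort statistics: mean +/- SEM over cells, two-sample Student's t-test.

Every fitter reports diagnostics (RSS, convergence, warning flags) instead
of failing silently; hard errors carry the pipeline stage name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .gating import BoltzmannParams, TauLaw
from .protocols import Protocol, Sweep
from .simulate import Trace

__all__ = [
    "AnalysisError",
    "BoltzmannFit",
    "ExpFit",
    "DoubleExpFit",
    "TauLawFit",
    "RecoveryFit",
    "CharacterizationResult",
    "TTestResult",
    "measure_iv",
    "extract_tail_amplitudes",
    "fit_boltzmann",
    "fit_single_exp",
    "fit_tau_law",
    "fit_double_exp",
    "fit_recovery",
    "measure_recovery",
    "characterize_cell",
    "cohort_stats",
    "summarize_cohort",
    "t_test",
]

#: capacitive-artifact window skipped after every voltage transition (ms)
SKIP_MS = 0.5
#: tail-peak search window after the skip (ms); kept short because the peak
#: tail sits immediately after the capacitive window, while a long search
#: window would pick up slow re-activation at the tail potential after
#: subthreshold prepulses and lift the foot of the activation curve
TAIL_WINDOW_MS = 5.0
#: activation-kinetics fits use steps at/above this potential (channels open)
ACT_FIT_MIN_MV = -30.0
#: deactivation-kinetics fits use post-steps at/below this potential
DEACT_FIT_MAX_MV = -50.0


class AnalysisError(ValueError):
    """Raised when a pipeline stage cannot produce a result."""


# ---------------------------------------------------------------------------
# fit-result containers


@dataclass
class BoltzmannFit:
    params: Optional[BoltzmannParams]
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class ExpFit:
    tau: float  # same unit as the input time vector
    amplitude: float
    offset: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class DoubleExpFit:
    tau_fast: float
    tau_slow: float
    frac_fast: float
    offset: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class TauLawFit:
    tau_at_Vhalf: float
    k_tau: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class RecoveryFit:
    tau: float
    R0: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class CharacterizationResult:
    """Table-shaped biophysical parameter set for one cell (or cohort row)."""

    cell_id: str
    V_half: float  # mV
    k: float  # mV
    act_tau_Vhalf: float  # ms
    deact_tau_Vhalf: float  # ms
    tau_fast: float  # s
    tau_slow: float  # s
    frac_fast: float
    tau_recovery: float  # s
    diagnostics: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "V_1/2": self.V_half,
            "k": self.k,
            "tau_V1/2_act": self.act_tau_Vhalf,
            "tau_V1/2_deact": self.deact_tau_Vhalf,
            "tau_fast": self.tau_fast,
            "tau_slow": self.tau_slow,
            "frac_fast": self.frac_fast,
            "tau_recovery": self.tau_recovery,
        }


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# helpers


def _sweep_by_label(protocol: Protocol, label: str) -> Sweep:
    for sw in protocol.sweeps:
        if sw.label == label:
            return sw
    raise AnalysisError(f"no sweep labelled {label!r} in {protocol.kind} protocol")


def _segment_slice(sweep: Sweep, index: int) -> slice:
    bounds = sweep.segment_sample_bounds()
    i0, i1 = bounds[index]
    return slice(i0, i1)


def _baseline(trace: Trace, sweep: Sweep) -> float:
    """Mean current over the leading holding segment."""
    if sweep.segments[0].level != sweep.holding:
        raise AnalysisError("sweep has no leading baseline window at holding")
    sl = _segment_slice(sweep, 0)
    if sl.stop - sl.start < 1:
        raise AnalysisError("baseline window contains no samples")
    return float(np.mean(trace.current[sl]))


# ---------------------------------------------------------------------------
# stage 1: IV table


def measure_iv(traces: Sequence[Trace], protocol: Protocol) -> pd.DataFrame:
    """Steady current per step: mean over the last 10% of the step segment,
    baseline-subtracted.  Suitable for non-inactivating currents on the
    200 ms timescale."""
    rows = []
    for trace in traces:
        sweep = _sweep_by_label(protocol, trace.sweep_label)
        base = _baseline(trace, sweep)
        step_idx = 1  # [baseline, step, closing]
        sl = _segment_slice(sweep, step_idx)
        n = sl.stop - sl.start
        tail_sl = slice(sl.stop - max(1, n // 10), sl.stop)
        rows.append(
            {
                "step_V": sweep.segments[step_idx].level,
                "current": float(np.mean(trace.current[tail_sl])) - base,
            }
        )
    return pd.DataFrame(rows).sort_values("step_V", ignore_index=True)


# ---------------------------------------------------------------------------
# stage 2: tail currents and Boltzmann fit


def extract_tail_amplitudes(
    traces: Sequence[Trace],
    protocol: Protocol,
    skip_ms: float = SKIP_MS,
    window_ms: float = TAIL_WINDOW_MS,
) -> pd.DataFrame:
    """Peak tail amplitude per prepulse potential, normalized to the maximum.

    The amplitude is the extremum (largest absolute deviation from baseline)
    of the tail-segment current within ``[tail_start + skip_ms,
    tail_start + skip_ms + window_ms]``; the leading ``skip_ms`` excludes
    the capacitive-artifact window.
    """
    rows = []
    for trace in traces:
        sweep = _sweep_by_label(protocol, trace.sweep_label)
        base = _baseline(trace, sweep)
        tail_idx = 2  # [baseline, prepulse, tail, closing]
        sl = _segment_slice(sweep, tail_idx)
        fs_ms = sweep.sampling_rate / 1e3
        lo = sl.start + int(round(skip_ms * fs_ms))
        hi = min(sl.stop, sl.start + int(round((skip_ms + window_ms) * fs_ms)) + 1)
        if hi <= lo:
            raise AnalysisError("tail window is empty; check skip_ms/window_ms")
        seg = trace.current[lo:hi] - base
        amp = seg[int(np.argmax(np.abs(seg)))]
        rows.append({"prepulse_V": sweep.segments[1].level, "amplitude": float(amp)})
    df = pd.DataFrame(rows).sort_values("prepulse_V", ignore_index=True)
    peak = float(np.max(np.abs(df["amplitude"])))
    if peak == 0:
        raise AnalysisError("all tail amplitudes are zero; no activation detected")
    df["normalized"] = df["amplitude"] / df["amplitude"].iloc[int(np.argmax(np.abs(df["amplitude"])))]
    return df


def fit_boltzmann(V: Sequence[float], y: Sequence[float]) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized activation curve."""
    V = np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(V) < 4:
        raise AnalysisError("Boltzmann fit needs at least 4 points")
    if np.ptp(y) < 0.2 or not (y.min() < 0.5 < y.max()):
        raise AnalysisError("activation curve does not bracket its midpoint; fit is degenerate")

    def model(v, vh, k):
        return expit((v - vh) / k)

    vh0 = float(V[int(np.argmin(np.abs(y - 0.5)))])
    k0 = max(1e-3, np.ptp(V) / 10.0)
    flags: list[str] = []
    try:
        popt, _ = optimize.curve_fit(model, V, y, p0=[vh0, k0], maxfev=10_000)
        resid = y - model(V, *popt)
        rss = float(resid @ resid)
        return BoltzmannFit(BoltzmannParams(float(popt[0]), float(popt[1])), rss, True, flags)
    except RuntimeError as exc:
        flags.append(f"non_convergence: {exc}")
        return BoltzmannFit(None, math.inf, False, flags)


# ---------------------------------------------------------------------------
# stage 3: exponential kinetics


def _exp_model(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def _crossing_tau(t: np.ndarray, y: np.ndarray, C0: float, A0: float) -> float:
    """Initial tau from the 63.2% settling time of the relaxation.

    Robust against slow secondary drifts that corrupt a log-linear estimate
    over the whole segment."""
    target = 1.0 - 1.0 / math.e
    # fraction of the way from y[0] toward the asymptote C0
    frac = (y[0] - y) / (y[0] - C0) if y[0] != C0 else np.zeros_like(y)
    idx = np.nonzero(frac >= target)[0]
    if len(idx) and idx[0] > 0:
        return float(t[idx[0]])
    return max(np.ptp(t) / 5.0, float(np.median(np.diff(t))))


def fit_single_exp(
    t: Sequence[float], y: Sequence[float], refine_window: bool = True
) -> ExpFit:
    """Fit ``I(t) = A*exp(-t/tau) + C``.

    tau is initialized from the 63.2% settling time and, with
    ``refine_window=True``, the fit window is restricted to about 8 initial
    time constants (and refined once against the fitted tau) so slow
    secondary drifts -- e.g. creeping C-type inactivation during a 200 ms
    activation step -- cannot bias the fast relaxation estimate.  Residual
    structure beyond 1% of |A| raises the ``nonmonoexponential`` flag.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    t = t - t[0]
    flags: list[str] = []
    n_tail = max(1, len(y) // 10)
    C0 = float(np.mean(y[-n_tail:]))
    A0 = float(y[0] - C0)
    if abs(A0) < 1e-12 * max(1.0, np.abs(y).max()):
        flags.append("amplitude_zero")
        return ExpFit(math.nan, 0.0, C0, 0.0, False, flags)
    tau0 = _crossing_tau(t, y, C0, A0)

    def attempt(tt, yy, p0):
        return optimize.curve_fit(_exp_model, tt, yy, p0=p0, maxfev=20_000)

    def window(tau_w):
        if refine_window and 8 * tau_w < t[-1]:
            mask = t <= 8 * tau_w
            if mask.sum() >= 5:
                return mask
        return np.ones(len(t), dtype=bool)

    mask = window(tau0)
    p0 = [A0, tau0, C0]
    popt = None
    for trial in range(3):
        try:
            popt, _ = attempt(t[mask], y[mask], p0)
            break
        except RuntimeError:
            p0 = [A0 * (1 + 0.3 * (trial + 1)), tau0 * (2.0 ** (trial + 1)), C0]
    if popt is None:
        flags.append("non_convergence")
        return ExpFit(math.nan, A0, C0, math.inf, False, flags)
    refined = window(popt[1])
    if refined.sum() != mask.sum():
        mask = refined
        try:
            popt, _ = attempt(t[mask], y[mask], list(popt))
        except RuntimeError:
            flags.append("refine_non_convergence")
    A, tau, C = (float(v) for v in popt)
    mask = t <= min(t[-1], 8 * tau) if refine_window else np.ones_like(t, bool)
    resid = y[mask] - _exp_model(t[mask], A, tau, C)
    rss = float(resid @ resid)
    if tau <= 0:
        flags.append("tau_nonpositive")
        return ExpFit(tau, A, C, rss, False, flags)
    if math.sqrt(rss / mask.sum()) > 0.01 * abs(A):
        flags.append("nonmonoexponential")
    return ExpFit(tau, A, C, rss, True, flags)


def fit_tau_law(
    V: Sequence[float], tau: Sequence[float], V_half: float
) -> TauLawFit:
    """Fit ``tau(V) = tau_Vhalf * exp((V - V_half)/k_tau)`` by linear least
    squares on log(tau); ``V_half`` comes from the same cell's Boltzmann fit."""
    V = np.asarray(V, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(V) < 3:
        raise AnalysisError("tau-law fit needs at least 3 points")
    if np.any(tau <= 0) or not np.all(np.isfinite(tau)):
        raise AnalysisError("tau-law fit requires positive finite time constants")
    slope, intercept = np.polyfit(V, np.log(tau), 1)
    resid = np.log(tau) - (slope * V + intercept)
    rss = float(resid @ resid)
    if abs(slope) < 1e-6:
        return TauLawFit(float(np.exp(intercept)), math.inf, rss, False, ["tau_voltage_independent"])
    k_tau = 1.0 / slope
    tau_vh = float(np.exp(intercept + slope * V_half))
    return TauLawFit(tau_vh, float(k_tau), rss, True, [])


def _double_exp_model(t, Af, tf, As, ts, C):
    return Af * np.exp(-t / tf) + As * np.exp(-t / ts) + C


def fit_double_exp(t: Sequence[float], y: Sequence[float]) -> DoubleExpFit:
    """Fit a decay with ``Af*exp(-t/tf) + As*exp(-t/ts) + C``.

    The fit starts at the current maximum (the activation rise before the
    peak is not part of the decay).  Components are ordered fast < slow and
    ``frac_fast = Af / (Af + As)``; near-equal time constants (within 5%)
    raise the ``component_collapse`` flag.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    i0 = int(np.argmax(np.abs(y)))
    t = t[i0:] - t[i0]
    y = y[i0:]
    if len(y) < 10:
        raise AnalysisError("decay segment too short for a double-exponential fit")
    flags: list[str] = []
    # peel: slow component from the last 60%, fast from the early residual
    C0 = float(min(np.abs(y[-max(1, len(y) // 50) :]).mean(), np.abs(y).min()))
    C0 = math.copysign(C0, y[0])
    half = len(y) * 2 // 5
    slow = fit_single_exp(t[half:], y[half:], refine_window=False)
    ts0 = slow.tau if slow.converged and slow.tau > 0 else np.ptp(t) / 3
    resid_early = y[:half] - _exp_model(t[:half], slow.amplitude, ts0, slow.offset)
    fast = fit_single_exp(t[:half], resid_early + np.sign(y[0]) * 1e-30, refine_window=False)
    tf0 = fast.tau if fast.converged and 0 < fast.tau < ts0 else ts0 / 8
    Af0 = fast.amplitude if fast.converged else 0.3 * y[0]
    As0 = y[0] - C0 - Af0
    lower = [-np.inf, 1e-12, -np.inf, 1e-12, -np.inf]
    upper = [np.inf] * 5
    try:
        popt, _ = optimize.curve_fit(
            _double_exp_model,
            t,
            y,
            p0=[Af0, tf0, As0, ts0, C0],
            bounds=(lower, upper),
            maxfev=40_000,
        )
    except RuntimeError as exc:
        raise AnalysisError(f"double-exponential fit did not converge: {exc}") from exc
    Af, tf, As, ts, C = (float(v) for v in popt)
    if tf > ts:
        Af, As, tf, ts = As, Af, ts, tf
    resid = y - _double_exp_model(t, Af, tf, As, ts, C)
    rss = float(resid @ resid)
    denom = Af + As
    frac = Af / denom if denom != 0 else math.nan
    if ts > 0 and abs(ts - tf) / ts < 0.05:
        flags.append("component_collapse")
    if frac < 0.02 or frac > 0.98:
        flags.append("component_collapse")
    return DoubleExpFit(tf, ts, frac, C, rss, True, flags)


# ---------------------------------------------------------------------------
# stage 5: recovery from inactivation


def measure_recovery(traces: Sequence[Trace], protocol: Protocol) -> pd.DataFrame:
    """Probe/conditioning peak-current ratios from a double-pulse protocol.

    P1 is the peak during the 20 s conditioning pulse, P2 the peak during the
    100 ms probe (both baseline-subtracted).  Ratios are normalized by the
    ratio at the longest interval and capped at 1.
    """
    rows = []
    for trace in traces:
        sweep = _sweep_by_label(protocol, trace.sweep_label)
        base = _baseline(trace, sweep)
        # [baseline, conditioning, interval, probe, closing]
        sl1 = _segment_slice(sweep, 1)
        sl2 = _segment_slice(sweep, 3)
        p1 = float(np.max(np.abs(trace.current[sl1] - base)))
        p2 = float(np.max(np.abs(trace.current[sl2] - base)))
        if p1 == 0:
            raise AnalysisError("conditioning pulse evoked no current")
        rows.append(
            {"interval_s": sweep.segments[2].duration / 1e3, "ratio": p2 / p1}
        )
    df = pd.DataFrame(rows).sort_values("interval_s", ignore_index=True)
    ref = df["ratio"].iloc[-1]
    if ref <= 0:
        raise AnalysisError("no recovery at the longest interval")
    df["normalized"] = np.minimum(df["ratio"] / ref, 1.0)
    return df


def fit_recovery(intervals_s: Sequence[float], ratios: Sequence[float]) -> RecoveryFit:
    """Fit the recovery curve with a rising exponential
    ``R(dt) = A - (A - R0) * exp(-dt / tau)``.

    The asymptote A is a free parameter: normalizing by the ratio at the
    longest (but finite) interval puts the true asymptote slightly above 1,
    and pinning it there would bias tau downward.  Reported R0 is the fitted
    curve's value at dt = 0.
    """
    dt = np.asarray(intervals_s, dtype=float)
    R = np.asarray(ratios, dtype=float)
    if len(dt) < 4:
        raise AnalysisError("recovery fit needs at least 4 intervals")
    if np.any(R > 1.1):
        raise AnalysisError("recovery ratios exceed 1.1; check peak measurement")
    if np.ptp(R) < 1e-6:
        return RecoveryFit(math.nan, float(R.mean()), 0.0, False, ["no_inactivation"])

    def model(x, tau, R0, A):
        return A - (A - R0) * np.exp(-x / tau)

    deficit = 1.0 - R
    mask = deficit > 1e-6
    if mask.sum() >= 2:
        slope, _ = np.polyfit(dt[mask], np.log(deficit[mask]), 1)
        tau0 = -1.0 / slope if slope < 0 else np.ptp(dt) / 3
    else:
        tau0 = np.ptp(dt) / 3
    try:
        popt, _ = optimize.curve_fit(
            model, dt, R, p0=[max(tau0, 1e-3), float(R[0]), 1.0], maxfev=20_000
        )
    except RuntimeError as exc:
        return RecoveryFit(math.nan, math.nan, math.inf, False, [f"non_convergence: {exc}"])
    resid = R - model(dt, *popt)
    return RecoveryFit(float(popt[0]), float(popt[1]), float(resid @ resid), True, [])


# ---------------------------------------------------------------------------
# stage 6: full-cell chain and cohort statistics


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, AnalysisError):
                raise AnalysisError(f"stage '{name}': {exc}") from exc
            if isinstance(exc, AnalysisError) and not str(exc).startswith("stage"):
                raise AnalysisError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def characterize_cell(
    recording: dict[str, Sequence[Trace]],
    protocols: dict[str, Protocol],
    cell_id: Optional[str] = None,
) -> CharacterizationResult:
    """Run the full characterization chain for one cell.

    ``recording`` maps protocol kind -> traces (as returned by
    :func:`kvclamp.simulate.simulate_cell`); ``protocols`` maps kind -> the
    matching protocol objects.  Deterministic given its inputs.
    """
    required = {"iv", "tail", "deactivation", "inactivation", "recovery"}
    missing = required - set(recording)
    if missing:
        raise AnalysisError(f"recording lacks protocols: {sorted(missing)}")
    if cell_id is None:
        cell_id = recording["iv"][0].cell_id
    diags: dict = {}

    with _stage("iv"):
        iv = measure_iv(recording["iv"], protocols["iv"])
        diags["iv"] = iv

    with _stage("activation_curve"):
        tails = extract_tail_amplitudes(recording["tail"], protocols["tail"])
        bfit = fit_boltzmann(tails["prepulse_V"], tails["normalized"])
        if not bfit.converged or bfit.params is None:
            raise AnalysisError(f"Boltzmann fit failed: {bfit.flags}")
        diags["boltzmann"] = bfit
        V_half, k = bfit.params.V_half, bfit.params.k

    with _stage("activation_kinetics"):
        taus_V, taus = [], []
        for trace in recording["iv"]:
            sweep = _sweep_by_label(protocols["iv"], trace.sweep_label)
            V = sweep.segments[1].level
            if V < ACT_FIT_MIN_MV:
                continue
            sl = _segment_slice(sweep, 1)
            fs_ms = sweep.sampling_rate / 1e3
            lo = sl.start + int(round(SKIP_MS * fs_ms))
            efit = fit_single_exp(trace.time_ms[lo : sl.stop], trace.current[lo : sl.stop])
            if efit.converged and efit.tau > 0:
                taus_V.append(V)
                taus.append(efit.tau)
        act_law = fit_tau_law(taus_V, taus, V_half)
        diags["act_tau_law"] = act_law

    with _stage("deactivation_kinetics"):
        taus_V, taus = [], []
        for trace in recording["deactivation"]:
            sweep = _sweep_by_label(protocols["deactivation"], trace.sweep_label)
            V = sweep.segments[2].level
            if V > DEACT_FIT_MAX_MV:
                continue
            sl = _segment_slice(sweep, 2)
            fs_ms = sweep.sampling_rate / 1e3
            lo = sl.start + int(round(SKIP_MS * fs_ms))
            efit = fit_single_exp(trace.time_ms[lo : sl.stop], trace.current[lo : sl.stop])
            if efit.converged and efit.tau > 0:
                taus_V.append(V)
                taus.append(efit.tau)
        deact_law = fit_tau_law(taus_V, taus, V_half)
        diags["deact_tau_law"] = deact_law

    with _stage("inactivation"):
        trace = recording["inactivation"][0]
        sweep = _sweep_by_label(protocols["inactivation"], trace.sweep_label)
        sl = _segment_slice(sweep, 1)
        dfit = fit_double_exp(trace.time_ms[sl], trace.current[sl])
        diags["inactivation"] = dfit

    with _stage("recovery"):
        rec = measure_recovery(recording["recovery"], protocols["recovery"])
        rfit = fit_recovery(rec["interval_s"], rec["normalized"])
        if not rfit.converged:
            raise AnalysisError(f"recovery fit failed: {rfit.flags}")
        diags["recovery"] = rfit

    return CharacterizationResult(
        cell_id=cell_id,
        V_half=V_half,
        k=k,
        act_tau_Vhalf=act_law.tau_at_Vhalf,
        deact_tau_Vhalf=deact_law.tau_at_Vhalf,
        tau_fast=dfit.tau_fast / 1e3,  # trace time is ms; report seconds
        tau_slow=dfit.tau_slow / 1e3,
        frac_fast=dfit.frac_fast,
        tau_recovery=rfit.tau,
        diagnostics=diags,
    )


def cohort_stats(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, SEM (n-1 denominator SD / sqrt(n)) and n over per-cell estimates."""
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n < 1:
        raise AnalysisError("cohort_stats needs at least one value")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return mean, sem, n


def summarize_cohort(results: Sequence[CharacterizationResult]) -> pd.DataFrame:
    """Mean +/- SEM table over cells, mirroring a one-row-per-parameter layout."""
    rows = []
    fields = [
        "V_1/2",
        "k",
        "tau_V1/2_act",
        "tau_V1/2_deact",
        "tau_fast",
        "tau_slow",
        "frac_fast",
        "tau_recovery",
    ]
    table = pd.DataFrame([r.to_row() for r in results])
    for f in fields:
        vals = table[f].dropna().to_numpy()
        mean, sem, n = cohort_stats(vals)
        rows.append({"parameter": f, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


def t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sample two-tailed Student's t-test with pooled variance."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise AnalysisError("t-test needs at least 2 values per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, False)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, True)
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, p < 0.05)
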