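"""Conductance-voltage curves, gating-charge integration and Q(V) analysis.

Gating currents are the tiny transient currents produced by voltage-sensor
(S4) charge movement, recorded with ionic conduction blocked.  Integrating
the ON gating current over the pulse (after excluding the capacitive spike)
yields the charge moved at each voltage; normalizing gives the Q(V) curve.
Q(V) follows a Boltzmann sigmoid

    Q(V) = A / (1 + exp((V_half - V) / s))

whose midpoint depends on the holding voltage: holding at 0 mV keeps S4 in
its relaxed/up state and shifts the midpoint negative (the "Q(V) shift" or
mode shift).  When part of the charge has already moved at the reference
holding voltage, the curve is refit with a sum of two Boltzmann components
sharing one slope, the second midpoint fixed, to separate the shifted
fraction and correct the measured shift.

Sign convention: ``slope > 0`` gives curves rising with depolarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np
from scipy.optimize import curve_fit

from .traces import GatingTrace

__all__ = [
    "GVCurve",
    "QVCurve",
    "BoltzmannFit",
    "TwoBoltzmannFit",
    "LeakCorrection",
    "DecayFit",
    "QVShift",
    "boltzmann",
    "conductance_curve",
    "fit_boltzmann",
    "leak_subtract",
    "integrate_charge",
    "build_qv",
    "fit_two_boltzmann_fixed",
    "qv_shift",
    "fit_gating_decay",
]


def boltzmann(v: np.ndarray, amplitude: float, v_half: float, slope: float) -> np.ndarray:
    """Boltzmann sigmoid A / (1 + exp((v_half - V)/slope))."""
    return amplitude / (1.0 + np.exp((v_half - v) / slope))


@dataclass(frozen=True)
class GVCurve:
    """Conductance vs. voltage, G = I/(V - V_rev)."""

    voltages: np.ndarray  # mV, strictly increasing
    conductances: np.ndarray  # µS
    v_rev: float  # mV

    def __post_init__(self) -> None:
        object.__setattr__(self, "voltages", np.asarray(self.voltages, dtype=float))
        object.__setattr__(self, "conductances", np.asarray(self.conductances, dtype=float))
        if len(self.voltages) != len(self.conductances):
            raise ValueError("voltages and conductances differ in length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass(frozen=True)
class QVCurve:
    """Normalized gating charge vs. voltage, in percent of maximum."""

    voltages: np.ndarray  # mV
    charge_pct: np.ndarray  # % of maximum
    holding_voltage: float  # mV

    def __post_init__(self) -> None:
        object.__setattr__(self, "voltages", np.asarray(self.voltages, dtype=float))
        object.__setattr__(self, "charge_pct", np.asarray(self.charge_pct, dtype=float))
        if len(self.voltages) != len(self.charge_pct):
            raise ValueError("voltages and charge_pct differ in length")


@dataclass(frozen=True)
class BoltzmannFit:
    amplitude: float
    v_half: float  # mV
    slope: float  # mV


@dataclass(frozen=True)
class TwoBoltzmannFit:
    """Constrained two-component Boltzmann fit with a shared slope."""

    fraction_2: float  # weight of the fixed-midpoint component, in [0, 1]
    v_half_1: float  # mV, free midpoint
    v_half_2: float  # mV
    slope: float  # mV, shared
    amplitude: float
    fixed_v_half_2: bool = True
    boundary_warning: bool = False


@dataclass(frozen=True)
class LeakCorrection:
    trace: GatingTrace
    correction_charge: float  # nC integrated over the ON window


@dataclass(frozen=True)
class DecayFit:
    tau: float  # ms
    amplitude: float
    offset: float
    low_confidence: bool = False


@dataclass(frozen=True)
class QVShift:
    shift: float  # mV, v_half(holding 0) - v_half(holding -80)
    corrected_shift: float | None = None  # mV, using the refit first component


def conductance_curve(
    currents: np.ndarray, voltages: np.ndarray, v_rev: float
) -> GVCurve:
    """Pointwise chord conductance G_K(V) = I_K / (V - V_rev)."""
    currents = np.asarray(currents, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    bad = np.isclose(voltages, v_rev)
    if np.any(bad):
        raise ValueError(
            f"conductance undefined at the reversal potential: V = {voltages[bad][0]} mV"
        )
    return GVCurve(voltages=voltages, conductances=currents / (voltages - v_rev), v_rev=v_rev)


def _curve_xy(curve: GVCurve | QVCurve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, GVCurve):
        return curve.voltages, curve.conductances
    return curve.voltages, curve.charge_pct


def fit_boltzmann(
    curve: GVCurve | QVCurve,
    shared_slope_partner: GVCurve | QVCurve | None = None,
) -> BoltzmannFit | tuple[BoltzmannFit, BoltzmannFit]:
    """Fit a Boltzmann sigmoid to a G(V) or Q(V) curve.

    With ``shared_slope_partner`` given, both curves are fit in one joint
    least-squares problem with a single common slope (separate amplitudes
    and midpoints), as is standard when comparing Q(V) curves recorded from
    two holding voltages.
    """
    v1, y1 = _curve_xy(curve)
    if len(v1) < 5:
        raise ValueError("need at least 5 points spanning the transition")

    params = lmfit.Parameters()
    ymax = float(np.max(np.abs(y1))) or 1.0
    params.add("amp1", value=ymax, min=1e-12)
    params.add("vh1", value=float(v1[np.argmin(np.abs(y1 - 0.5 * ymax))]))
    params.add("slope", value=10.0, min=1e-3)

    if shared_slope_partner is None:
        def resid(p):
            return y1 - boltzmann(v1, p["amp1"], p["vh1"], p["slope"])
    else:
        v2, y2 = _curve_xy(shared_slope_partner)
        if len(v2) < 5:
            raise ValueError("partner curve needs at least 5 points")
        ymax2 = float(np.max(np.abs(y2))) or 1.0
        params.add("amp2", value=ymax2, min=1e-12)
        params.add("vh2", value=float(v2[np.argmin(np.abs(y2 - 0.5 * ymax2))]))

        def resid(p):
            return np.concatenate(
                [
                    y1 - boltzmann(v1, p["amp1"], p["vh1"], p["slope"]),
                    y2 - boltzmann(v2, p["amp2"], p["vh2"], p["slope"]),
                ]
            )

    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(
            f"Boltzmann fit did not converge: {out.message}; "
            f"residual norm {np.linalg.norm(out.residual):.3g}"
        )
    p = out.params
    fit1 = BoltzmannFit(
        amplitude=float(p["amp1"]), v_half=float(p["vh1"]), slope=float(p["slope"])
    )
    if shared_slope_partner is None:
        return fit1
    fit2 = BoltzmannFit(
        amplitude=float(p["amp2"]), v_half=float(p["vh2"]), slope=float(p["slope"])
    )
    return fit1, fit2


def _voltage_profile(trace: GatingTrace) -> np.ndarray:
    """Commanded membrane voltage at each sample (holding outside the pulse)."""
    v = np.full_like(trace.time, trace.holding_voltage)
    v[trace.on_mask] = trace.step_voltage
    return v


def leak_subtract(
    trace: GatingTrace,
    method: str = "linear_baseline",
    subthreshold: GatingTrace | None = None,
) -> LeakCorrection:
    """Offline leak-current correction of a gating-current sweep.

    ``linear_baseline`` fits a straight line in time to the pre-pulse
    samples and subtracts its extrapolation across the sweep (removes
    offsets and slow drift).  ``subthreshold_scaling`` scales a companion
    sweep recorded at a subthreshold step (pure leak, no gating charge) by
    the pointwise command-voltage ratio — the P/n-style correction that
    removes an ohmic leak exactly.
    """
    if method == "linear_baseline":
        base = trace.baseline_mask
        if int(base.sum()) < 2:
            raise ValueError("linear_baseline needs >= 2 pre-pulse samples")
        coef = np.polyfit(trace.time[base], trace.current[base], deg=1)
        correction = np.polyval(coef, trace.time)
    elif method == "subthreshold_scaling":
        if subthreshold is None:
            raise ValueError("subthreshold_scaling needs a companion subthreshold trace")
        v_main = _voltage_profile(trace)
        v_sub = _voltage_profile(subthreshold)
        leak = np.interp(trace.time, subthreshold.time, subthreshold.current)
        v_sub_i = np.interp(trace.time, subthreshold.time, v_sub)
        if np.any((v_sub_i == 0) & (v_main != 0)):
            raise ValueError("subthreshold command voltage is zero where the test pulse is not")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(v_sub_i != 0, v_main / v_sub_i, 0.0)
        correction = leak * ratio
    else:
        raise ValueError(f"unknown leak-subtraction method {method!r}")

    corrected = replace(trace, current=trace.current - correction)
    on = trace.on_mask
    q_corr = float(np.trapezoid(correction[on], trace.time[on]))  # µA·ms == nC
    return LeakCorrection(trace=corrected, correction_charge=q_corr)


def integrate_charge(
    trace: GatingTrace, exclusion_ms: float = 1.5, phase: str = "on"
) -> float:
    """Integrate gating current to charge (nC) over one pulse phase.

    The first ``exclusion_ms`` after the phase onset are excluded to drop
    the residual capacitive transient; the trapezoidal integral runs from
    there to the end of the phase, with the window edges interpolated onto
    the sample grid.  µA x ms integrates directly to nC.
    """
    if phase == "on":
        t0, t1 = exclusion_ms, trace.pulse_duration
    elif phase == "off":
        t0, t1 = trace.pulse_duration + exclusion_ms, float(trace.time[-1])
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if t0 >= t1:
        raise ValueError(
            f"exclusion window ({exclusion_ms} ms) leaves no samples in the {phase} phase"
        )
    inner = (trace.time > t0) & (trace.time < t1)
    t = np.concatenate([[t0], trace.time[inner], [t1]])
    i = np.concatenate(
        [
            [np.interp(t0, trace.time, trace.current)],
            trace.current[inner],
            [np.interp(t1, trace.time, trace.current)],
        ]
    )
    return float(np.trapezoid(i, t))


def build_qv(
    traces: list[GatingTrace],
    holding_voltage: float,
    exclusion_ms: float = 1.5,
) -> QVCurve:
    """Integrate ON gating currents per voltage and normalize to percent.

    Charges are divided by the maximum and scaled to 100, so the curve is
    invariant to uniform charge scaling and idempotent under renormalization.
    """
    if len(traces) < 5:
        raise ValueError("need gating traces at >= 5 voltages")
    volts = np.array([tr.step_voltage for tr in traces], dtype=float)
    charges = np.array([integrate_charge(tr, exclusion_ms) for tr in traces])
    order = np.argsort(volts)
    volts, charges = volts[order], charges[order]
    qmax = charges.max()
    if qmax <= 0:
        raise ValueError("all integrated charges are zero or negative")
    return QVCurve(
        voltages=volts, charge_pct=100.0 * charges / qmax, holding_voltage=holding_voltage
    )


def normalize_qv(qv: QVCurve) -> QVCurve:
    """Re-normalize a Q(V) curve to percent of its maximum (idempotent)."""
    qmax = qv.charge_pct.max()
    if qmax <= 0:
        raise ValueError("all charges are zero or negative")
    return replace(qv, charge_pct=100.0 * qv.charge_pct / qmax)


def fit_two_boltzmann_fixed(qv: QVCurve, fixed_v_half_2: float) -> TwoBoltzmannFit:
    """Fit a two-component Boltzmann sum with the second midpoint fixed.

    Model: ``A * [f2 * B(V; fixed_v_half_2, s) + (1 - f2) * B(V; v_half_1, s)]``
    with one shared slope ``s``.  Used to separate the fraction of gating
    charge already shifted at the reference holding voltage; a fraction
    pinned at 0 or 1 raises a boundary warning on the result.
    """
    v, y = qv.voltages, qv.charge_pct
    if len(v) < 8:
        raise ValueError("need at least 8 points for the two-component fit")

    params = lmfit.Parameters()
    params.add("amp", value=float(y.max()) or 100.0, min=1e-12)
    params.add("f2", value=0.2, min=0.0, max=1.0)
    params.add("vh1", value=float(np.median(v)))
    params.add("slope", value=10.0, min=1e-3)

    def resid(p):
        model = p["amp"] * (
            p["f2"] * boltzmann(v, 1.0, fixed_v_half_2, p["slope"])
            + (1 - p["f2"]) * boltzmann(v, 1.0, p["vh1"], p["slope"])
        )
        return y - model

    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"two-Boltzmann fit did not converge: {out.message}")
    f2 = float(out.params["f2"])
    at_bound = f2 < 1e-6 or f2 > 1 - 1e-6
    if at_bound:
        warnings.warn(
            f"two-Boltzmann fraction pinned at boundary (f2 = {f2:.3g}); "
            "the complementary midpoint is unidentifiable",
            stacklevel=2,
        )
    return TwoBoltzmannFit(
        fraction_2=f2,
        v_half_1=float(out.params["vh1"]),
        v_half_2=fixed_v_half_2,
        slope=float(out.params["slope"]),
        amplitude=float(out.params["amp"]),
        fixed_v_half_2=True,
        boundary_warning=at_bound,
    )


def qv_shift(
    fit_from_neg_holding: BoltzmannFit,
    fit_from_0_holding: BoltzmannFit,
    corrected_first_component: float | None = None,
) -> QVShift:
    """Holding-voltage-dependent Q(V) midpoint shift.

    ``shift = V_half(holding 0) - V_half(holding negative)``; when the
    refit first-component midpoint is supplied, the corrected shift uses it
    as the reference instead of the raw negative-holding midpoint.
    """
    shift = fit_from_0_holding.v_half - fit_from_neg_holding.v_half
    corrected = None
    if corrected_first_component is not None:
        corrected = fit_from_0_holding.v_half - corrected_first_component
    return QVShift(shift=float(shift), corrected_shift=corrected)


def fit_gating_decay(
    trace: GatingTrace, start: float | None = None, phase: str = "on"
) -> DecayFit:
    """Single-exponential decay constant of |gating current| after its peak.

    ``start`` defaults to the time where |current| has fallen halfway from
    its peak toward the tail level — past the slowly rising phase, where the
    decay is genuinely exponential; the magnitude is fit to
    ``A*exp(-t/tau) + C`` from there to the end of the phase.  A tau far
    beyond the window flags the fit as low-confidence rather than failing.
    """
    if phase == "on":
        mask = trace.on_mask
    elif phase == "off":
        mask = trace.time > trace.pulse_duration
    else:
        raise ValueError(f"unknown phase {phase!r}")
    t_all = trace.time[mask]
    i_all = np.abs(trace.current[mask])
    if start is None:
        peak_idx = int(np.argmax(i_all))
        tail = float(np.mean(i_all[-max(3, len(i_all) // 20):]))
        half = tail + 0.5 * (i_all[peak_idx] - tail)
        past = np.nonzero(i_all[peak_idx:] <= half)[0]
        start_idx = peak_idx + int(past[0]) if len(past) else peak_idx
        # keep enough samples for the fit
        start_idx = min(start_idx, len(t_all) - 15)
        start = float(t_all[max(start_idx, peak_idx)])
    sel = t_all >= start
    if int(sel.sum()) < 15:
        raise ValueError("fewer than 15 samples in the decaying segment")
    t = t_all[sel] - start
    i = i_all[sel]
    window = float(t[-1])

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = max(float(i[0] - i[-1]), 1e-12)
    try:
        popt, _ = curve_fit(
            model,
            t,
            i,
            p0=[a0, window / 5, float(i[-1])],
            bounds=([0, 1e-9, 0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        a, tau, c = (float(x) for x in popt)
        low_conf = tau > 100 * window
    except RuntimeError:
        a, tau, c = a0, 1e3 * window, float(i[-1])
        low_conf = True
    return DecayFit(tau=tau, amplitude=a, offset=c, low_confidence=low_conf)
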