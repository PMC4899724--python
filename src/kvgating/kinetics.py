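"""Three-state gating kinetics and C-type inactivation rate analysis.

The macroscopic model is the classic three-state scheme

    C  <--(beta)--/--(alpha)-->  O  <--(lambda)--/--(kappa)-->  I

with fast activation rates ``alpha``/``beta`` (per millisecond) and slow
inactivation rates ``kappa``/``lambda`` (per second).  When the open
probability is high (``alpha >> beta`` at the test voltage) the decay of the
open current is a single exponential

    I(t) = (I_max - SS) * exp(-t / tau) + SS

with ``tau = 1/(kappa + lambda)`` and ``SS/I_max = lambda/(kappa + lambda)``,
so both slow rates are recoverable from a fit of the decaying phase:

    kappa  = (1 - SS/I_max) / tau
    lambda = (SS/I_max) / tau

This module simulates the full scheme exactly (matrix exponential of the
3x3 generator, no two-state approximation), fits the inactivating phase,
converts fits to rate constants, and expresses mutant / drug / metal-bridge
effects as fold changes, percent changes and kappa/lambda quotient ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit

from .traces import CurrentTrace

__all__ = [
    "KineticRates",
    "InactivationFit",
    "EffectFactor",
    "AmplitudeCorrectedFits",
    "voltage_dependent_activation",
    "simulate_three_state",
    "fit_inactivation",
    "rates_from_fit",
    "amplitude_corrected_fit",
    "quotient_ratio",
    "fold_change",
    "percent_change",
]

# A fit is flagged low-confidence when the fitted tau exceeds this multiple
# of the fitting window (decay not resolved within the sweep).
LOW_CONFIDENCE_TAU_FACTOR = 100.0

RateLike = float | Callable[[float], float]


def voltage_dependent_activation(
    alpha0: float = 0.3,
    beta0: float = 0.3,
    s_a: float = 30.0,
    s_b: float = 30.0,
) -> tuple[Callable[[float], float], Callable[[float], float]]:
    """Exponentially voltage-dependent activation rates (per ms).

    ``alpha(V) = alpha0 * exp(V / s_a)`` and ``beta(V) = beta0 * exp(-V / s_b)``
    with V in mV.  The defaults make activation settle within ~10 ms at
    +80 mV while keeping the channel essentially closed at -80 mV, which is
    all the slow-inactivation analysis requires of the fast gate.
    """
    return (lambda v: alpha0 * np.exp(v / s_a), lambda v: beta0 * np.exp(-v / s_b))


@dataclass(frozen=True)
class KineticRates:
    """Rate constants of the C<->O<->I scheme.

    ``alpha`` and ``beta`` are per-millisecond and may be callables of
    voltage (mV); ``kappa`` (O->I) and ``lambda_`` (I->O) are per-second.
    """

    alpha: RateLike
    beta: RateLike
    kappa: float
    lambda_: float

    def __post_init__(self) -> None:
        for name in ("kappa", "lambda_"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not callable(v) and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def activation_at(self, voltage: float) -> tuple[float, float]:
        """Evaluate (alpha, beta) in per-ms at a voltage."""
        a = self.alpha(voltage) if callable(self.alpha) else self.alpha
        b = self.beta(voltage) if callable(self.beta) else self.beta
        if not (np.isfinite(a) and np.isfinite(b)) or a < 0 or b < 0:
            raise ValueError(f"alpha/beta evaluate to invalid rates at {voltage} mV")
        return float(a), float(b)


@dataclass(frozen=True)
class InactivationFit:
    """Result of the exponential decay fit of an inactivating current."""

    i_max: float  # µA, current at fit start
    ss_abs: float  # µA, fitted steady-state current
    ss_frac: float  # SS / I_max, dimensionless
    tau: float  # seconds
    residual_norm: float  # µA
    low_confidence: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.low_confidence:
            if not (0.0 <= self.ss_frac <= 1.0):
                raise ValueError(f"ss_frac {self.ss_frac} outside [0, 1]")
            if self.i_max <= 0:
                raise ValueError("i_max must be positive")


@dataclass(frozen=True)
class EffectFactor:
    """A dimensionless effect size comparing two conditions."""

    kind: str  # fold_tau | percent_tau_change | quotient_ratio
    value: float
    before_label: str = ""
    after_label: str = ""


@dataclass(frozen=True)
class AmplitudeCorrectedFits:
    """Paired control/treated fits with the peak-amplitude ratio reported."""

    control: InactivationFit
    treated: InactivationFit
    amplitude_ratio: float  # i_max(treated) / i_max(control)


def _generator(alpha: float, beta: float, kappa: float, lam: float) -> np.ndarray:
    """3x3 rate generator for state vector (P_C, P_O, P_I), rates per second."""
    return np.array(
        [
            [-alpha, beta, 0.0],
            [alpha, -(beta + kappa), lam],
            [0.0, kappa, -lam],
        ]
    )


def _stationary(a: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (null vector, normalized)."""
    w, v = np.linalg.eig(a)
    idx = int(np.argmin(np.abs(w)))
    p = np.real(v[:, idx])
    p = np.abs(p)
    return p / p.sum()


def simulate_three_state(
    rates: KineticRates,
    step_voltage: float,
    holding_voltage: float = -80.0,
    duration: float = 10.0,
    dt: float = 0.01,
    g_max: float = 0.025,
    v_rev: float = -80.0,
    initial_state: np.ndarray | None = None,
    label: str = "",
    return_states: bool = False,
) -> CurrentTrace | tuple[CurrentTrace, np.ndarray]:
    """Simulate a voltage step under the three-state scheme.

    The master equation ``dP/dt = A P`` is solved exactly by propagating the
    matrix exponential of the step-voltage generator over each uniform sample
    interval.  The initial distribution is the stationary distribution of the
    holding-voltage generator unless ``initial_state`` is given explicitly.

    Parameters
    ----------
    rates : KineticRates
        Scheme rate constants; alpha/beta may be voltage-dependent.
    step_voltage, holding_voltage : float
        Test and holding potentials in mV.
    duration, dt : float
        Sweep length and sample interval, seconds.
    g_max : float
        Maximal open-channel conductance, µS.
    v_rev : float
        K+ reversal potential, mV.
    initial_state : ndarray, optional
        Explicit (P_C, P_O, P_I) at t = 0 overriding the holding stationary
        distribution.
    return_states : bool
        Also return the (n_samples, 3) state-probability matrix.

    Returns
    -------
    CurrentTrace, optionally with the state-probability time courses.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 10 * dt:
        raise ValueError("duration must cover at least 10 samples")

    a_step, b_step = rates.activation_at(step_voltage)
    # per-ms -> per-s so the generator shares units with kappa/lambda
    gen_step = _generator(a_step * 1e3, b_step * 1e3, rates.kappa, rates.lambda_)

    if initial_state is None:
        a_hold, b_hold = rates.activation_at(holding_voltage)
        gen_hold = _generator(a_hold * 1e3, b_hold * 1e3, rates.kappa, rates.lambda_)
        p0 = _stationary(gen_hold)
    else:
        p0 = np.asarray(initial_state, dtype=float)
        if p0.shape != (3,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("initial_state must be a probability vector of length 3")

    n = int(round(duration / dt)) + 1
    time = np.arange(n) * dt
    propagator = expm(gen_step * dt)
    states = np.empty((n, 3))
    states[0] = p0
    for i in range(1, n):
        states[i] = propagator @ states[i - 1]
    # guard against accumulated round-off
    states /= states.sum(axis=1, keepdims=True)

    current = states[:, 1] * g_max * (step_voltage - v_rev)
    trace = CurrentTrace(
        time=time,
        current=current,
        step_voltage=step_voltage,
        holding_voltage=holding_voltage,
        label=label,
    )
    return (trace, states) if return_states else trace


def fit_inactivation(
    trace: CurrentTrace,
    fit_start: float | None = None,
) -> InactivationFit:
    """Fit the decaying phase of a K+ current to a single exponential.

    ``fit_start`` defaults to the time of the current maximum; the window
    runs from there to the end of the sweep with time re-zeroed at the start
    of the fit.  The fit is flagged low-confidence when the decay is not
    resolved within the window (tau > 100x window length) or when the
    optimizer cannot separate amplitude from steady state (flat trace).
    """
    if fit_start is None:
        fit_start = float(trace.time[np.argmax(trace.current)])
    peak_time = float(trace.time[np.argmax(trace.current)])
    if fit_start < peak_time - 1e-12:
        raise ValueError(
            f"fit_start {fit_start} precedes the current maximum at {peak_time}"
        )

    mask = trace.time >= fit_start
    if int(mask.sum()) < 20:
        raise ValueError("fewer than 20 samples in the fitting window")
    t = trace.time[mask] - fit_start
    i = trace.current[mask]
    window = float(t[-1])

    def model(tt, i_max, ss, tau):
        return (i_max - ss) * np.exp(-tt / tau) + ss

    i0 = float(i[0])
    ss0 = max(float(np.mean(i[-max(3, len(i) // 10):])), 0.0)
    # crude tau guess: time to decay half way toward the tail level
    half = ss0 + 0.5 * (i0 - ss0)
    below = np.nonzero(i <= half)[0]
    tau0 = float(t[below[0]]) / np.log(2) if len(below) and below[0] > 0 else window / 3
    tau0 = min(max(tau0, window * 1e-3), window * 10)

    try:
        popt, _ = curve_fit(
            model,
            t,
            i,
            p0=[max(i0, 1e-12), ss0, tau0],
            bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        i_max, ss, tau = (float(x) for x in popt)
        resid = float(np.linalg.norm(i - model(t, *popt)))
    except RuntimeError:
        # flat / non-decaying window: report the degenerate description
        i_max = max(i0, 1e-12)
        ss = i_max
        tau = LOW_CONFIDENCE_TAU_FACTOR * 10 * max(window, 1.0)
        resid = float(np.linalg.norm(i - np.mean(i)))

    low_conf = tau > LOW_CONFIDENCE_TAU_FACTOR * window or i_max <= 0
    # a vanishing decay amplitude leaves tau unidentifiable
    if i_max > 0 and abs(i_max - ss) < 1e-6 * i_max:
        low_conf = True
    ss_frac = ss / i_max if i_max > 0 else 1.0
    if ss_frac > 1.0:
        # amplitude indistinguishable from steady state within noise
        if ss_frac > 1.0 + 1e-6:
            low_conf = True
        ss_frac = 1.0
    return InactivationFit(
        i_max=i_max,
        ss_abs=ss,
        ss_frac=ss_frac,
        tau=tau,
        residual_norm=resid,
        low_confidence=bool(low_conf),
        label=trace.label,
    )


def rates_from_fit(fit: InactivationFit) -> KineticRates:
    """Convert a decay fit to the slow rate constants.

    ``kappa = (1 - SS/I_max)/tau`` and ``lambda = (SS/I_max)/tau`` so that
    ``1/(kappa + lambda) == tau`` identically.  The fast rates are not
    determined by the decay and are returned as zero placeholders.
    """
    if fit.tau <= 0:
        raise ValueError("fit has non-positive tau")
    if not (0.0 <= fit.ss_frac <= 1.0):
        raise ValueError(f"ss_frac {fit.ss_frac} outside [0, 1]")
    kappa = (1.0 - fit.ss_frac) / fit.tau
    lam = fit.ss_frac / fit.tau
    return KineticRates(alpha=0.0, beta=0.0, kappa=kappa, lambda_=lam)


def amplitude_corrected_fit(
    control: CurrentTrace,
    treated: CurrentTrace,
    fit_start: float | None = None,
) -> AmplitudeCorrectedFits:
    """Fit a control/treated pair with per-trace amplitude normalization.

    Some interventions (e.g. a metal bridge) change the peak current as well
    as the kinetics.  Each trace's steady-state fraction is defined relative
    to its own fitted peak, so the kinetic comparison is independent of the
    amplitude change; the peak ratio is reported alongside.
    """
    if (control.step_voltage, control.holding_voltage) != (
        treated.step_voltage,
        treated.holding_voltage,
    ):
        raise ValueError("control and treated traces come from different protocols")
    fc = fit_inactivation(control, fit_start)
    ft = fit_inactivation(treated, fit_start)
    return AmplitudeCorrectedFits(
        control=fc, treated=ft, amplitude_ratio=ft.i_max / fc.i_max
    )


def quotient_ratio(before: InactivationFit, after: InactivationFit) -> EffectFactor:
    """Ratio of kappa/lambda quotients between two conditions.

    Because ``kappa/lambda = (1 - SS)/SS``, the ratio depends only on the
    steady-state fractions and the time constants cancel, making it a clean
    measure of how strongly an intervention biases the O<->I equilibrium.
    """
    for f in (before, after):
        if not (0.0 < f.ss_frac < 1.0):
            raise ValueError(
                f"ss_frac {f.ss_frac} gives an infinite or zero kappa/lambda quotient"
            )
    q_before = (1.0 - before.ss_frac) / before.ss_frac
    q_after = (1.0 - after.ss_frac) / after.ss_frac
    return EffectFactor(
        kind="quotient_ratio",
        value=q_after / q_before,
        before_label=before.label,
        after_label=after.label,
    )


def fold_change(tau_ref: float, tau_alt: float, before_label: str = "", after_label: str = "") -> EffectFactor:
    """Fold acceleration of inactivation: tau_ref / tau_alt."""
    if tau_ref <= 0 or tau_alt <= 0:
        raise ValueError("time constants must be positive")
    return EffectFactor(
        kind="fold_tau",
        value=tau_ref / tau_alt,
        before_label=before_label,
        after_label=after_label,
    )


def percent_change(tau_ctrl: float, tau_drug: float, before_label: str = "", after_label: str = "") -> EffectFactor:
    """Percent reduction of the time constant: 100*(tau_ctrl - tau_drug)/tau_ctrl."""
    if tau_ctrl <= 0 or tau_drug <= 0:
        raise ValueError("time constants must be positive")
    return EffectFactor(
        kind="percent_tau_change",
        value=100.0 * (tau_ctrl - tau_drug) / tau_ctrl,
        before_label=before_label,
        after_label=after_label,
    )
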