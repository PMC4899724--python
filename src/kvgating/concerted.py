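"""Double-mutant tests for concerted action in C-type inactivation.

Two residues act *in concert* when the free-energy perturbations of their
mutations add, so the rate (fold) effects multiply:

    tau_AB = tau_wt * (tau_A / tau_wt) * (tau_B / tau_wt) = tau_A * tau_B / tau_wt

If the residues instead act independently, the mutation producing the faster
inactivation dominates and the double mutant simply matches the faster
single mutant:

    tau_AB = min(tau_A, tau_B)

An observed double-mutant time constant is classified by its log10 distance
to each prediction.  Observations *faster* than the multiplicative
prediction still classify as concerted: super-multiplicative behaviour is
even stronger evidence that the two perturbations load onto one cooperative
transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MutantTau",
    "ConcertVerdict",
    "predict_concerted",
    "predict_independent",
    "classify",
]

DEFAULT_LOG10_BAND = 0.15


@dataclass(frozen=True)
class MutantTau:
    """Inactivation time constant of one channel variant."""

    label: str
    tau: float  # seconds
    sem: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class ConcertVerdict:
    """Comparison of an observed double mutant against both predictions."""

    tau_concert_pred: float
    tau_independent_pred: float
    observed_tau: float
    log_distance_concert: float
    log_distance_independent: float
    classification: str  # concerted | independent | indeterminate
    band: float = DEFAULT_LOG10_BAND


def predict_concerted(wt: MutantTau, a: MutantTau, b: MutantTau) -> float:
    """Multiplicative (energy-additive) double-mutant prediction."""
    return a.tau * b.tau / wt.tau


def predict_independent(a: MutantTau, b: MutantTau) -> float:
    """Independent-action prediction: the faster single mutant dominates."""
    return min(a.tau, b.tau)


def classify(
    wt: MutantTau,
    a: MutantTau,
    b: MutantTau,
    observed: MutantTau,
    band: float = DEFAULT_LOG10_BAND,
) -> ConcertVerdict:
    """Classify an observed double mutant as concerted or independent.

    The observation is assigned to whichever prediction is nearer in
    log10(tau), provided the margin between the two distances exceeds
    ``band`` (log10 units); otherwise the verdict is indeterminate.
    Observations beyond the concerted prediction (even faster) count as
    concerted regardless of the margin.
    """
    if band <= 0:
        raise ValueError("band must be positive")
    pred_c = predict_concerted(wt, a, b)
    pred_i = predict_independent(a, b)
    d_c = abs(np.log10(observed.tau / pred_c))
    d_i = abs(np.log10(observed.tau / pred_i))

    if observed.tau <= pred_c and pred_c <= pred_i:
        classification = "concerted"
    elif abs(d_c - d_i) <= band:
        classification = "indeterminate"
    else:
        classification = "concerted" if d_c < d_i else "independent"
    return ConcertVerdict(
        tau_concert_pred=pred_c,
        tau_independent_pred=pred_i,
        observed_tau=observed.tau,
        log_distance_concert=float(d_c),
        log_distance_independent=float(d_i),
        classification=classification,
        band=band,
    )
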