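"""Dichotomous fGn/fBm signal classification and the 1−H deviation score.

A measured signal is assigned to one of two process classes before its
Hurst exponent is interpreted: fractional Gaussian noise (stationary,
fluctuation exponent and spectral β below 1) or fractional Brownian
motion (nonstationary walk regime, both above 1).  Classification is only
attempted on signals that passed the −1 < β < 3 scale-invariance screen.
For fGn signals H = H_fGn and the deviation score 1 − H_fGn quantifies how
far the region falls from the well-attuned H ≈ 1 dynamics.

The DFA exponent is the classifying fluctuation exponent (DFA is the
standard instrument for this dichotomy); the AFA estimate supplies the
H_fGn value carried forward, and both are recorded as evidence.  Optional
guard zones around the class boundary (default width 0) turn borderline
cases into ``ambiguous`` rather than forcing a label.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectral import BETA_LOWER, BETA_UPPER

__all__ = ["SignalClassification", "classify_signal", "deviation_score"]

FGN = "fGn"
FBM = "fBm"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SignalClassification:
    """Class label plus the evidence it was decided on.

    ``h_fgn`` and ``deviation`` (= 1 − h_fgn exactly) are present iff the
    label is ``"fGn"``.
    """

    label: str
    h_fgn: float | None
    deviation: float | None
    evidence: dict

    def __post_init__(self):
        if self.label not in (FGN, FBM, AMBIGUOUS):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == FGN) != (self.deviation is not None):
            raise ValueError("deviation present iff label is fGn")
        if self.deviation is not None and self.deviation != 1.0 - self.h_fgn:
            raise ValueError("deviation must equal 1 - h_fgn exactly")


def classify_signal(afa_h: float, dfa_exponent: float, beta: float,
                    guard_exponent: float = 0.0,
                    guard_beta: float = 0.0) -> SignalClassification:
    """Apply the dichotomous fGn/fBm rule.

    fGn when the DFA fluctuation exponent and β both fall below 1 (minus
    their guard widths); fBm when both exceed 1 (plus guard widths);
    ``ambiguous`` when the indicators conflict or land inside a guard
    zone.  Signals outside the scale-invariance gate (β outside (−1, 3))
    are refused: no fractal class is defined for them.
    """
    if not (BETA_LOWER < beta < BETA_UPPER):
        raise ValueError(
            f"beta = {beta:g} fails the scale-invariance gate "
            f"({BETA_LOWER:g} < beta < {BETA_UPPER:g}); refusing to classify")
    if guard_exponent < 0 or guard_beta < 0:
        raise ValueError("guard widths must be nonnegative")

    evidence = {"afa_h": float(afa_h), "dfa_exponent": float(dfa_exponent),
                "beta": float(beta), "gate_passed": True}
    is_fgn = dfa_exponent < 1.0 - guard_exponent and beta < 1.0 - guard_beta
    is_fbm = dfa_exponent > 1.0 + guard_exponent and beta > 1.0 + guard_beta
    if is_fgn:
        return SignalClassification(FGN, float(afa_h), 1.0 - float(afa_h),
                                    evidence)
    if is_fbm:
        return SignalClassification(FBM, None, None, evidence)
    return SignalClassification(AMBIGUOUS, None, None, evidence)


def deviation_score(classification: SignalClassification) -> float:
    """1 − H_fGn for an fGn-labelled signal; other labels are an error."""
    if classification.label != FGN:
        raise ValueError(
            f"deviation score is defined for fGn signals only "
            f"(got {classification.label!r})")
    return classification.deviation
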