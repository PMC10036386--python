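"""Mosaicism-ratio classification of deletion origin (fetal vs maternal).

The mosaicism ratio MR divides the event-specific fraction (the share of
cfDNA carrying the deletion) by the fetal fraction.  A purely fetal
heterozygous event has MR ~ 1 at any fetal fraction; a maternal carrier
contributes most of the plasma cfDNA, so MR = (1-ff)/ff when the fetus
did not inherit the deletion and 1/ff when it did - both far above 1 at
typical fetal fractions.  A single cutoff (default 3) therefore
separates the two origins except at unusually high fetal fractions,
where (1-ff)/ff drops below the cutoff (ff > 0.25) and a maternal
non-transmitted event is indistinguishable from a fetal one by MR alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .simulate import DeletionScenario

__all__ = [
    "MosaicismAssessment",
    "mosaicism_ratio",
    "classify_origin",
    "analytic_mr",
    "OriginClassifier",
]

DEFAULT_MR_CUTOFF = 3.0

LIKELY_MATERNAL = "likely_maternal"
SUSPECTED_FETAL = "suspected_fetal"


@dataclass(frozen=True)
class MosaicismAssessment:
    mr: float
    origin_call: str
    cutoff: float = DEFAULT_MR_CUTOFF


def mosaicism_ratio(event_fraction: float, ff: float) -> float:
    """MR = event fraction / fetal fraction."""
    if ff <= 0:
        raise ValueError(f"fetal fraction must be positive, got {ff}")
    if not (0.0 <= event_fraction <= 1.0):
        raise ValueError(f"event fraction must be in [0,1], got {event_fraction}")
    return event_fraction / ff


def classify_origin(mr: float, cutoff: float = DEFAULT_MR_CUTOFF) -> str:
    """likely_maternal iff MR > cutoff; a tie at the cutoff is called fetal.

    The tie-break toward suspected_fetal is conservative for fetal
    follow-up testing.
    """
    if mr < 0:
        raise ValueError(f"mosaicism ratio must be >= 0, got {mr}")
    return LIKELY_MATERNAL if mr > cutoff else SUSPECTED_FETAL


def assess(event_fraction: float, ff: float, cutoff: float = DEFAULT_MR_CUTOFF) -> MosaicismAssessment:
    mr = mosaicism_ratio(event_fraction, ff)
    return MosaicismAssessment(mr=mr, origin_call=classify_origin(mr, cutoff), cutoff=cutoff)


def analytic_mr(scenario: DeletionScenario | str, ff: float) -> float:
    """Expected MR under the mixture model, as a function of origin and ff.

    fetal (de novo or paternal) -> 1; maternal non-transmitted ->
    (1-ff)/ff; maternal transmitted -> 1/ff; no event -> 0.
    """
    if not (0.0 < ff < 1.0):
        raise ValueError(f"fetal fraction must be in (0,1), got {ff}")
    origin = scenario.origin if isinstance(scenario, DeletionScenario) else scenario
    if origin in ("fetal_de_novo", "paternal_fetal"):
        return 1.0
    if origin == "maternal_not_transmitted":
        return (1.0 - ff) / ff
    if origin == "maternal_transmitted":
        return 1.0 / ff
    if origin == "none":
        return 0.0
    raise ValueError(f"unknown origin {origin!r}")


class OriginClassifier(BaseEstimator, ClassifierMixin):
    """MR-threshold origin classifier over (event_fraction, fetal_fraction) rows.

    Rule-based: no parameters are learned, so ``fit`` only records the
    label set.  ``predict`` applies the MR cutoff, plus an optional
    secondary rule flagging likely_maternal whenever the event fraction
    exceeds 0.5, which is impossible for a purely fetal event (the fetal
    compartment never holds more than half the region's cfDNA copies at
    ff < 1).

    Parameters
    ----------
    cutoff : float
        MR threshold; MR > cutoff is called likely_maternal.
    epsilon_rule : bool
        Enable the secondary event-fraction > 0.5 rule.
    """

    def __init__(self, cutoff: float = DEFAULT_MR_CUTOFF, epsilon_rule: bool = True):
        self.cutoff = cutoff
        self.epsilon_rule = epsilon_rule

    def fit(self, X=None, y=None) -> "OriginClassifier":
        self.classes_ = np.array([LIKELY_MATERNAL, SUSPECTED_FETAL])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns event_fraction, ff")
        eps, ff = X[:, 0], X[:, 1]
        if (ff <= 0).any():
            raise ValueError("fetal fractions must be positive")
        mr = eps / ff
        maternal = mr > self.cutoff
        if self.epsilon_rule:
            maternal |= eps > 0.5
        return np.where(maternal, LIKELY_MATERNAL, SUSPECTED_FETAL)

    def assess(self, event_fraction: float, ff: float) -> MosaicismAssessment:
        """Single-sample assessment (pure MR rule, matching classify_origin)."""
        return assess(event_fraction, ff, cutoff=self.cutoff)
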