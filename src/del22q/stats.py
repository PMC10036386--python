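"""Cohort statistics: multi-scenario PPV, Wilson CIs, rank tests, concordance.

Positive predictive value in a screening cohort with incomplete
verification is not one number: it depends on how unverified cases are
counted.  Five scenarios are computed:

* ``complete``      TP/(TP+FP) over cases with complete diagnostic testing;
* ``fetal_only``    the same restricted to suspected-fetal cases with
                    fetal testing;
* ``conservative``  TP/(TP+FP+incomplete), treating incompletely tested
                    cases as hypothetical false positives;
* ``upper_bound``   all cases without complete testing counted as true
                    positives, over the whole cohort;
* ``lower_bound``   TP over the whole cohort.

On any cohort, lower_bound <= conservative <= complete-range <= upper_bound.

Confidence intervals use the Wilson score interval by default
(continuity-corrected Wilson and Clopper-Pearson are selectable);
reported percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "PPVEstimate",
    "PPVScenarioSet",
    "wilson_ci",
    "ppv_scenarios",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "size_concordance",
    "summarize_cohort",
    "percent",
]


def percent(numerator: float, denominator: float, dp: int = 1) -> float:
    """Percentage rounded half-up to ``dp`` decimals (reporting convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-dp), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Proportion confidence intervals
# ---------------------------------------------------------------------------

def wilson_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "wilson",
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion.

    ``method`` is one of 'wilson' (score interval, default),
    'wilson_cc' (continuity-corrected) or 'clopper_pearson'.
    Bounds lie in [0,1] and bracket successes/n.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not (0 <= successes <= n):
        raise ValueError(f"successes {successes} outside [0, {n}]")
    p = successes / n
    z = sp_stats.norm.ppf(0.5 + level / 2.0)
    if method == "wilson":
        denom = 1.0 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = center - half, center + half
    elif method == "wilson_cc":
        denom = 2 * (n + z**2)
        lo = (2 * n * p + z**2 - 1 - z * np.sqrt(z**2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
        hi = (2 * n * p + z**2 + 1 + z * np.sqrt(z**2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
        if p == 0:
            lo = 0.0
        if p == 1:
            hi = 1.0
    elif method == "clopper_pearson":
        alpha = 1.0 - level
        lo = 0.0 if successes == 0 else float(sp_stats.beta.ppf(alpha / 2, successes, n - successes + 1))
        hi = 1.0 if successes == n else float(sp_stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (float(max(0.0, lo)), float(min(1.0, hi)))


# ---------------------------------------------------------------------------
# PPV scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPVEstimate:
    successes: int
    n: int
    point: float        # proportion in [0,1]
    ci: tuple[float, float]

    @property
    def pct(self) -> float:
        return percent(self.successes, self.n)


@dataclass(frozen=True)
class PPVScenarioSet:
    complete: Optional[PPVEstimate]
    fetal_only: Optional[PPVEstimate]
    conservative: Optional[PPVEstimate]
    upper_bound: Optional[PPVEstimate]
    lower_bound: Optional[PPVEstimate]
    notes: tuple[str, ...] = ()


def _estimate(successes: int, n: int, ci_method: str, level: float) -> Optional[PPVEstimate]:
    if n == 0:
        return None
    return PPVEstimate(
        successes=successes,
        n=n,
        point=successes / n,
        ci=wilson_ci(successes, n, level=level, method=ci_method),
    )


def ppv_scenarios(
    cohort: pd.DataFrame, ci_method: str = "wilson", level: float = 0.95
) -> PPVScenarioSet:
    """All five PPV accounting scenarios for a cohort table.

    Expects the cohort schema of :mod:`del22q.fixture` (columns
    suspected_origin, testing, completeness, confirmed).  Scenarios with
    an empty denominator are returned as None and noted.
    """
    complete = cohort["completeness"] == "complete"
    incomplete = cohort["completeness"] == "incomplete"
    tp = cohort["confirmed"] == "true_positive"
    fp = cohort["confirmed"] == "false_positive"
    untested = cohort["testing"] == "none"
    fetal_tested = cohort["testing"].isin(["fetal_only", "both"])
    suspected_fetal = cohort["suspected_origin"] == "fetal"

    n_tp = int(tp.sum())
    n_fp = int(fp.sum())
    n_inc = int(incomplete.sum())
    n_untested = int(untested.sum())
    total = len(cohort)

    fetal_mask = suspected_fetal & fetal_tested & complete
    notes = []
    result = PPVScenarioSet(
        complete=_estimate(n_tp, n_tp + n_fp, ci_method, level),
        fetal_only=_estimate(
            int((tp & fetal_mask).sum()), int(fetal_mask.sum()), ci_method, level
        ),
        conservative=_estimate(n_tp, n_tp + n_fp + n_inc, ci_method, level),
        upper_bound=_estimate(n_tp + n_inc + n_untested, total, ci_method, level),
        lower_bound=_estimate(n_tp, total, ci_method, level),
        notes=tuple(notes),
    )
    for name in ("complete", "fetal_only", "conservative", "upper_bound", "lower_bound"):
        if getattr(result, name) is None:
            notes.append(f"{name}: empty denominator, undefined")
    return PPVScenarioSet(
        complete=result.complete,
        fetal_only=result.fetal_only,
        conservative=result.conservative,
        upper_bound=result.upper_bound,
        lower_bound=result.lower_bound,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Rank and exact tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> TestResult:
    """Two-sample Wilcoxon rank-sum test, two-sided.

    The statistic is the midrank sum of ``x`` in the pooled sample.  For
    total n <= ``exact_limit`` the p-value is exact, by enumeration of
    all C(N, n_x) labelings of the pooled data (valid under ties via
    midranks); otherwise a normal approximation with tie and continuity
    corrections is used.  The two-sided p doubles the smaller one-sided
    exact tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sp_stats.rankdata(pooled)
    w = float(ranks[:nx].sum())
    n = nx + ny
    if n <= exact_limit:
        total = 0
        n_le = 0
        n_ge = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n), nx):
            s = ranks[list(combo)].sum()
            total += 1
            if s <= w + eps:
                n_le += 1
            if s >= w - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return TestResult(statistic=w, pvalue=p)
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=w, pvalue=1.0)
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    zstat = (diff - cc) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(sp_stats.norm.sf(abs(zstat))))
    return TestResult(statistic=w, pvalue=p)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    pvalue: float


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Fisher's exact test for the 2x2 table [[a, b], [c, d]], two-sided.

    The p-value sums hypergeometric probabilities of tables (with the
    observed margins) no more probable than the observed one.  The odds
    ratio is the sample OR ad/bc; when any cell is zero the
    Haldane-Anscombe correction (+0.5 to every cell) is applied so the
    OR stays finite.
    """
    cells = (a, b, c, d)
    if any((not float(v).is_integer()) or v < 0 for v in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError(f"degenerate margins in table {(a, b, c, d)}")
    _, p = sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        oratio = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = a * d / (b * c)
    return FisherResult(odds_ratio=float(oratio), pvalue=float(p))


@dataclass(frozen=True)
class ConcordanceResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def size_concordance(pairs: Sequence[tuple[float, float]] | np.ndarray) -> ConcordanceResult:
    """OLS of confirmed size on estimated size; r-squared of the fit."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): estimated, confirmed")
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 pairs, got {arr.shape[0]}")
    x, y = arr[:, 0], arr[:, 1]
    if np.var(x) == 0:
        raise ValueError("estimated sizes are constant; regression undefined")
    fit = sp_stats.linregress(x, y)
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=arr.shape[0],
    )


# ---------------------------------------------------------------------------
# Cohort percentage summary
# ---------------------------------------------------------------------------

def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """The cohort's headline percentages, each half-up rounded to 1 decimal.

    Returns a dict mapping metric name to
    ``{"numerator": int, "denominator": int, "pct": float}``; metrics
    whose denominator is empty are omitted and listed under ``"notes"``.
    """
    maternal = cohort["suspected_origin"] == "maternal"
    tested = cohort["testing"] != "none"
    fetal_tested = cohort["testing"].isin(["fetal_only", "both"])
    ultrasound = cohort["ultrasound"].astype(bool)
    mat_fetal_tested = maternal & fetal_tested

    raw = {
        "pct_suspected_maternal": (int(maternal.sum()), len(cohort)),
        "pct_ultrasound": (int(ultrasound.sum()), len(cohort)),
        "pct_diagnostic_testing": (int(tested.sum()), len(cohort)),
        "pct_deferred_postnatal": (
            int(cohort.loc[fetal_tested, "deferred_postnatal"].astype(bool).sum()),
            int(fetal_tested.sum()),
        ),
        "pct_cardiac_of_ultrasound": (
            int(cohort.loc[ultrasound, "cardiac"].astype(bool).sum()),
            int(ultrasound.sum()),
        ),
        "pct_fetal_inheritance": (
            int((cohort.loc[mat_fetal_tested, "fetal_inherited"] == "yes").sum()),
            int(mat_fetal_tested.sum()),
        ),
    }
    out: dict = {}
    notes = []
    for name, (num, den) in raw.items():
        if den == 0:
            notes.append(f"{name}: empty denominator, omitted")
            continue
        out[name] = {"numerator": num, "denominator": den, "pct": percent(num, den)}
    if notes:
        out["notes"] = notes
    return out
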