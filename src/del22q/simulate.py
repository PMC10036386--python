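"""Synthetic maternal-plasma cfDNA mixtures with 22q11.2 deletions.

Maternal plasma cfDNA is a mixture of maternal and placental (fetal)
fragments; the fetal fraction ``ff`` is the placental share.  A
heterozygous deletion carried by a fraction ``c`` of the cfDNA removes
half of that fraction's copies in the deleted interval, so the expected
read depth there, relative to the diploid baseline, is ``1 - c/2`` with

* ``c = ff``        for a fetal event (de novo or paternally inherited),
* ``c = 1 - ff``    for a maternal deletion NOT transmitted to the fetus,
* ``c = 1``         for a maternal deletion transmitted to the fetus,
* ``c = 0``         for no event.

Counts are generated per 50-kb bin, Poisson by default with an optional
negative-binomial overdispersion knob, with boundary bins attenuated in
proportion to their overlap with the deletion interval.  There is no
read-level simulation and no GC/mappability bias by default (a per-bin
multiplicative bias hook exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import BinGrid, GenomicInterval, RegionModel, canonical_deletions

__all__ = [
    "ORIGINS",
    "DeletionScenario",
    "SampleTruth",
    "SimParams",
    "BinProfile",
    "CohortParams",
    "carrier_fraction",
    "expected_depth_ratio",
    "simulate_sample",
    "generate_cohort",
]

ORIGINS = (
    "none",
    "fetal_de_novo",
    "maternal_not_transmitted",
    "maternal_transmitted",
    "paternal_fetal",
)

#: origins in which the pregnant patient carries the deletion
MATERNAL_ORIGINS = ("maternal_not_transmitted", "maternal_transmitted")
#: origins in which the fetus carries the deletion
FETAL_CARRIER_ORIGINS = ("fetal_de_novo", "paternal_fetal", "maternal_transmitted")


@dataclass(frozen=True)
class DeletionScenario:
    """Deletion origin plus the true genomic interval (absent iff origin='none')."""

    origin: str
    interval: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; expected one of {ORIGINS}")
        if (self.origin == "none") != (self.interval is None):
            raise ValueError("interval must be present iff origin != 'none'")


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated plasma sample."""

    sample_id: str
    ff: float
    scenario: DeletionScenario
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ff < 1.0):
            raise ValueError(f"fetal fraction must be in (0,1), got {self.ff}")


@dataclass(frozen=True)
class SimParams:
    """Count-noise parameters.

    mean_depth : expected reads per 50-kb bin in an unaffected region.
    dispersion : negative-binomial overdispersion d (variance = m + d*m^2);
                 0 means Poisson.
    reference_panel_size : number of unaffected samples used for the
                 caller's baseline.
    bias : optional per-bin multiplicative bias vector (default all ones).
    """

    mean_depth: float = 1000.0
    dispersion: float = 0.0
    reference_panel_size: int = 50
    bias: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class BinProfile:
    """Per-bin read counts for one sample, plus the reported fetal fraction."""

    sample_id: str
    counts: np.ndarray
    ff: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


def carrier_fraction(origin: str, ff: float) -> float:
    """Fraction of plasma cfDNA carrying the deletion under a scenario."""
    if not (0.0 < ff < 1.0):
        raise ValueError(f"fetal fraction must be in (0,1), got {ff}")
    if origin == "none":
        return 0.0
    if origin in ("fetal_de_novo", "paternal_fetal"):
        return ff
    if origin == "maternal_not_transmitted":
        return 1.0 - ff
    if origin == "maternal_transmitted":
        return 1.0
    raise ValueError(f"unknown origin {origin!r}")


def expected_depth_ratio(scenario: DeletionScenario, ff: float) -> float:
    """Expected depth inside the deleted interval relative to diploid baseline.

    Equals ``1 - c/2`` where c is the carrier fraction; outside the
    interval the ratio is 1 by definition.
    """
    return 1.0 - carrier_fraction(scenario.origin, ff) / 2.0


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    # Gamma-Poisson mixture: variance = m + d*m^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_sample(
    truth: SampleTruth,
    params: SimParams,
    grid: BinGrid,
    seed: int | None = None,
) -> BinProfile:
    """Draw one per-bin count profile under a deletion scenario.

    Each bin is drawn independently with mean
    ``mean_depth * bias_b * (1 - f_b * c/2)`` where ``f_b`` is the bin's
    fractional overlap with the deletion interval, so boundary bins that
    are partially deleted are attenuated proportionally.  Identical
    (truth, seed) always reproduces the same profile.
    """
    scenario = truth.scenario
    if scenario.interval is not None and not grid.span.contains(scenario.interval):
        raise ValueError(
            f"deletion interval {scenario.interval} lies outside the bin grid {grid.span}"
        )
    ratio_in = expected_depth_ratio(scenario, truth.ff)
    if scenario.interval is None:
        frac = np.zeros(grid.n_bins)
    else:
        frac = grid.overlap_fractions(scenario.interval)
    bias = params.bias if params.bias is not None else 1.0
    mean = params.mean_depth * bias * (1.0 - frac * (1.0 - ratio_in))
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    counts = _draw_counts(rng, mean, params.dispersion)
    return BinProfile(sample_id=truth.sample_id, counts=counts, ff=truth.ff)


@dataclass(frozen=True)
class CohortParams:
    """Latent-variable distribution for a simulated screen-positive cohort.

    Defaults emulate the composition of the published clinical series:
    57.7% suspected-maternal share, 50% transmission risk for a maternal
    carrier, ~85% weight on the common A-D deletion with the remainder on
    nested intervals, a lognormal fetal-fraction distribution with median
    10.48% truncated to [0.02, 0.45], half of cases ultrasound-flagged,
    and diagnostic-testing dispositions at the observed cohort rates.
    """

    n_cases: int = 307
    p_maternal_suspected: float = 0.577
    p_transmit: float = 0.5
    p_paternal: float = 0.008  # among fetal-carrier cases, inherited from father
    size_mix: dict = field(
        default_factory=lambda: {
            "A-D": 0.85,
            "A-B": 0.05,
            "C-D": 0.05,
            "A-B_small": 0.05,
        }
    )
    ff_lognorm_mu: float = float(np.log(0.1048))
    ff_lognorm_sigma: float = 0.45
    ff_bounds: tuple[float, float] = (0.02, 0.45)
    p_ultrasound: float = 0.511
    testing_probs: dict = field(
        default_factory=lambda: {
            "fetal_only": 83 / 307,
            "maternal_only": 76 / 307,
            "both": 35 / 307,
            "none": 113 / 307,
        }
    )

    def __post_init__(self) -> None:
        for name in ("p_maternal_suspected", "p_transmit", "p_paternal", "p_ultrasound"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for mix_name, mix in (("size_mix", self.size_mix), ("testing_probs", self.testing_probs)):
            total = sum(mix.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{mix_name} weights must sum to 1, got {total}")


def _sample_ff(rng: np.random.Generator, cp: CohortParams, n: int) -> np.ndarray:
    lo, hi = cp.ff_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(cp.ff_lognorm_mu, cp.ff_lognorm_sigma, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(
    cp: CohortParams,
    model: RegionModel,
    params: SimParams,
    seed: int = 0,
) -> tuple[list[tuple[SampleTruth, BinProfile]], pd.DataFrame]:
    """Simulate a whole screen-positive cohort.

    Returns the (truth, profile) pairs and a truth table recording every
    latent variable (origin, interval, fetal fraction, ultrasound flag,
    testing disposition, per-sample seed).  Fully reproducible under the
    given seed.
    """
    if cp.n_cases <= 0:
        raise ValueError(f"n_cases must be positive, got {cp.n_cases}")
    rng = np.random.default_rng(seed)
    dels = canonical_deletions(model)
    unknown = [k for k in cp.size_mix if k not in dels]
    if unknown:
        raise ValueError(f"size_mix names not in deletion menu: {unknown}")
    del_names = sorted(cp.size_mix)
    del_weights = np.array([cp.size_mix[k] for k in del_names])

    ffs = _sample_ff(rng, cp, cp.n_cases)
    testing_names = sorted(cp.testing_probs)
    testing_weights = np.array([cp.testing_probs[k] for k in testing_names])

    samples: list[tuple[SampleTruth, BinProfile]] = []
    rows = []
    for i in range(cp.n_cases):
        if rng.random() < cp.p_maternal_suspected:
            origin = (
                "maternal_transmitted"
                if rng.random() < cp.p_transmit
                else "maternal_not_transmitted"
            )
        else:
            origin = "paternal_fetal" if rng.random() < cp.p_paternal else "fetal_de_novo"
        del_name = str(rng.choice(del_names, p=del_weights))
        interval = dels[del_name]
        ultrasound = bool(rng.random() < cp.p_ultrasound)
        testing = str(rng.choice(testing_names, p=testing_weights))
        sample_seed = int(rng.integers(0, 2**31 - 1))
        truth = SampleTruth(
            sample_id=f"sim_{i:05d}",
            ff=float(ffs[i]),
            scenario=DeletionScenario(origin=origin, interval=interval),
            seed=sample_seed,
        )
        profile = simulate_sample(truth, params, model.grid)
        samples.append((truth, profile))
        rows.append(
            {
                "sample_id": truth.sample_id,
                "origin": origin,
                "deletion": del_name,
                "chrom": interval.chrom,
                "start": interval.start,
                "end": interval.end,
                "true_size_mb": interval.length / 1e6,
                "ff": truth.ff,
                "ultrasound": ultrasound,
                "testing": testing,
                "seed": sample_seed,
            }
        )
    truth_table = pd.DataFrame(rows)
    return samples, truth_table


def simulate_null_panel(
    params: SimParams, grid: BinGrid, seed: int = 0, n: int | None = None
) -> np.ndarray:
    """Counts matrix (n_samples x n_bins) of unaffected plasma samples."""
    n = params.reference_panel_size if n is None else n
    rng = np.random.default_rng(seed)
    mean = np.full(grid.n_bins, params.mean_depth) * (
        params.bias if params.bias is not None else 1.0
    )
    return np.vstack([_draw_counts(rng, mean, params.dispersion) for _ in range(n)])
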