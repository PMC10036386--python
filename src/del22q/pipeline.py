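"""End-to-end orchestration: simulate -> call -> classify -> advise -> stats.

``run_end_to_end`` produces a fully deterministic result bundle (truth
table, deletion calls, origin classifications, testing recommendations,
statistics) from a :class:`RunConfig`; every output file carries the
seed and a config hash in its header, and identical seed+config yields
byte-identical outputs.

``reproduce_reference`` recomputes the published cohort's PPV scenarios
and headline percentages from the deterministic fixture and tabulates
them against the printed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import caller as caller_mod
from . import fish, origin, stats
from .fixture import reference_cohort
from .regions import RegionModel, load_region_model
from .simulate import (
    CohortParams,
    FETAL_CARRIER_ORIGINS,
    MATERNAL_ORIGINS,
    SimParams,
    generate_cohort,
    simulate_null_panel,
)

__all__ = ["RunConfig", "run_end_to_end", "reproduce_reference", "PUBLISHED_VALUES"]

#: printed values of the reference study, used only by the reproduction report
PUBLISHED_VALUES = {
    "ppv_complete": 99.4,
    "ppv_fetal_only": 98.7,
    "ppv_conservative": 90.7,
    "ppv_upper_bound": 99.7,
    "ppv_lower_bound": 57.3,
    "pct_suspected_maternal": 57.7,
    "pct_ultrasound": 51.1,
    "pct_diagnostic_testing": 63.2,
    "pct_deferred_postnatal": 45.8,
    "pct_cardiac_of_ultrasound": 60.5,
    "pct_fetal_inheritance": 58.1,
}


@dataclass
class RunConfig:
    seed: int = 1
    n_cases: int = 200
    outdir: str = "del22q_run"
    # region model
    region_bed: Optional[str] = None
    lcr_bed: Optional[str] = None
    probe_bed: Optional[str] = None
    bin_width: int = 50_000
    build: str = "GRCh38"
    # simulation
    mean_depth: float = 1000.0
    dispersion: float = 0.0
    panel_size: int = 50
    p_maternal_suspected: float = 0.577
    p_transmit: float = 0.5
    p_ultrasound: float = 0.511
    # thresholds
    z_threshold: float = 5.0
    min_bins: int = 2
    mr_cutoff: float = 3.0
    ci_method: str = "wilson"

    def __post_init__(self) -> None:
        for name in ("z_threshold", "mr_cutoff", "bin_width", "mean_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        for name in ("region_bed", "lcr_bed", "probe_bed"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise ValueError(f"config field {name}: file not found: {path}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def sha256(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _header(config: RunConfig) -> str:
    return f"# del22q\n# seed={config.seed}\n# config_sha256={config.sha256()}\n"


def _write_tsv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _write_json(path: Path, obj, config: RunConfig) -> None:
    payload = {"meta": {"seed": config.seed, "config_sha256": config.sha256()}, "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def derive_cohort_table(truth_table: pd.DataFrame, origin_calls: pd.Series) -> pd.DataFrame:
    """Map simulated truths + origin calls onto the cohort-record schema.

    Diagnostic verification is resolved from the simulated ground truth:
    a tested individual who carries the deletion confirms it (complete,
    true positive); if no tested individual carries it, the case is a
    complete false positive when the suspected individual was among
    those tested and incomplete otherwise (testing inadequate to rule
    the event out).  Untested cases stay unknown.
    """
    rows = []
    for (_, t), call in zip(truth_table.iterrows(), origin_calls):
        suspected = "maternal" if call == origin.LIKELY_MATERNAL else "fetal"
        mother_carries = t["origin"] in MATERNAL_ORIGINS
        fetus_carries = t["origin"] in FETAL_CARRIER_ORIGINS
        testing = t["testing"]
        tested_mother = testing in ("maternal_only", "both")
        tested_fetus = testing in ("fetal_only", "both")
        if testing == "none":
            completeness, confirmed = "none", "unknown"
        elif (tested_mother and mother_carries) or (tested_fetus and fetus_carries):
            completeness, confirmed = "complete", "true_positive"
        elif (suspected == "maternal" and tested_mother) or (
            suspected == "fetal" and tested_fetus
        ):
            completeness, confirmed = "complete", "false_positive"
        else:
            completeness, confirmed = "incomplete", "unknown"
        if suspected == "maternal" and tested_fetus:
            inherited = "yes" if fetus_carries else "no"
        else:
            inherited = "unknown"
        rows.append(
            {
                "case_id": t["sample_id"],
                "suspected_origin": suspected,
                "testing": testing,
                "completeness": completeness,
                "confirmed": confirmed,
                "fetal_inherited": inherited,
                "ultrasound": bool(t["ultrasound"]),
                "cardiac": False,
                "deferred_postnatal": False,
            }
        )
    return pd.DataFrame(rows)


def run_end_to_end(config: RunConfig) -> dict:
    """Run the whole pipeline and write the result bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = load_region_model(
        region_bed=config.region_bed,
        lcr_bed=config.lcr_bed,
        probe_bed=config.probe_bed,
        bin_width=config.bin_width,
        build=config.build,
    )
    ss = np.random.SeedSequence(config.seed)
    panel_seed, cohort_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    params = SimParams(
        mean_depth=config.mean_depth,
        dispersion=config.dispersion,
        reference_panel_size=config.panel_size,
    )
    cp = CohortParams(
        n_cases=config.n_cases,
        p_maternal_suspected=config.p_maternal_suspected,
        p_transmit=config.p_transmit,
        p_ultrasound=config.p_ultrasound,
    )

    panel = simulate_null_panel(params, model.grid, seed=panel_seed)
    det = caller_mod.DeletionCaller(
        model=model, z_threshold=config.z_threshold, min_bins=config.min_bins
    ).fit(panel)
    clf = origin.OriginClassifier(cutoff=config.mr_cutoff).fit()

    samples, truth_table = generate_cohort(cp, model, params, seed=cohort_seed)

    call_rows, classify_rows, recs = [], [], {}
    for truth, profile in samples:
        call = det.predict(profile)
        row = {"sample_id": truth.sample_id, "detected": call.detected}
        if call.detected:
            row.update(
                chrom=call.interval.chrom,
                start=call.interval.start,
                end=call.interval.end,
                size_mb=call.size_mb,
                z=round(call.z, 4),
                event_fraction=round(call.event_fraction, 4),
                n_bins=call.n_bins,
            )
            assessment = clf.assess(call.event_fraction, truth.ff)
            classify_rows.append(
                {
                    "sample_id": truth.sample_id,
                    "event_fraction": round(call.event_fraction, 4),
                    "ff": round(truth.ff, 4),
                    "mr": round(assessment.mr, 4),
                    "origin_call": assessment.origin_call,
                }
            )
            rec = fish.recommend_testing(call, assessment, model)
            recs[truth.sample_id] = {
                "probe_detectable": rec.probe_detectable,
                "fish_sufficient": rec.fish_sufficient,
                "recommended_assays": list(rec.recommended_assays),
                "maternal_testing_advised": rec.maternal_testing_advised,
            }
        call_rows.append(row)

    calls_df = pd.DataFrame(call_rows)
    classify_df = pd.DataFrame(classify_rows)

    origin_by_sample = classify_df.set_index("sample_id")["origin_call"] if len(classify_df) else pd.Series(dtype=object)
    detected_mask = truth_table["sample_id"].isin(origin_by_sample.index)
    cohort_table = derive_cohort_table(
        truth_table[detected_mask],
        origin_by_sample.loc[truth_table.loc[detected_mask, "sample_id"]].to_numpy(),
    )

    ppv = stats.ppv_scenarios(cohort_table, ci_method=config.ci_method)
    merged = calls_df[calls_df["detected"]].merge(truth_table, on="sample_id")
    conc = (
        stats.size_concordance(merged[["size_mb", "true_size_mb"]].to_numpy())
        if len(merged) >= 3 and merged["size_mb"].var() > 0
        else None
    )
    stats_obj = {
        "n_cases": config.n_cases,
        "n_detected": int(calls_df["detected"].sum()),
        "ppv": {
            name: (
                None
                if getattr(ppv, name) is None
                else {
                    "successes": getattr(ppv, name).successes,
                    "n": getattr(ppv, name).n,
                    "pct": getattr(ppv, name).pct,
                    "ci": list(getattr(ppv, name).ci),
                }
            )
            for name in ("complete", "fetal_only", "conservative", "upper_bound", "lower_bound")
        },
        "size_concordance": None
        if conc is None
        else {"slope": conc.slope, "intercept": conc.intercept, "r_squared": conc.r_squared, "n": conc.n},
        "summary": stats.summarize_cohort(cohort_table),
    }

    _write_tsv(outdir / "truth.tsv", truth_table, config)
    _write_tsv(outdir / "calls.tsv", calls_df, config)
    _write_tsv(outdir / "classifications.tsv", classify_df, config)
    _write_tsv(outdir / "cohort_table.tsv", cohort_table, config)
    _write_json(outdir / "recommendations.json", recs, config)
    _write_json(outdir / "stats.json", stats_obj, config)

    return {
        "model": model,
        "truth": truth_table,
        "calls": calls_df,
        "classifications": classify_df,
        "cohort_table": cohort_table,
        "recommendations": recs,
        "stats": stats_obj,
    }


def reproduce_reference(ci_method: str = "wilson") -> pd.DataFrame:
    """Recompute the published cohort numbers from the deterministic fixture.

    Returns a table with one row per quantity: computed value, expected
    printed value, and a pass flag.
    """
    cohort = reference_cohort()
    ppv = stats.ppv_scenarios(cohort, ci_method=ci_method)
    summary = stats.summarize_cohort(cohort)
    computed = {
        "ppv_complete": ppv.complete.pct,
        "ppv_fetal_only": ppv.fetal_only.pct,
        "ppv_conservative": ppv.conservative.pct,
        "ppv_upper_bound": ppv.upper_bound.pct,
        "ppv_lower_bound": ppv.lower_bound.pct,
        **{k: v["pct"] for k, v in summary.items() if k != "notes"},
    }
    rows = [
        {
            "quantity": name,
            "computed": computed[name],
            "expected": expected,
            "pass": computed[name] == expected,
        }
        for name, expected in PUBLISHED_VALUES.items()
    ]
    return pd.DataFrame(rows)
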