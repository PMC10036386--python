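"""Confirmatory-testing advice: will standard FISH probes see this deletion?

Clinical FISH probes for 22q11.2 (N25, TUPLE1/HIRA, TBX1) hybridize
between LCR22A and LCR22B, so nested deletions distal to that interval
(e.g. C-D) produce a normal FISH result despite a real deletion.
Microarray resolves size and gene content and is always recommended
first; FISH is listed only when every configured probe overlaps the
predicted interval.  A likely-maternal call additionally advises
maternal testing, since a confirmed maternal deletion carries a 50%
transmission risk to the fetus.

"Detectable" means >= 1 bp overlap between the predicted interval and
the probe target; hybridization efficiency is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .caller import DeletionCall
from .origin import LIKELY_MATERNAL, MosaicismAssessment
from .regions import RegionModel, overlap_bp

__all__ = ["TestingRecommendation", "probe_detectability", "recommend_testing"]

MICROARRAY = "microarray"
FISH = "FISH"


@dataclass(frozen=True)
class TestingRecommendation:
    probe_detectable: dict[str, bool]
    fish_sufficient: bool
    recommended_assays: tuple[str, ...]
    maternal_testing_advised: bool


def probe_detectability(call: DeletionCall, model: RegionModel) -> dict[str, bool]:
    """Per-probe flag: does the predicted interval overlap the probe target?"""
    if not call.detected or call.interval is None:
        raise ValueError("probe detectability requires a detected call with an interval")
    return {
        name: overlap_bp(call.interval, probe) > 0
        for name, probe in model.probes.items()
    }


def recommend_testing(
    call: DeletionCall,
    assessment: MosaicismAssessment,
    model: RegionModel,
) -> TestingRecommendation:
    """Ordered confirmatory-testing recommendation for a detected deletion.

    Microarray always comes first; FISH is appended only when all
    configured probes would detect the predicted interval; maternal
    testing is advised for likely-maternal calls.
    """
    detectable = probe_detectability(call, model)
    fish_sufficient = all(detectable.values())
    assays = (MICROARRAY, FISH) if fish_sufficient else (MICROARRAY,)
    return TestingRecommendation(
        probe_detectable=detectable,
        fish_sufficient=fish_sufficient,
        recommended_assays=assays,
        maternal_testing_advised=assessment.origin_call == LIKELY_MATERNAL,
    )
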