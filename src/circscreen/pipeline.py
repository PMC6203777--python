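"""End-to-end orchestration: detection in every library, union-catalog
quantification, the two no-replicate contrasts, and the coding screen."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import pandas as pd

from . import detect, quantde, screen
from .index import build_index
from .simulate import LIBRARIES, StudyData
from .types import CircCandidate, DeResult, ScreenCandidate

CONTRAST_TOTAL = ("normal_total", "tumor_total")
CONTRAST_RNC = ("normal_rnc", "tumor_rnc")


@dataclass
class AnalysisResult:
    detections: Dict[str, detect.DetectResult]
    counts: pd.DataFrame  # circ_id x library, junction reads
    de_total: List[DeResult]
    de_rnc: List[DeResult]
    screen_candidates: List[ScreenCandidate]
    funnel: Dict[str, int]
    catalog: Dict[str, CircCandidate] = field(default_factory=dict)


def analyze_study(
    study: StudyData,
    anchor: int = detect.DEFAULT_ANCHOR,
    m: int = 0,
    min_support: int = 2,
    bcv: float = quantde.DEFAULT_BCV,
    fc_threshold: float = quantde.DEFAULT_FC,
    fdr_threshold: float = quantde.DEFAULT_FDR,
    min_aa: int = screen.DEFAULT_MIN_AA,
    use_ires: bool = True,
) -> AnalysisResult:
    k = anchor if m == 0 else max(1, anchor // (m + 1))
    index = build_index(study.bundle.sequences, k=k)
    detections = {
        lib: detect.detect_library(
            reads, study.bundle, anchor=anchor, m=m,
            min_support=min_support, index=index,
        )
        for lib, reads in study.libraries.items()
    }

    de_libs = {lib: detections[lib] for lib in LIBRARIES if lib in detections}
    counts = detect.quantify(de_libs, min_support=min_support)
    records = quantde.records_from_counts(counts)
    de_total = quantde.call_degs(records, CONTRAST_TOTAL, bcv=bcv,
                                 fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)
    de_rnc = quantde.call_degs(records, CONTRAST_RNC, bcv=bcv,
                               fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)

    catalog: Dict[str, CircCandidate] = {}
    for res in de_libs.values():
        for cand in res.candidates:
            prev = catalog.get(cand.circ_id)
            if prev is None or cand.support > prev.support:
                catalog[cand.circ_id] = cand

    screen_candidates, funnel = screen.run_screen(
        de_total, de_rnc, list(catalog.values()), study.bundle.sequences,
        ires_intervals=study.ires_intervals if use_ires else None,
        min_aa=min_aa,
    )
    return AnalysisResult(
        detections=detections, counts=counts, de_total=de_total,
        de_rnc=de_rnc, screen_candidates=screen_candidates, funnel=funnel,
        catalog=catalog,
    )
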