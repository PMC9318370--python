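"""The 13 time-domain HRV descriptors computed per 60 s segment.

Definitions (RR in ms; "pairs" are successive-interval pairs whose members
were adjacent in the original stream — pairs spanning a removed interval
are never formed):

==============  ===========================================================
pRR50           100 x #{|RR_{n+1} - RR_n| >= 50 ms} / #pairs  [%]
SD1             SD over pairs of (RR_{n+1} - RR_n)/sqrt(2): Poincare-plot
                dispersion across the identity line (short-term HRV)  [ms]
SD2             SD over pairs of (RR_{n+1} + RR_n)/sqrt(2): dispersion
                along the identity line (long-term HRV)  [ms]
SD2/SD1         long-term to short-term variability ratio
SDRR            SD of the retained intervals  [ms]
RRdif           mean |RR_{n+1} - RR_n|  [ms]
CV              SDRR / meanRR
relRRdif        RRdif / meanRR
meanSuccRat     mean RR_{n+1} / RR_n
SDSuccRat       SD of RR_{n+1} / RR_n
meanRR          mean retained interval  [ms]
RRrange         max(RR) - min(RR)  [ms]
relRRrange      RRrange / meanRR
==============  ===========================================================

All standard deviations use the sample convention (denominator n - 1) by
default; ``ddof=0`` is available for sensitivity checks.  SD1/SD2 are
computed by rotating the Poincare cloud onto the identity line rather than
by the ellipse-fitting shortcut, so the rotation identity
SD1^2 + SD2^2 = Var(RR_n) + Var(RR_{n+1}) (over pairs) holds exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import InsufficientDataError
from .types import RRSegment

log = logging.getLogger(__name__)

#: canonical column order of the feature table
FEATURE_NAMES = [
    "pRR50", "SD1", "SD2", "SD2/SD1", "SDRR", "RRdif", "CV", "relRRdif",
    "meanSuccRat", "SDSuccRat", "meanRR", "RRrange", "relRRrange",
]

META_COLUMNS = ["patient_id", "database_tag", "segment_index", "rhythm_class"]


@dataclass
class FeatureVector:
    pRR50: float
    SD1: float
    SD2: float
    SD2_over_SD1: float
    SDRR: float
    RRdif: float
    CV: float
    relRRdif: float
    meanSuccRat: float
    SDSuccRat: float
    meanRR: float
    RRrange: float
    relRRrange: float
    valid_pair_count: int

    def as_dict(self) -> dict[str, float]:
        d = {
            "pRR50": self.pRR50, "SD1": self.SD1, "SD2": self.SD2,
            "SD2/SD1": self.SD2_over_SD1, "SDRR": self.SDRR,
            "RRdif": self.RRdif, "CV": self.CV, "relRRdif": self.relRRdif,
            "meanSuccRat": self.meanSuccRat, "SDSuccRat": self.SDSuccRat,
            "meanRR": self.meanRR, "RRrange": self.RRrange,
            "relRRrange": self.relRRrange,
        }
        d["valid_pair_count"] = self.valid_pair_count
        return d


def successive_pairs(segment: RRSegment) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (RR_n, RR_{n+1}) of pairs that were adjacent in the original
    stream; pairs bridging a removal gap are excluded."""
    rr = segment.rr_ms
    if len(rr) < 2:
        return np.empty(0), np.empty(0)
    adj = segment.adjacency
    return rr[:-1][adj], rr[1:][adj]


def compute_features(segment: RRSegment, *, ddof: int = 1,
                     prr_threshold_ms: float = 50.0) -> FeatureVector:
    """Compute the 13 descriptors for one segment.

    ``prr_threshold_ms`` is exposed for property testing only; the pipeline
    always uses the 50 ms counting threshold.  Raises
    :class:`InsufficientDataError` with fewer than 2 valid pairs.  SD2/SD1
    is NaN when SD1 = 0 (a degenerate, constant-difference segment); such
    rows are excluded downstream with a logged count.
    """
    rr = segment.rr_ms
    a, b = successive_pairs(segment)
    if len(a) < 2:
        raise InsufficientDataError(
            f"segment {segment.patient_id}/{segment.segment_index}: "
            f"{len(a)} valid pairs (< 2)")

    diffs = b - a
    mean_rr = float(np.mean(rr))
    sdrr = float(np.std(rr, ddof=ddof))
    rr_range = float(np.max(rr) - np.min(rr))
    prr = 100.0 * float(np.count_nonzero(np.abs(diffs) >= prr_threshold_ms)) / len(diffs)
    sd1 = float(np.std(diffs / np.sqrt(2.0), ddof=ddof))
    sd2 = float(np.std((a + b) / np.sqrt(2.0), ddof=ddof))
    ratio = np.nan if sd1 == 0.0 else sd2 / sd1
    rrdif = float(np.mean(np.abs(diffs)))
    succ = b / a
    return FeatureVector(
        pRR50=prr, SD1=sd1, SD2=sd2, SD2_over_SD1=float(ratio), SDRR=sdrr,
        RRdif=rrdif, CV=sdrr / mean_rr, relRRdif=rrdif / mean_rr,
        meanSuccRat=float(np.mean(succ)), SDSuccRat=float(np.std(succ, ddof=ddof)),
        meanRR=mean_rr, RRrange=rr_range, relRRrange=rr_range / mean_rr,
        valid_pair_count=int(len(a)),
    )


def build_feature_table(segments: list[RRSegment], *, ddof: int = 1,
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per usable segment: provenance, class label and the 13 features.

    Returns the table plus exclusion counters (segments with too few valid
    pairs, and segments whose SD2/SD1 is undefined because SD1 = 0).
    """
    rows = []
    exclusions = {"insufficient_pairs": 0, "undefined_ratio": 0}
    for seg in segments:
        try:
            fv = compute_features(seg, ddof=ddof)
        except InsufficientDataError:
            exclusions["insufficient_pairs"] += 1
            continue
        if not np.isfinite(fv.SD2_over_SD1):
            exclusions["undefined_ratio"] += 1
            continue
        row = {
            "patient_id": seg.patient_id, "database_tag": seg.database_tag,
            "segment_index": seg.segment_index, "rhythm_class": seg.rhythm_class,
        }
        row.update(fv.as_dict())
        rows.append(row)
    if exclusions["insufficient_pairs"] or exclusions["undefined_ratio"]:
        log.info("feature table exclusions: %s", exclusions)
    columns = META_COLUMNS + FEATURE_NAMES + ["valid_pair_count"]
    table = pd.DataFrame(rows, columns=columns)
    return table, exclusions


__all__ = ["FEATURE_NAMES", "META_COLUMNS", "FeatureVector",
           "successive_pairs", "compute_features", "build_feature_table"]
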