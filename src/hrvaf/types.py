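"""Core data containers for annotated RR streams and 60 s segments.

An :class:`RRRecording` is one patient's beat-to-beat stream: interval
durations in milliseconds plus a per-interval beat-type label (sinus /
supraventricular / ventricular / artifact) and rhythm label (AF / SR /
other).  An :class:`RRSegment` is one 60 s window that survived rhythm-purity
and artifact filtering, with adjacency flags marking which consecutive
retained intervals were actually consecutive in the original stream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

BEAT_LABELS = ("sinus", "supraventricular", "ventricular", "artifact")
RHYTHM_LABELS = ("AF", "SR", "other")


@dataclass
class RRRecording:
    """One patient's annotated RR-interval stream."""

    patient_id: str
    database_tag: str
    rr_ms: np.ndarray
    beat_label: np.ndarray
    rhythm_label: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_label = np.asarray(self.beat_label, dtype=object)
        self.rhythm_label = np.asarray(self.rhythm_label, dtype=object)
        n = len(self.rr_ms)
        if n < 1:
            raise ValueError("recording must contain at least one interval")
        if len(self.beat_label) != n or len(self.rhythm_label) != n:
            raise ValueError("rr_ms, beat_label and rhythm_label must have equal length")
        if not np.all(self.rr_ms > 0):
            raise ValueError("all RR durations must be strictly positive")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.rr_ms.sum())


@dataclass
class RRSegment:
    """A retained 60 s window of pure-rhythm RR intervals.

    ``adjacency[i]`` is True iff ``rr_ms[i]`` and ``rr_ms[i+1]`` were
    consecutive in the original stream; it is False across a removed
    (out-of-range) interval, so successive-difference statistics never
    bridge a removal gap.
    """

    patient_id: str
    database_tag: str
    segment_index: int
    rhythm_class: str
    rr_ms: np.ndarray
    adjacency: np.ndarray
    removed_ms_total: float = 0.0
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if len(self.adjacency) != max(len(self.rr_ms) - 1, 0):
            raise ValueError("adjacency must have length len(rr_ms) - 1")
        if self.rhythm_class not in ("AF", "SR"):
            raise ValueError("segment rhythm_class must be 'AF' or 'SR'")

    def __len__(self) -> int:
        return len(self.rr_ms)
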