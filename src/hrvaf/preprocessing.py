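"""Cutting RR recordings into filtered, pure-rhythm 60 s segments.

The recording is tiled from its start into consecutive, non-overlapping
windows of nominal 60 s; an interval belongs to the window containing its
starting beat.  A window is emitted iff

1. every interval in it carries the same rhythm label, AF or SR (windows
   mixing rhythms, or containing any other rhythm, are discarded);
2. after removing intervals outside the physiological [240, 3000] ms band,
   the removed durations total strictly less than 10% of the nominal window
   duration (>= 6 s removed, inclusive, discards the window);
3. at least ``min_retained_intervals`` intervals remain.

Only the duration rule removes intervals; beat-type labels are carried
through but never used for removal.  A trailing window not fully covered by
the recording is never emitted.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .types import RRRecording, RRSegment

log = logging.getLogger(__name__)

DISCARD_REASONS = (
    "mixed_rhythm", "other_rhythm", "artifact_excess", "too_few_intervals",
    "incomplete_window",
)


@dataclass
class SegmentationConfig:
    window_s: float = 60.0
    rr_min_ms: float = 240.0
    rr_max_ms: float = 3000.0
    max_removed_fraction: float = 0.10
    min_retained_intervals: int = 18
    anchor_offset_s: float = 0.0  # alternative window anchorings, off by default

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be positive")
        if not 0 < self.rr_min_ms < self.rr_max_ms:
            raise ConfigurationError("need 0 < rr_min_ms < rr_max_ms")
        if not 0 < self.max_removed_fraction <= 1:
            raise ConfigurationError("max_removed_fraction must lie in (0, 1]")
        if self.min_retained_intervals < 2:
            raise ConfigurationError("min_retained_intervals must be >= 2")


@dataclass
class SegmentationQC:
    """Per-recording bookkeeping of window outcomes."""

    patient_id: str
    database_tag: str
    n_windows: int = 0
    n_emitted: int = 0
    discarded: Counter = None
    # pure-rhythm windows per class before (total) / after (filtered) the
    # artifact-based discards -- the Table-2-shaped bookkeeping
    pure_total: Counter = None
    pure_filtered: Counter = None

    def __post_init__(self):
        self.discarded = Counter() if self.discarded is None else self.discarded
        self.pure_total = Counter() if self.pure_total is None else self.pure_total
        self.pure_filtered = Counter() if self.pure_filtered is None else self.pure_filtered


def segment_recording(recording: RRRecording | None,
                      config: SegmentationConfig | None = None,
                      ) -> tuple[list[RRSegment], SegmentationQC]:
    """Tile a recording into windows and apply the purity/artifact filters."""
    config = config or SegmentationConfig()
    config.validate()
    if recording is None or len(recording) == 0:
        return [], SegmentationQC("", "")

    qc = SegmentationQC(recording.patient_id, recording.database_tag)
    window_ms = config.window_s * 1000.0
    ends = np.cumsum(recording.rr_ms)
    starts = ends - recording.rr_ms
    offset = config.anchor_offset_s * 1000.0
    widx = np.floor((starts - offset) / window_ms).astype(int)
    widx[widx < 0] = -1  # intervals before the anchor are never windowed

    segments: list[RRSegment] = []
    seg_counter = 0
    for w in np.unique(widx):
        if w < 0:
            continue
        sel = widx == w
        qc.n_windows += 1
        window_end = offset + (w + 1) * window_ms
        if ends[sel][-1] < window_end - 1e-9:
            qc.discarded["incomplete_window"] += 1
            continue
        labels = set(recording.rhythm_label[sel])
        if "other" in labels or not labels <= {"AF", "SR"}:
            qc.discarded["other_rhythm"] += 1
            continue
        if len(labels) != 1:
            qc.discarded["mixed_rhythm"] += 1
            continue
        rhythm = labels.pop()
        qc.pure_total[rhythm] += 1

        rr = recording.rr_ms[sel]
        keep = (rr >= config.rr_min_ms) & (rr <= config.rr_max_ms)
        removed_ms = float(rr[~keep].sum())
        if removed_ms >= config.max_removed_fraction * window_ms:
            qc.discarded["artifact_excess"] += 1
            continue
        kept_idx = np.flatnonzero(keep)
        if len(kept_idx) < config.min_retained_intervals:
            qc.discarded["too_few_intervals"] += 1
            continue
        adjacency = np.diff(kept_idx) == 1
        segments.append(RRSegment(
            patient_id=recording.patient_id,
            database_tag=recording.database_tag,
            segment_index=seg_counter,
            rhythm_class=rhythm,
            rr_ms=rr[kept_idx],
            adjacency=adjacency,
            removed_ms_total=removed_ms,
            n_removed=int((~keep).sum()),
        ))
        seg_counter += 1
        qc.n_emitted += 1
        qc.pure_filtered[rhythm] += 1
    return segments, qc


def segment_cohort(recordings: Iterable[RRRecording],
                   config: SegmentationConfig | None = None,
                   ) -> tuple[list[RRSegment], list[SegmentationQC]]:
    """Segment every recording of a cohort, collecting per-recording QC."""
    all_segments, qcs = [], []
    for rec in recordings:
        segs, qc = segment_recording(rec, config)
        all_segments.extend(segs)
        qcs.append(qc)
    return all_segments, qcs


def summarize_filtering(qcs: Iterable[SegmentationQC],
                        split_of_patient: Mapping[str, str] | None = None,
                        ) -> pd.DataFrame:
    """Segment counts per class and data split, before/after artifact discards.

    ``split_of_patient`` maps patient_id to a split name (e.g. ``Training`` /
    ``Test``); unmapped patients are pooled under ``all``.  Returns one row
    per split with AF/SR totals and post-filter counts.
    """
    buckets: dict[str, Counter] = {}
    for qc in qcs:
        split = (split_of_patient or {}).get(qc.patient_id, "all")
        b = buckets.setdefault(split, Counter())
        for cls in ("AF", "SR"):
            b[f"{cls}_total"] += qc.pure_total[cls]
            b[f"{cls}_filtered"] += qc.pure_filtered[cls]
    cols = ["AF_total", "AF_filtered", "SR_total", "SR_filtered"]
    if not buckets:
        return pd.DataFrame([{c: 0 for c in cols}], index=["all"]).rename_axis("dataset")
    df = pd.DataFrame.from_dict(buckets, orient="index").reindex(columns=cols, fill_value=0)
    return df.sort_index().rename_axis("dataset")


# ---------------------------------------------------------------------------
# optional adapter: plain-text annotation files (rdann-style export)

_BEAT_MAP = {"N": "sinus", "S": "supraventricular", "A": "supraventricular",
             "V": "ventricular", "|": "artifact", "~": "artifact", "Q": "artifact"}
_RHYTHM_MAP = {"(AFIB": "AF", "(AF": "AF", "(N": "SR", "(NSR": "SR", "(SR": "SR"}


def read_rr_annotation_text(path: str | Path) -> RRRecording:
    """Read an RR recording from a plain-text annotation export.

    Format: one annotation per line, ``time_s<TAB>symbol[<TAB>aux]``.  Beat
    annotations carry a beat symbol (N/S/A/V/|/~/Q); rhythm changes carry
    symbol ``+`` with the rhythm string in the aux field.  RR intervals are
    the differences of consecutive beat times; each interval takes the beat
    label of its opening beat and the rhythm carried forward from the most
    recent rhythm-change annotation.  Unknown rhythm strings map to
    ``other`` with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file not found: {path}")
    beat_times, beat_syms, rhythm_events = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise IOError(f"malformed line {ln} in {path}: {line!r}")
            t, sym = float(parts[0]), parts[1]
            if sym == "+":
                aux = parts[2] if len(parts) > 2 else ""
                rhythm = _RHYTHM_MAP.get(aux)
                if rhythm is None:
                    log.warning("unknown rhythm %r at t=%.3f in %s -> 'other'", aux, t, path)
                    rhythm = "other"
                rhythm_events.append((t, rhythm))
            else:
                beat_times.append(t)
                beat_syms.append(sym)
    if len(beat_times) < 2:
        raise IOError(f"fewer than two beat annotations in {path}")
    times = np.asarray(beat_times)
    rr = np.diff(times) * 1000.0
    beats = np.array([_BEAT_MAP.get(s, "artifact") for s in beat_syms[:-1]], dtype=object)
    rhythms = np.full(len(rr), "other", dtype=object)
    if rhythm_events:
        ev_t = np.array([t for t, _ in rhythm_events])
        ev_r = np.array([r for _, r in rhythm_events], dtype=object)
        idx = np.searchsorted(ev_t, times[:-1], side="right") - 1
        ok = idx >= 0
        rhythms[ok] = ev_r[idx[ok]]
    return RRRecording(path.stem, path.parent.name or "adapter", rr, beats, rhythms)


def write_rr_annotation_text(recording: RRRecording, path: str | Path) -> Path:
    """Write a recording in the adapter's annotation format (for round-trips)."""
    path = Path(path)
    inv_beat = {"sinus": "N", "supraventricular": "S", "ventricular": "V", "artifact": "|"}
    inv_rhythm = {"AF": "(AFIB", "SR": "(N", "other": "(OTHER"}
    times = [float(t) for t in
             np.concatenate([[0.0], np.cumsum(recording.rr_ms) / 1000.0])]
    with open(path, "w") as fh:
        fh.write("# time_s\tsymbol\taux\n")
        last_rhythm = None
        for i in range(len(recording)):
            r = recording.rhythm_label[i]
            if r != last_rhythm:
                fh.write(f"{times[i]!r}\t+\t{inv_rhythm.get(r, '(OTHER')}\n")
                last_rhythm = r
            fh.write(f"{times[i]!r}\t{inv_beat.get(recording.beat_label[i], 'Q')}\n")
        fh.write(f"{times[-1]!r}\tN\n")  # closing beat of the final interval
    return path


# ---------------------------------------------------------------------------
# segment persistence (delimited text, one row per segment)


def write_segments(segments: list[RRSegment], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in segments:
        rows.append({
            "patient_id": s.patient_id, "database_tag": s.database_tag,
            "segment_index": s.segment_index, "rhythm_class": s.rhythm_class,
            "removed_ms_total": s.removed_ms_total, "n_removed": s.n_removed,
            "rr_ms": ";".join(repr(float(v)) for v in s.rr_ms),
            "adjacency": "".join("1" if a else "0" for a in s.adjacency),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_segments(path: str | Path) -> list[RRSegment]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        rr = np.array([float(v) for v in str(row["rr_ms"]).split(";")])
        adj = np.array([c == "1" for c in str(row["adjacency"])], dtype=bool)
        out.append(RRSegment(
            str(row["patient_id"]), str(row["database_tag"]),
            int(row["segment_index"]), str(row["rhythm_class"]),
            rr, adj, float(row["removed_ms_total"]), int(row["n_removed"])))
    return out


__all__ = [
    "SegmentationConfig", "SegmentationQC", "segment_recording",
    "segment_cohort", "summarize_filtering", "read_rr_annotation_text",
    "write_rr_annotation_text", "write_segments", "read_segments",
]
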