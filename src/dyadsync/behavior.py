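"""Behavioral microcoding proportions and the CIB safety composite.

Event logs carry second-by-second coded intervals on two channels (gaze,
affect). Three infant measures are derived:

* visual attention — time gazing at the adult (social gaze or joint
  attention), excluding negative-affect moments, as a proportion of
  codable, non-negative session time;
* positive arousal — positive-affect time as a proportion of codable
  session time;
* CIB safety — mean of seven 5-point items, with dyadic tension reversed
  (6 - x) so all items point the same way.

Gaps (time not covered by any interval) are treated as uncodable with a
warning; a coverage warning is also emitted when codable time drops
below half the session.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

from .datatypes import BehaviorScores, EventLog

__all__ = [
    "read_event_log",
    "visual_attention",
    "positive_arousal",
    "cib_safety",
    "behavior_scores",
    "GAZE_CODES",
    "AFFECT_CODES",
    "CIB_SAFETY_ITEMS",
]

GAZE_CODES = frozenset(
    {
        "social_gaze",
        "gaze_to_object",
        "joint_attention",
        "gaze_aversion",
        "gaze_to_environment",
        "drowsy",
        "uncodable",
    }
)
AFFECT_CODES = frozenset({"positive", "neutral", "negative", "uncodable"})

CIB_SAFETY_ITEMS = (
    "adult_supportive_presence",
    "infant_positive_affect",
    "infant_initiation",
    "infant_lead_interaction",
    "dyadic_reciprocity",
    "dyadic_adaptation_regulation",
    "dyadic_tension",
)


def read_event_log(
    path: str | Path,
    channel: str,
    session_duration: float | None = None,
) -> EventLog:
    """Read a ``code,onset_s,offset_s`` CSV into a validated EventLog.

    Unknown codes, negative times and within-channel overlaps are
    rejected. An empty file yields a valid empty log (downstream
    proportions will then fail on an empty denominator).
    """
    allowed = {"gaze": GAZE_CODES, "affect": AFFECT_CODES}.get(channel)
    if allowed is None:
        raise ValueError(f"channel must be 'gaze' or 'affect', got {channel!r}")
    intervals: list[tuple[str, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is not None:
            expected = {"code", "onset_s", "offset_s"}
            if not expected.issubset(set(reader.fieldnames)):
                raise ValueError(f"header must contain {sorted(expected)}")
        for row in reader:
            code = row["code"].strip()
            if code not in allowed:
                raise ValueError(f"unknown {channel} code {code!r}")
            onset = float(row["onset_s"])
            offset = float(row["offset_s"])
            if onset < 0 or offset <= onset:
                raise ValueError(f"invalid interval [{onset}, {offset}) for {code!r}")
            intervals.append((code, onset, offset))
    duration = session_duration
    if duration is None:
        duration = max((off for _, _, off in intervals), default=0.0)
    return EventLog(channel=channel, intervals=intervals, session_duration=duration)


def _merge(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(lo, hi) for lo, hi in out]


def _total(spans: list[tuple[float, float]]) -> float:
    return sum(hi - lo for lo, hi in _merge(spans))


def _intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> list[tuple[float, float]]:
    a = _merge(a)
    b = _merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _gaps(log: EventLog) -> list[tuple[float, float]]:
    """Uncovered time within [0, session_duration]."""
    covered = _merge([(on, off) for _, on, off in log.intervals])
    gaps = []
    cursor = 0.0
    for lo, hi in covered:
        if lo > cursor + 1e-9:
            gaps.append((cursor, min(lo, log.session_duration)))
        cursor = max(cursor, hi)
    if cursor < log.session_duration - 1e-9:
        gaps.append((cursor, log.session_duration))
    return gaps


def _uncodable_spans(log: EventLog) -> list[tuple[float, float]]:
    gaps = _gaps(log)
    if _total(gaps) > 1e-9:
        warnings.warn(
            f"{log.channel} log leaves {_total(gaps):.1f} s uncovered; treated as uncodable"
        )
    return log.spans("uncodable") + gaps


def _coverage_check(log: EventLog, codable: float) -> None:
    if log.session_duration > 0 and codable < 0.5 * log.session_duration:
        warnings.warn(
            f"codable {log.channel} time ({codable:.1f} s) below half the session"
        )


def visual_attention(gaze: EventLog, affect: EventLog) -> float:
    """Proportion of codable time the infant gazed at the adult.

    Numerator: social gaze plus joint attention, minus any overlap with
    negative affect. Denominator: session time minus the union of
    uncodable-gaze and negative-affect time. Raises when the denominator
    is not positive.
    """
    if gaze.channel != "gaze" or affect.channel != "affect":
        raise ValueError("expected (gaze, affect) logs in that order")
    if abs(gaze.session_duration - affect.session_duration) > 1e-6:
        raise ValueError("logs must cover the same session")
    attention = gaze.spans("social_gaze", "joint_attention")
    negative = affect.spans("negative")
    excluded = _uncodable_spans(gaze) + negative
    denom = gaze.session_duration - _total(excluded)
    _coverage_check(gaze, denom)
    if denom <= 1e-9:
        raise ValueError("no codable non-negative time: denominator is empty")
    num = _total(attention) - _total(_intersect(attention, negative))
    return num / denom


def positive_arousal(affect: EventLog) -> float:
    """Positive-affect time as a proportion of codable session time."""
    if affect.channel != "affect":
        raise ValueError("expected an affect log")
    denom = affect.session_duration - _total(_uncodable_spans(affect))
    _coverage_check(affect, denom)
    if denom <= 1e-9:
        raise ValueError("no codable affect time: denominator is empty")
    return affect.duration_of("positive") / denom


def cib_safety(items: dict[str, float]) -> float:
    """Mean of the seven safety items with dyadic tension reversed.

    All seven items must be present and within the 1-5 Likert range;
    tension is aligned with the others as ``6 - x`` before averaging.
    """
    missing = [k for k in CIB_SAFETY_ITEMS if k not in items]
    if missing:
        raise ValueError(f"missing CIB items: {missing}")
    aligned = []
    for key in CIB_SAFETY_ITEMS:
        v = float(items[key])
        if not (1.0 <= v <= 5.0):
            raise ValueError(f"item {key!r} out of Likert range: {v}")
        aligned.append(6.0 - v if key == "dyadic_tension" else v)
    return sum(aligned) / len(aligned)


def behavior_scores(
    gaze: EventLog, affect: EventLog, cib_items: dict[str, float] | None = None
) -> BehaviorScores:
    """Bundle the three infant measures for one session."""
    return BehaviorScores(
        visual_attention=visual_attention(gaze, affect),
        positive_arousal=positive_arousal(affect),
        cib_safety=cib_safety(cib_items) if cib_items is not None else None,
    )
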