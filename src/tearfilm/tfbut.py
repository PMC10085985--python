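"""Blink segmentation and tear-film breakup time (TFBUT) estimation.

The per-frame label stream is converted to a per-eye TFBUT the way a
clinician reads the exam: each eye opening after a blink restarts the clock
at 0 s, the breakup time of that inter-blink segment is the time until the
first breakup-positive frame, and the reported TFBUT is the mean of the
first three measured (uncensored) segments. A segment that ends in the next
blink without any breakup only bounds its breakup time from below
(censoring); the censored value equals the segment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BlinkSegment",
    "TFBUTResult",
    "detect_eye_openings",
    "segment_breakup_time",
    "estimate_tfbut",
    "tfbut_from_table",
]


@dataclass
class BlinkSegment:
    """One inter-blink interval, from eye opening to the next blink closure."""

    opening_time_s: float
    end_time_s: float
    frame_indices: list[int] = field(default_factory=list)  # quality-passing rows
    breakup_time_s: float | None = None  # seconds after opening; None = not yet set
    censored: bool = False

    @property
    def length_s(self) -> float:
        return self.end_time_s - self.opening_time_s


@dataclass
class TFBUTResult:
    segments: list[BlinkSegment]
    tfbut_s: float
    n_segments_used: int
    censored_flag: bool
    is_lower_bound: bool = False
    warning: str | None = None

    @property
    def short_tfbut(self) -> bool:
        """ADES short-TFBUT criterion: measured (or bounded) TFBUT <= 5 s."""
        return self.tfbut_s <= 5.0


def detect_eye_openings(table: pd.DataFrame) -> list[BlinkSegment]:
    """Segment the frame timeline at blinks.

    A blink is a maximal run of frames excluded for a missing cornea
    (``reason == "no_cornea"``); the opening time is the timestamp of the
    first quality-passing frame after the run, and the segment extends to
    the onset of the next blink (or to the end of the recording). Frames
    before the first blink are discarded — their eye-opening time is not
    observed.
    """
    ts = table["timestamp_s"].to_numpy(dtype=float)
    is_blink = (table["reason"] == "no_cornea").to_numpy()
    is_pass = (table["quality"] == "pass").to_numpy()
    n = len(table)
    if n == 0:
        raise ValueError("empty frame table")

    # maximal no_cornea runs
    runs: list[tuple[int, int]] = []  # [start, end) row indices
    i = 0
    while i < n:
        if is_blink[i]:
            j = i
            while j < n and is_blink[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    segments: list[BlinkSegment] = []
    interval = float(np.median(np.diff(ts))) if n > 1 else 0.0
    for k, (_, run_end) in enumerate(runs):
        # opening = first passing frame after the blink run
        open_row = None
        next_blink_row = runs[k + 1][0] if k + 1 < len(runs) else n
        for r in range(run_end, next_blink_row):
            if is_pass[r]:
                open_row = r
                break
        if open_row is None:
            continue  # no usable frame in this interval
        opening = float(ts[open_row])
        end = float(ts[next_blink_row]) if next_blink_row < n else float(ts[-1]) + interval
        frame_idx = [r for r in range(open_row, next_blink_row) if is_pass[r]]
        segments.append(
            BlinkSegment(opening_time_s=opening, end_time_s=end, frame_indices=frame_idx)
        )
    return segments


def segment_breakup_time(
    segment: BlinkSegment,
    table: pd.DataFrame,
    persistence: int = 1,
) -> BlinkSegment:
    """Fill in the breakup time of one segment from the labeled frame table.

    The breakup time is the timestamp of the first positive quality-passing
    frame (required to stay positive for ``persistence`` consecutive passing
    frames) minus the opening time; if no such frame exists the segment is
    censored at its length.
    """
    if not segment.frame_indices:
        raise ValueError("segment contains no quality-passing frames")
    labels = table["label"].to_numpy()
    ts = table["timestamp_s"].to_numpy(dtype=float)
    rows = segment.frame_indices
    pos = [labels[r] == "positive" for r in rows]
    onset = None
    for j in range(len(rows)):
        if all(pos[j : j + persistence]) and len(pos[j : j + persistence]) == persistence:
            onset = rows[j]
            break
    if onset is None:
        segment.breakup_time_s = segment.length_s
        segment.censored = True
    else:
        segment.breakup_time_s = float(ts[onset]) - segment.opening_time_s
        segment.censored = False
    return segment


def estimate_tfbut(segments: list[BlinkSegment]) -> TFBUTResult:
    """Average the first three uncensored segment breakup times.

    With fewer than three uncensored segments the available ones are
    averaged and the result is flagged; with none, the reported value is the
    smallest censored bound and is a lower bound only (usable for the
    "TFBUT > 5 s" side of the diagnostic decision, never as a measurement).
    """
    if not segments:
        raise ValueError("no blink segments to estimate TFBUT from")
    if any(s.breakup_time_s is None for s in segments):
        raise ValueError("segments must have breakup times filled in first")
    uncensored = [s.breakup_time_s for s in segments if not s.censored]
    warning = None
    if len(segments) < 3:
        warning = (
            f"only {len(segments)} complete blink segments; the protocol calls "
            "for three measurements"
        )
    first_three = segments[:3]
    censored_flag = any(s.censored for s in first_three) or len(first_three) < 3
    if uncensored:
        used = uncensored[:3]
        return TFBUTResult(
            segments=segments,
            tfbut_s=float(np.mean(used)),
            n_segments_used=len(used),
            censored_flag=censored_flag,
            is_lower_bound=False,
            warning=warning,
        )
    bound = min(s.breakup_time_s for s in segments)
    return TFBUTResult(
        segments=segments,
        tfbut_s=float(bound),
        n_segments_used=0,
        censored_flag=True,
        is_lower_bound=True,
        warning=warning,
    )


def tfbut_from_table(table: pd.DataFrame, persistence: int = 1) -> TFBUTResult:
    """Frame table (timestamp_s, quality, reason, label) -> TFBUTResult."""
    segments = detect_eye_openings(table)
    if not segments:
        raise ValueError("no blink segments found in the frame table")
    segments = [
        segment_breakup_time(s, table, persistence=persistence)
        for s in segments
        if s.frame_indices
    ]
    return estimate_tfbut(segments)


def result_to_dict(result: TFBUTResult) -> dict:
    """JSON-ready summary of a TFBUT estimate."""
    return {
        "tfbut_s": result.tfbut_s,
        "n_segments_used": result.n_segments_used,
        "censored_flag": result.censored_flag,
        "is_lower_bound": result.is_lower_bound,
        "warning": result.warning,
        "segments": [
            {
                "opening_time_s": s.opening_time_s,
                "end_time_s": s.end_time_s,
                "breakup_time_s": s.breakup_time_s,
                "censored": s.censored,
            }
            for s in result.segments
        ],
    }
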