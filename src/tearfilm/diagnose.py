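"""ADES dry-eye diagnosis: short TFBUT plus positive subjective symptoms.

The revised Asia Dry Eye Society criteria diagnose dry eye disease when the
tear film is unstable (TFBUT of 5 s or less) *and* the patient reports
symptoms (OSDI questionnaire score over 13). Both boundaries are sharp:
TFBUT exactly 5.0 s is short, an OSDI of exactly 13 is not symptomatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CaseRecord", "compute_osdi", "diagnose", "diagnose_cases"]

TFBUT_CUTOFF_S = 5.0
OSDI_CUTOFF = 13.0
N_OSDI_ITEMS = 12


@dataclass
class CaseRecord:
    """One eye of one case, with its estimate and (optionally) references."""

    case_id: str
    eye: str  # "right" | "left"
    tfbut_s: float
    osdi_score: float
    tfbut_is_lower_bound: bool = False
    predicted_dx: str | None = None  # "DED" | "non-DED"
    reference_dx: str = "unknown"
    reference_tfbut_s: float | None = None


def compute_osdi(responses: Sequence[float | None]) -> float:
    """Score the 12-item OSDI questionnaire.

    Each item is scored 0-4 or left unanswered (None/NaN); the total is
    ``sum(answered) * 100 / (4 * n_answered)``, giving a 0-100 scale that is
    robust to skipped items. At least one item must be answered.
    """
    if len(responses) != N_OSDI_ITEMS:
        raise ValueError(f"OSDI has {N_OSDI_ITEMS} items, got {len(responses)}")
    answered = [r for r in responses if r is not None and not (isinstance(r, float) and np.isnan(r))]
    if not answered:
        raise ValueError("all OSDI items unanswered; the score is undefined")
    for r in answered:
        if not (0 <= r <= 4):
            raise ValueError(f"OSDI item score {r} outside the 0-4 range")
    return float(sum(answered) * 100.0 / (4.0 * len(answered)))


def diagnose(tfbut_s: float, osdi_score: float) -> str:
    """Apply the ADES rule: DED iff TFBUT <= 5 s and OSDI > 13.

    A censored TFBUT (lower bound) is compared as its bound: a bound above
    5 s rules out a short TFBUT; a bound at or below 5 s cannot rule it in,
    but by the comparison convention it counts as short only if the bound
    itself is <= 5 (the most conservative reading available without an
    observed breakup).
    """
    if osdi_score is None or (isinstance(osdi_score, float) and np.isnan(osdi_score)):
        raise ValueError("OSDI score is required to evaluate the ADES criteria")
    if not (0.0 <= osdi_score <= 100.0):
        raise ValueError(f"OSDI score {osdi_score} outside the 0-100 range")
    if tfbut_s is None or (isinstance(tfbut_s, float) and np.isnan(tfbut_s)):
        raise ValueError("TFBUT is required to evaluate the ADES criteria")
    short_tfbut = tfbut_s <= TFBUT_CUTOFF_S
    symptomatic = osdi_score > OSDI_CUTOFF
    return "DED" if (short_tfbut and symptomatic) else "non-DED"


def diagnose_cases(cases: pd.DataFrame) -> pd.DataFrame:
    """Add a ``predicted_dx`` column to a case table.

    The table needs ``tfbut_s`` plus either ``osdi_score`` or the twelve
    response columns ``osdi_q1`` .. ``osdi_q12`` (NaN = unanswered).
    """
    out = cases.copy()
    if "osdi_score" not in out.columns:
        qcols = [f"osdi_q{i}" for i in range(1, N_OSDI_ITEMS + 1)]
        missing = [c for c in qcols if c not in out.columns]
        if missing:
            raise ValueError(f"case table lacks osdi_score and response columns {missing}")
        out["osdi_score"] = [
            compute_osdi([None if pd.isna(v) else float(v) for v in row])
            for row in out[qcols].itertuples(index=False)
        ]
    out["predicted_dx"] = [
        diagnose(t, o) for t, o in zip(out["tfbut_s"], out["osdi_score"])
    ]
    return out
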