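"""End-to-end plumbing: video -> frame table -> TFBUT -> diagnosis.

Also hosts the synthetic cohort builder used for pipeline-level validation:
a set of simulated eyes spanning the four quadrants of the diagnostic rule
(short/normal TFBUT x symptomatic/asymptomatic OSDI), each run through the
full chain and scored against its simulated reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as _classify
from . import diagnose as _diagnose
from . import simulate as _simulate
from . import tfbut as _tfbut
from .preprocess import (
    DEFAULT_QUALITY,
    FrameSequence,
    QualityParams,
    preprocess_sequence,
    records_to_table,
)

__all__ = [
    "label_frame_table",
    "analyze_sequence",
    "true_labels_for_table",
    "build_cohort_config",
    "run_cohort",
]


def label_frame_table(
    records,
    model: "_classify.ClassifierModel",
    decision_threshold: float | None = None,
) -> pd.DataFrame:
    """Classify quality-passing records and return the full frame table."""
    _classify.classify_records(records, model, decision_threshold)
    return records_to_table(records)


def analyze_sequence(
    seq: FrameSequence,
    model: "_classify.ClassifierModel | None" = None,
    interval_s: float = 0.2,
    quality_params: QualityParams = DEFAULT_QUALITY,
    persistence: int = 1,
    already_sliced: bool = False,
) -> tuple[pd.DataFrame, "_tfbut.TFBUTResult"]:
    """Run the imaging chain on one recording and estimate its TFBUT."""
    if model is None:
        model = _classify.RuleBasedClassifier()
    records = preprocess_sequence(
        seq, interval_s=interval_s, quality_params=quality_params,
        already_sliced=already_sliced,
    )
    table = label_frame_table(records, model)
    result = _tfbut.tfbut_from_table(table, persistence=persistence)
    return table, result


def true_labels_for_table(
    gt: "_simulate.GroundTruth", table: pd.DataFrame
) -> pd.Series:
    """Ground-truth label of the source frame behind each table row."""
    labels = [gt.per_frame_labels[int(i)] for i in table["source_index"]]
    return pd.Series(labels, index=table.index, name="true_label")


def _osdi_responses(rng: np.random.Generator, symptomatic: bool) -> list[int]:
    """Item responses placing the OSDI score clearly on one side of 13."""
    if symptomatic:
        return [int(v) for v in rng.integers(1, 5, size=12)]  # score in [25, 100]
    k = int(rng.integers(0, 7))  # score k*100/48 <= 12.5
    items = np.zeros(12, dtype=int)
    items[rng.choice(12, size=k, replace=False)] = 1
    return [int(v) for v in items]


def config_for_breakup_times(
    breakup_times_s: tuple[float, ...],
    seed: int,
    resolution: tuple[int, int] = (192, 256),
    margin_s: float = 0.8,
    **kwargs,
) -> "_simulate.SimulationConfig":
    """Simulation config whose segments are long enough for the given breakups.

    The blink spacing is sized so that even the worst-case jittered segment
    exceeds the latest breakup time by ``margin_s``.
    """
    n = len(breakup_times_s)
    max_bt = max(t for t in breakup_times_s if t is not None)
    blink = kwargs.get("blink_duration_s", 0.3)
    jitter = kwargs.get("blink_jitter_frac", 0.1)
    spacing = (max_bt + margin_s + blink) / max(1.0 - 2.0 * jitter, 0.1)
    duration = float((n + 1) * spacing)
    return _simulate.SimulationConfig(
        duration_s=duration,
        resolution=resolution,
        n_blinks=n,
        true_breakup_times_s=tuple(breakup_times_s),
        seed=seed,
        **kwargs,
    )


def build_cohort_config(
    case_seed: int,
    short_tfbut: bool,
    resolution: tuple[int, int] = (192, 256),
    artifact_rate: float | None = None,
    noise_sd: float | None = None,
) -> "_simulate.SimulationConfig":
    """Simulation config for one cohort eye.

    Short-TFBUT eyes break up at 2.0-4.2 s per segment (mean well under the
    5-s cutoff); stable eyes at 6.2-8.0 s (mean well over it). Segment
    lengths are sized so every configured breakup fits.
    """
    rng = np.random.default_rng((case_seed, 11))
    if short_tfbut:
        times = tuple(float(t) for t in rng.uniform(2.0, 4.2, size=3))
    else:
        times = tuple(float(t) for t in rng.uniform(6.2, 8.0, size=3))
    kwargs = {}
    if artifact_rate is not None:
        kwargs["artifact_rate"] = artifact_rate
    if noise_sd is not None:
        kwargs["noise_sd"] = noise_sd
    return config_for_breakup_times(times, seed=case_seed, resolution=resolution, **kwargs)


def run_cohort(
    n_cases: int = 40,
    seed: int = 0,
    mode: str = "detector",
    resolution: tuple[int, int] = (192, 256),
    artifact_rate: float | None = None,
    noise_sd: float | None = None,
    model: "_classify.ClassifierModel | None" = None,
) -> pd.DataFrame:
    """Simulate a cohort and push every eye through the diagnostic chain.

    Half the cases sit in the DED quadrant (short TFBUT and symptomatic);
    the rest are spread over the other three quadrants. ``mode`` selects the
    frame-label source: ``"oracle"`` reads the simulator's labels (isolates
    the timing and diagnosis logic), ``"detector"`` renders the frames and
    runs the imaging chain.

    Returns a case table with estimated and reference TFBUT, OSDI, and the
    predicted and reference diagnoses.
    """
    if mode not in ("oracle", "detector"):
        raise ValueError("mode must be 'oracle' or 'detector'")
    rng = np.random.default_rng((seed, 7))
    rows = []
    # quadrant plan: half (short, symptomatic); remainder cycles the others
    others = [(False, False), (False, True), (True, False)]
    for i in range(n_cases):
        if i < n_cases // 2:
            short, symptomatic = True, True
        else:
            short, symptomatic = others[i % 3]
        case_seed = int(seed * 100003 + i) % (2**31)
        config = build_cohort_config(
            case_seed, short, resolution=resolution,
            artifact_rate=artifact_rate, noise_sd=noise_sd,
        )
        gt = _simulate.ground_truth(config)
        if mode == "oracle":
            table = _simulate.oracle_frame_table(gt, config)
            result = _tfbut.tfbut_from_table(table)
        else:
            seq, gt = _simulate.generate_sliced(config)
            table, result = analyze_sequence(seq, model=model, already_sliced=True)
        osdi = _diagnose.compute_osdi(_osdi_responses(rng, symptomatic))
        predicted = _diagnose.diagnose(result.tfbut_s, osdi)
        reference = _diagnose.diagnose(gt.true_tfbut_s, osdi)
        rows.append(
            {
                "case_id": f"case{i:03d}",
                "eye": "right" if i % 2 == 0 else "left",
                "tfbut_s": result.tfbut_s,
                "tfbut_is_lower_bound": result.is_lower_bound,
                "osdi_score": osdi,
                "predicted_dx": predicted,
                "reference_dx": reference,
                "reference_tfbut_s": gt.true_tfbut_s,
            }
        )
    return pd.DataFrame(rows)
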