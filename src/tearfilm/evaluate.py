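"""Diagnostic-performance statistics with 95% confidence intervals.

Covers the statistical surface a screening study reports: the frame-level
2x2 table with accuracy, F1 and ROC/AUC, the case-level sensitivity,
specificity, PPV and NPV, and the Spearman correlation between estimated
and reference TFBUT.

CI methods (the underlying study reports intervals without naming methods,
so these are package choices, recorded in every report): Clopper-Pearson
exact binomial for proportions, Fisher z for Spearman, seeded percentile
bootstrap for AUC and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable",
    "MetricCI",
    "EvalReport",
    "confusion",
    "accuracy_f1",
    "roc_auc",
    "diagnostic_metrics",
    "spearman_ci",
    "clopper_pearson",
    "evaluate_frames",
    "evaluate_cases",
]

DEFAULT_BOOTSTRAP = 2000


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricCI:
    """Point estimate with a 95% interval; ``defined`` is False when the
    metric's denominator is empty (never silently reported as 0)."""

    value: float
    lo: float
    hi: float
    n: int
    method: str = ""
    defined: bool = True


def confusion(pred_labels, true_labels, positive=None) -> ConfusionTable:
    """Exact 2x2 counts from aligned label sequences.

    ``positive`` defaults to the value that looks like the positive class
    ("positive", "DED", 1, True) among those present.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty label lists")
    if positive is None:
        candidates = ("positive", "DED", 1, True)
        present = set(pred.tolist()) | set(true.tolist())
        positive = next((c for c in candidates if c in present), None)
        if positive is None:
            raise ValueError("cannot infer the positive class; pass `positive=`")
    p = pred == positive
    t = true == positive
    return ConfusionTable(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial 95% interval for a proportion k/n."""
    if n == 0:
        raise ValueError("empty denominator")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _items_from_table(ct: ConfusionTable) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct per-item (truth, prediction) arrays from 2x2 counts."""
    true = np.concatenate(
        [np.ones(ct.tp + ct.fn, dtype=int), np.zeros(ct.fp + ct.tn, dtype=int)]
    )
    pred = np.concatenate(
        [
            np.ones(ct.tp, dtype=int),
            np.zeros(ct.fn, dtype=int),
            np.ones(ct.fp, dtype=int),
            np.zeros(ct.tn, dtype=int),
        ]
    )
    return true, pred


def accuracy_f1(
    ct: ConfusionTable,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> tuple[MetricCI, MetricCI]:
    """Accuracy (exact binomial CI) and F1 (seeded bootstrap CI) from a 2x2 table."""
    if ct.total == 0:
        raise ValueError("empty confusion table")
    correct = ct.tp + ct.tn
    acc_lo, acc_hi = clopper_pearson(correct, ct.total)
    acc = MetricCI(
        value=correct / ct.total,
        lo=acc_lo,
        hi=acc_hi,
        n=ct.total,
        method="clopper_pearson",
    )
    if ct.tp + ct.fp == 0 or ct.tp + ct.fn == 0:
        f1 = MetricCI(
            value=float("nan"), lo=float("nan"), hi=float("nan"),
            n=ct.total, method="bootstrap", defined=False,
        )
        return acc, f1
    precision = ct.tp / (ct.tp + ct.fp)
    recall = ct.tp / (ct.tp + ct.fn)
    f1_val = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    true, pred = _items_from_table(ct)
    rng = np.random.default_rng(seed)
    reps = []
    n = ct.total
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t, p = true[idx], pred[idx]
        tp = int(np.sum(p & t))
        denom = 2 * tp + int(np.sum(p & ~t)) + int(np.sum(~p & t))
        if denom > 0:
            reps.append(2 * tp / denom)
    lo, hi = np.percentile(reps, [2.5, 97.5]) if reps else (float("nan"), float("nan"))
    f1 = MetricCI(value=float(f1_val), lo=float(lo), hi=float(hi), n=n, method="bootstrap")
    return acc, f1


def _auc_rank(conf: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), midrank ties."""
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    ranks = stats.rankdata(conf)  # midranks
    rank_sum = ranks[truth.astype(bool)].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(
    confidences,
    true_labels,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    positive=None,
) -> tuple[MetricCI, pd.DataFrame]:
    """AUC (rank statistic, stratified-bootstrap CI) and the full ROC sweep."""
    from sklearn.metrics import roc_curve

    conf = np.asarray(confidences, dtype=float)
    labels = np.asarray(true_labels)
    if positive is None:
        truth = labels.astype(bool) if labels.dtype != object else (labels == "positive")
    else:
        truth = labels == positive
    truth = truth.astype(int)
    if truth.sum() == 0 or truth.sum() == len(truth):
        raise ValueError("ROC requires both classes to be present")
    auc_val = _auc_rank(conf, truth)
    fpr, tpr, thr = roc_curve(truth, conf)
    curve = pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(truth == 1)
    neg_idx = np.flatnonzero(truth == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        reps[b] = _auc_rank(conf[idx], truth[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return (
        MetricCI(
            value=auc_val, lo=float(lo), hi=float(hi), n=len(truth),
            method="stratified_bootstrap",
        ),
        curve,
    )


def diagnostic_metrics(ct: ConfusionTable) -> dict[str, MetricCI]:
    """Sensitivity, specificity, PPV and NPV with Clopper-Pearson intervals."""
    out: dict[str, MetricCI] = {}
    for name, k, n in [
        ("sensitivity", ct.tp, ct.tp + ct.fn),
        ("specificity", ct.tn, ct.tn + ct.fp),
        ("ppv", ct.tp, ct.tp + ct.fp),
        ("npv", ct.tn, ct.tn + ct.fn),
    ]:
        if n == 0:
            out[name] = MetricCI(
                value=float("nan"), lo=float("nan"), hi=float("nan"),
                n=0, method="clopper_pearson", defined=False,
            )
            continue
        lo, hi = clopper_pearson(k, n)
        out[name] = MetricCI(value=k / n, lo=lo, hi=hi, n=n, method="clopper_pearson")
    return out


def spearman_ci(x, y) -> MetricCI:
    """Spearman rank correlation with a Fisher-z 95% interval.

    The Fisher transform with SE 1/sqrt(n-3) is an approximation for rank
    correlations; it is the documented convention here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("Spearman CI requires at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MetricCI(
            value=float("nan"), lo=float("nan"), hi=float("nan"),
            n=n, method="fisher_z", defined=False,
        )
    r = float(stats.spearmanr(x, y).statistic)
    if abs(r) >= 1.0:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(0.975)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return MetricCI(value=r, lo=float(lo), hi=float(hi), n=n, method="fisher_z")


@dataclass
class EvalReport:
    """All metrics of one evaluation run, JSON-serializable."""

    accuracy: MetricCI | None = None
    f1: MetricCI | None = None
    auc: MetricCI | None = None
    sensitivity: MetricCI | None = None
    specificity: MetricCI | None = None
    ppv: MetricCI | None = None
    npv: MetricCI | None = None
    spearman_r: MetricCI | None = None
    confusion: ConfusionTable | None = None
    threshold_sweep: pd.DataFrame | None = None
    seed: int = 0
    n_bootstrap: int = DEFAULT_BOOTSTRAP

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "n_bootstrap": self.n_bootstrap}
        for name in (
            "accuracy", "f1", "auc", "sensitivity", "specificity", "ppv", "npv", "spearman_r",
        ):
            m = getattr(self, name)
            if m is not None:
                out[name] = asdict(m)
        if self.confusion is not None:
            out["confusion"] = asdict(self.confusion)
        if self.threshold_sweep is not None:
            out["threshold_sweep"] = self.threshold_sweep.to_dict(orient="list")
        return out


def plot_roc(curve: pd.DataFrame, path, title: str = "ROC"):  # pragma: no cover
    """Save an ROC curve plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def evaluate_frames(
    table: pd.DataFrame,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> EvalReport:
    """Frame-level report: 2x2 table, accuracy, F1 and ROC/AUC.

    Expects ``label`` (predicted), ``true_label`` and ``confidence`` columns;
    only quality-passing frames with a known truth are scored.
    """
    mask = (table["quality"] == "pass") & table["true_label"].isin(["positive", "negative"])
    sub = table.loc[mask]
    ct = confusion(sub["label"], sub["true_label"], positive="positive")
    acc, f1 = accuracy_f1(ct, n_boot=n_boot, seed=seed)
    auc, curve = roc_auc(
        sub["confidence"], sub["true_label"], n_boot=n_boot, seed=seed, positive="positive"
    )
    return EvalReport(
        accuracy=acc, f1=f1, auc=auc, confusion=ct, threshold_sweep=curve,
        seed=seed, n_bootstrap=n_boot,
    )


def evaluate_cases(
    cases: pd.DataFrame,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> EvalReport:
    """Case-level report: sensitivity/specificity/PPV/NPV, AUC, Spearman.

    Expects ``predicted_dx`` and ``reference_dx``; the case-level ROC sweeps
    the estimated TFBUT as the continuous score (shorter TFBUT = more
    disease-like, so the score is ``-tfbut_s``) with OSDI held at its
    criterion. Spearman is computed when ``reference_tfbut_s`` is present.
    """
    known = cases.loc[cases["reference_dx"].isin(["DED", "non-DED"])]
    ct = confusion(known["predicted_dx"], known["reference_dx"], positive="DED")
    metrics = diagnostic_metrics(ct)
    report = EvalReport(
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        ppv=metrics["ppv"],
        npv=metrics["npv"],
        confusion=ct,
        seed=seed,
        n_bootstrap=n_boot,
    )
    if "tfbut_s" in known.columns and known["reference_dx"].nunique() == 2:
        try:
            report.auc, report.threshold_sweep = roc_auc(
                -known["tfbut_s"].to_numpy(dtype=float),
                known["reference_dx"],
                n_boot=n_boot,
                seed=seed,
                positive="DED",
            )
        except ValueError:
            pass
    if "reference_tfbut_s" in cases.columns:
        paired = cases.dropna(subset=["tfbut_s", "reference_tfbut_s"])
        if len(paired) >= 4:
            report.spearman_r = spearman_ci(paired["tfbut_s"], paired["reference_tfbut_s"])
    return report
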