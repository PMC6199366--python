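"""Group-comparison statistics and ROC analysis for feature distributions.

Feature distributions (VCI, VAI) are compared between the LVO and control
groups with the Mann-Whitney U test; the U statistic divided by the
product of group sizes is the common-language effect size, identical to
the area under the ROC curve.  Both the U-based and the trapezoidal ROC
AUC are exposed (they agree exactly when ties are half-counted).
Confidence intervals on group means are percentile bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from . import classify
from .errors import ValidationError
from .exams import IHC, LVO

#: features for which the positive (LVO) group takes *lower* values
LOWER_IN_POSITIVE = ("vci", "vai")


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    auc: float


def mann_whitney(pos: Sequence[float], neg: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test plus the equivalent ROC AUC.

    The AUC is oriented so that values above 0.5 mean the feature runs
    higher in the negative (control) group, the direction both VCI and
    VAI take under occlusion.  Exact enumeration is used for small
    problems without ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both groups must be non-empty")
    n_pairs = len(pos) * len(neg)
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < len(pos) + len(neg)
    method = "exact" if (n_pairs <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(neg, pos, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        auc=float(res.statistic) / n_pairs,
    )


def roc_points(
    values: Sequence[float],
    labels: Sequence,
    direction: str = classify.BELOW,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC staircase (FPR, TPR, thresholds) and its trapezoidal AUC."""
    values = np.asarray(values, dtype=float)
    pos = classify._positive_mask(labels)
    if pos.all() or not pos.any():
        raise ValidationError("ROC requires both classes")
    if direction == classify.BELOW:
        scores = -values
    elif direction == classify.ABOVE:
        scores = values
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    fpr, tpr, thr = skmetrics.roc_curve(pos, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    if direction == classify.BELOW:
        thr = -thr
    return fpr, tpr, thr, auc


def bootstrap_ci_mean(
    values: Sequence[float],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap 95% CI for the mean (resample with replacement)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("bootstrap CI requires at least 2 values")
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap CI will be unstable", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def performance_at_youden(
    values: Sequence[float],
    labels: Sequence,
    direction: str = classify.BELOW,
) -> Tuple[float, float, float, float]:
    """(threshold, SEN, SPE, ACC) at the cut maximizing ordinary Youden J."""
    model = classify.fit_threshold(values, labels, direction, alpha=0.5)
    pred = model.predict(values)
    counts = classify.confusion(labels, pred)
    return model.threshold, counts.sen, counts.spe, counts.acc


def _format_p(p: float) -> str:
    if p < 0.001:
        return "p < 0.001"
    return f"p = {p:.3g}"


def evaluation_report(
    rows: Sequence,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.6,
) -> dict:
    """Per-feature group comparison plus cross-validated classifier table.

    Returns a JSON-serializable dict with, per feature: group means,
    bootstrap CIs, U statistic, p value, AUC, and Youden-point SEN/SPE/
    ACC; plus LOOCV SEN/SPE/ACC for the VAI, VCI, and tree classifiers at
    the given alpha.  Deterministic for a fixed seed.
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("no feature rows to evaluate")
    labels = np.asarray([r.label for r in rows])
    pos = labels == LVO
    neg = labels == IHC
    if not pos.any() or not neg.any():
        raise ValidationError("evaluation requires both classes")

    rng = np.random.default_rng(seed)
    report: dict = {
        "n_lvo": int(pos.sum()),
        "n_ihc": int(neg.sum()),
        "n_boot": int(n_boot),
        "seed": int(seed),
        "alpha": float(alpha),
        "features": {},
        "crossval": {},
    }

    for name in LOWER_IN_POSITIVE:
        values = np.asarray([getattr(r, name) for r in rows], dtype=float)
        mw = mann_whitney(values[pos], values[neg])
        _, _, _, auc_trap = roc_points(values, labels, classify.BELOW)
        ci_pos = bootstrap_ci_mean(values[pos], n_boot, rng=rng)
        ci_neg = bootstrap_ci_mean(values[neg], n_boot, rng=rng)
        thr, sen, spe, acc = performance_at_youden(values, labels, classify.BELOW)
        report["features"][name] = {
            "orientation": "lower in LVO",
            "mean_lvo": float(values[pos].mean()),
            "mean_ihc": float(values[neg].mean()),
            "ci_lvo": [round(ci_pos[0], 12), round(ci_pos[1], 12)],
            "ci_ihc": [round(ci_neg[0], 12), round(ci_neg[1], 12)],
            "auc": mw.auc,
            "auc_trapezoid": auc_trap,
            "u_statistic": mw.u_statistic,
            "p_value": float(f"{mw.p_value:.3g}"),
            "p_text": _format_p(mw.p_value),
            "youden_threshold": thr,
            "sen": sen,
            "spe": spe,
            "acc": acc,
        }

    for spec_name in classify.CLASSIFIERS:
        cv = classify.loocv(rows, spec_name, alpha)
        report["crossval"][spec_name] = {
            "sen": cv.sen,
            "spe": cv.spe,
            "acc": cv.acc,
            "tp": cv.counts.tp,
            "fn": cv.counts.fn,
            "fp": cv.counts.fp,
            "tn": cv.counts.tn,
        }
    return report


def render_report_text(report: dict) -> str:
    """Render the evaluation report as aligned plain text."""
    lines = [
        f"Cohort: {report['n_lvo']} LVO vs {report['n_ihc']} controls "
        f"(bootstrap n={report['n_boot']}, seed={report['seed']})",
        "",
        f"{'metric':<6} {'mean LVO':>9} {'mean IHC':>9} {'AUC':>6} "
        f"{'SEN':>6} {'SPE':>6} {'ACC':>6}  p",
    ]
    for name, f in report["features"].items():
        lines.append(
            f"{name.upper():<6} {f['mean_lvo']:>9.3f} {f['mean_ihc']:>9.3f} "
            f"{f['auc']:>6.3f} {f['sen']:>6.2f} {f['spe']:>6.2f} "
            f"{f['acc']:>6.2f}  {f['p_text']}"
        )
    lines += [
        "",
        f"Leave-one-out cross-validation at alpha = {report['alpha']:.2f}:",
        f"{'classifier':<12} {'SEN':>6} {'SPE':>6} {'ACC':>6}",
    ]
    for name, c in report["crossval"].items():
        lines.append(
            f"{name:<12} {c['sen']:>6.2f} {c['spe']:>6.2f} {c['acc']:>6.2f}"
        )
    return "\n".join(lines) + "\n"
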