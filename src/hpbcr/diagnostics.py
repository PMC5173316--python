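"""Diagnostic-test validation metrics for binary prognosis classifiers.

Implements the standard battery used to validate clinical diagnosis
systems against a gold standard: sensitivity/specificity and their
complements (type I/II error rates), precision, F-score, balanced
accuracy (the two-point AUC), likelihood ratios, the diagnostic odds
ratio (DOR), Matthews correlation, discriminant power
(DP = sqrt(3)/pi * log10 DOR), Cohen's kappa, qualitative bands for
DP/AUC/kappa, a composite clinical-reliability verdict, and McNemar's
paired test for comparing two classifiers on the same cases.

Positive class throughout is "recurrence within 5 years".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ComparisonResult",
    "confusion",
    "metrics",
    "metrics_from_rates",
    "cohen_kappa",
    "mcnemar",
    "grade",
    "f_score",
]

#: sqrt(3)/pi, the logistic-to-probit scaling constant in discriminant power.
_DP_SCALE = math.sqrt(3.0) / math.pi

#: |z| threshold for a two-sided 5% McNemar test.
MCNEMAR_Z_CRIT = 1.96

# Column order used for the plain-text report table.
REPORT_COLUMNS = [
    "se", "sp", "acc", "pr", "f_score", "alpha", "beta",
    "auc", "mcc", "dor", "dp", "kappa",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix; positives are recurrent cases."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """All derived performance measures plus qualitative bands.

    ``flags`` records degeneracies (zero denominators, infinite DOR)
    instead of silently coercing them.
    """

    se: float = math.nan
    sp: float = math.nan
    acc: float = math.nan
    pr: float = math.nan
    f_score: float = math.nan
    alpha: float = math.nan
    beta: float = math.nan
    auc: float = math.nan
    lr_pos: float = math.nan
    lr_neg: float = math.nan
    dor: float = math.nan
    mcc: float = math.nan
    dp: float = math.nan
    kappa: float = math.nan
    dp_band: str = ""
    auc_band: str = ""
    kappa_band: str = ""
    reliable: bool = False
    reliability: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(self.to_dict(), sort_keys=True, default=_default, **kwargs)

    def to_text(self) -> str:
        """Render the Se..Kappa columns as a fixed-order text table."""
        header = []
        values = []
        for col in REPORT_COLUMNS:
            v = getattr(self, col)
            header.append(col.upper() if col != "f_score" else "F-score")
            if col == "dor":
                values.append(f"{v:.1f}" if math.isfinite(v) else str(v))
            else:
                values.append(f"{v:.2f}" if isinstance(v, float) and math.isfinite(v) else str(v))
        w = [max(len(h), len(s)) for h, s in zip(header, values)]
        line1 = "  ".join(h.rjust(k) for h, k in zip(header, w))
        line2 = "  ".join(s.rjust(k) for s, k in zip(values, w))
        return line1 + "\n" + line2


@dataclass
class ComparisonResult:
    """McNemar comparison of classifiers A and B on shared cases."""

    a: str
    b: str
    x: int  #: misclassified by A only
    y: int  #: misclassified by B only
    z: float
    significant: bool
    winner: str  #: 'A'/'B' label of the higher-DP classifier, or 'none'

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tabulate a 2x2 confusion matrix from 0/1 vectors."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size < 1:
        raise ValueError("need at least one case")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def f_score(pr: float, se: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both vanish."""
    if pr + se <= 0 or math.isnan(pr) or math.isnan(se):
        return 0.0
    return 2.0 * pr * se / (pr + se)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between prediction and gold standard."""
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.tn + cm.fn) * (cm.tn + cm.fp)) / (n * n)
    if abs(1.0 - pe) < 1e-12:
        # degenerate marginals: agreement is entirely forced by the margins
        return 0.0
    return (po - pe) / (1.0 - pe)


def _ratio(num: float, den: float, flags: list, label: str) -> float:
    if den == 0:
        if num == 0:
            flags.append(f"{label}: 0/0 undefined")
            return math.nan
        flags.append(f"{label}: division by zero, reported as inf")
        return math.inf
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Compute the full metric battery from a confusion matrix.

    Zero denominators are propagated as inf/NaN with an entry in
    ``flags`` rather than corrected; DP uses log base 10.
    """
    flags: list = []
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.total
    se = _ratio(tp, tp + fn, flags, "se")
    sp = _ratio(tn, tn + fp, flags, "sp")
    pr = _ratio(tp, tp + fp, flags, "pr")
    acc = (tp + tn) / n

    rep = _from_rates(se, sp, pr, flags)
    rep.acc = acc
    # MCC directly from counts (the rate form loses the cell sizes)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        flags.append("mcc: degenerate margin, reported as 0")
        rep.mcc = 0.0
    else:
        rep.mcc = (tp * tn - fp * fn) / denom
    rep.kappa = cohen_kappa(cm)
    grade(rep)
    return rep


def metrics_from_rates(se: float, sp: float, pr: float = math.nan) -> MetricReport:
    """Partial report from printed rates (no counts: Acc/MCC/kappa omitted)."""
    flags: list = []
    rep = _from_rates(se, sp, pr, flags)
    grade(rep)
    return rep


def _from_rates(se: float, sp: float, pr: float, flags: list) -> MetricReport:
    rep = MetricReport(se=se, sp=sp, pr=pr, flags=flags)
    rep.alpha = 1.0 - sp
    rep.beta = 1.0 - se
    rep.auc = 0.5 * (se + sp)
    rep.f_score = f_score(pr, se)
    rep.lr_pos = _ratio(se, 1.0 - sp, flags, "lr_pos")
    rep.lr_neg = _ratio(1.0 - se, sp, flags, "lr_neg")
    if rep.lr_neg == 0 or math.isinf(rep.lr_pos):
        flags.append("dor: infinite")
        rep.dor = math.inf
    elif math.isnan(rep.lr_pos) or math.isnan(rep.lr_neg):
        rep.dor = math.nan
    else:
        rep.dor = rep.lr_pos / rep.lr_neg
    if math.isfinite(rep.dor) and rep.dor > 0:
        rep.dp = _DP_SCALE * math.log10(rep.dor)
    else:
        flags.append("dp: undefined for non-finite or non-positive DOR")
        rep.dp = math.nan
    return rep


def grade(report: MetricReport) -> MetricReport:
    """Assign qualitative bands and the clinical reliability verdict.

    Bands operate on the unrounded values. Reliability requires
    sensitivity >= 80% (statistical power), specificity >= 95%
    (type I error <= 5%) and false discovery rate (1 - precision)
    <= 5%; the conservative likelihood-ratio rule is DOR > 100.
    """
    dp, auc, kappa = report.dp, report.auc, report.kappa
    if math.isnan(dp):
        report.dp_band = "undefined"
    elif dp < 1:
        report.dp_band = "poor"
    elif dp < 2:
        report.dp_band = "limited"
    elif dp < 3:
        report.dp_band = "fair"
    else:
        report.dp_band = "good"

    if math.isnan(auc):
        report.auc_band = "undefined"
    elif auc >= 0.9:
        report.auc_band = "excellent"
    elif auc >= 0.8:
        report.auc_band = "very good"
    elif auc >= 0.7:
        report.auc_band = "good"
    else:
        report.auc_band = "below"

    if math.isnan(kappa):
        report.kappa_band = "undefined"
    elif kappa > 0.75:
        report.kappa_band = "excellent"
    elif kappa >= 0.40:
        report.kappa_band = "fair-to-good"
    else:
        report.kappa_band = "poor"

    crit = {
        "power_ge_80": bool(report.se >= 0.80),
        "type1_le_05": bool(report.sp >= 0.95),
        "fdr_le_05": bool(math.isfinite(report.pr) and (1.0 - report.pr) <= 0.05),
        "lr_pos_gt_10": bool(report.lr_pos > 10),
        "lr_neg_lt_0_1": bool(report.lr_neg < 0.1),
        "conservative_dor_gt_100": bool(report.dor > 100),
    }
    report.reliability = crit
    report.reliable = crit["power_ge_80"] and crit["type1_le_05"] and crit["fdr_le_05"]
    return report


def mcnemar(preds_a, preds_b, y_true, label_a: str = "A", label_b: str = "B",
            dp_a: float = math.nan, dp_b: float = math.nan) -> ComparisonResult:
    """Continuity-corrected McNemar test on the discordant misclassifications.

    z = (|x - y| - 1)/sqrt(x + y), signed by which classifier errs more;
    significant at the 5% level when |z| > 1.96. When significant, the
    classifier with the higher discriminant power is reported superior.
    """
    pa = np.asarray(preds_a).astype(int)
    pb = np.asarray(preds_b).astype(int)
    yt = np.asarray(y_true).astype(int)
    if not (pa.shape == pb.shape == yt.shape):
        raise ValueError("prediction vectors and truth must share length")
    wrong_a = pa != yt
    wrong_b = pb != yt
    x = int(np.sum(wrong_a & ~wrong_b))
    y = int(np.sum(wrong_b & ~wrong_a))
    if x + y == 0:
        raise ValueError("no discordant pairs: classifiers err on identical cases")
    z = (abs(x - y) - 1.0) / math.sqrt(x + y)
    if x < y:
        z = -z
    significant = abs(z) > MCNEMAR_Z_CRIT
    winner = "none"
    if significant and not (math.isnan(dp_a) or math.isnan(dp_b)):
        winner = label_a if dp_a > dp_b else label_b
    return ComparisonResult(a=label_a, b=label_b, x=x, y=y, z=z,
                            significant=significant, winner=winner)
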