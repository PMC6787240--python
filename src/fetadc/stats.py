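"""Cohort statistics and the step-wise biparametric classifier.

Implements the diagnostic-accuracy toolkit used to compare recurrent
glioma (REC, the positive class) against post-treatment related
effects (PTRE): pooled-variance two-sample t-tests, empirical ROC
curves with the AUC as the normalised Mann-Whitney statistic (ties
counted 1/2), AUC standard errors and covariances from DeLong's
structural components, Youden-optimal cutoffs, the two-marker OR rule
("one parameter above threshold is classified as recurrence") at a
fixed operating point, and the two-threshold ROC envelope that the
same OR rule traces when both cutoffs sweep.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ROCResult",
    "ClassifierRule",
    "DiagnosticMeasures",
    "independent_t_test",
    "empirical_roc",
    "compare_roc",
    "youden_cutoff",
    "classify_biparametric",
    "bivariate_roc",
    "diagnostic_measures",
    "DEFAULT_RULE",
]

REC, PTRE = "REC", "PTRE"


# ---------------------------------------------------------------------------
# group comparison


@dataclasses.dataclass
class GroupComparison:
    metric: str
    mean_rec: float
    mean_ptre: float
    md: float  # mean difference, REC - PTRE
    se: float  # SE of the difference (pooled)
    t: float
    df: int
    p_value: float


def independent_t_test(
    values_rec: np.ndarray, values_ptre: np.ndarray, metric: str = "", welch: bool = False
) -> GroupComparison:
    """Two-sample t-test on a metric, REC minus PTRE.

    Pooled-variance Student's test by default (matching the reported
    mean +/- SE convention); Welch's unequal-variance form behind the
    ``welch`` flag.
    """
    x = np.asarray(values_rec, dtype=float)
    y = np.asarray(values_ptre, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    md = float(x.mean() - y.mean())
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se = float(np.sqrt(v1 / n1 + v2 / n2))
        df_f = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        ) if se > 0 else n1 + n2 - 2
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
        df_f = n1 + n2 - 2
    if se == 0:
        t = 0.0 if md == 0 else float(np.sign(md)) * np.inf
        p = 1.0 if md == 0 else 0.0
    else:
        t = md / se
        p = float(2.0 * sps.t.sf(abs(t), df_f))
    return GroupComparison(
        metric=metric,
        mean_rec=float(x.mean()),
        mean_ptre=float(y.mean()),
        md=md,
        se=se,
        t=float(t),
        df=int(round(df_f)),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# ROC machinery


@dataclasses.dataclass
class ROCResult:
    metric: str
    direction: str  # "larger" -> larger scores indicate recurrence
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    p_value: float  # AUC vs 0.5, normal approximation on the DeLong SE
    scores_pos: np.ndarray = dataclasses.field(repr=False, default=None)
    scores_neg: np.ndarray = dataclasses.field(repr=False, default=None)


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction not in ("larger", "smaller"):
        raise ValueError("direction must be 'larger' or 'smaller'")
    scores = np.asarray(scores, dtype=float)
    return scores if direction == "larger" else -scores


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = np.asarray(scores, dtype=float)[labels == 1]
    neg = np.asarray(scores, dtype=float)[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def as_binary_labels(labels) -> np.ndarray:
    """Map REC/PTRE (or 0/1) labels to 1/0 integers."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        out = arr.astype(int)
        if not set(np.unique(out)) <= {0, 1}:
            raise ValueError("integer labels must be 0/1")
        return out
    return np.asarray([1 if str(v) == REC else 0 for v in arr], dtype=int)


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong V10 (per positive), V01 (per negative) and the AUC."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    v10, v01, auc = _structural_components(pos, neg)
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(np.sqrt(s10 / m + s01 / n))


def _logit_ci(auc: float, se: float, level: float = 0.95) -> tuple[float, float]:
    if se == 0 or auc in (0.0, 1.0):
        return (auc, auc)
    z = sps.norm.ppf(0.5 + level / 2.0)
    logit = np.log(auc / (1.0 - auc))
    se_logit = se / (auc * (1.0 - auc))
    lo, hi = logit - z * se_logit, logit + z * se_logit
    expit = lambda t: 1.0 / (1.0 + np.exp(-t))
    return (float(expit(lo)), float(expit(hi)))


def empirical_roc(scores, labels, direction: str = "larger", metric: str = "") -> ROCResult:
    """Empirical ROC of one marker.

    AUC is the normalised Mann-Whitney statistic with ties counted
    1/2; its SE comes from DeLong's structural components; the 95% CI
    is computed on the logit scale (boundary-safe) and the p-value
    tests AUC = 0.5 by normal approximation.
    """
    oriented = _oriented(scores, direction)
    pos, neg = _split(oriented, as_binary_labels(labels))
    auc, se = _delong_se(pos, neg)

    # operating points: classify positive when score > cutoff
    cuts = np.unique(np.concatenate([oriented, [-np.inf, np.inf]]))
    sens = np.array([(pos > c).mean() for c in cuts])
    spec = np.array([(neg <= c).mean() for c in cuts])

    if se == 0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return ROCResult(
        metric=metric,
        direction=direction,
        thresholds=cuts,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_se=se,
        ci95=_logit_ci(auc, se),
        p_value=p,
        scores_pos=pos,
        scores_neg=neg,
    )


def compare_roc(roc_a: ROCResult, roc_b: ROCResult, paired: bool = True):
    """DeLong comparison of two AUCs.

    Paired mode requires both ROCs to come from the same subjects (in
    the same order) and uses the covariance of the structural
    components; unpaired mode adds the independent variances.
    Returns ``(difference, se, p_value)`` for AUC_a - AUC_b.
    """
    a_pos, a_neg = roc_a.scores_pos, roc_a.scores_neg
    b_pos, b_neg = roc_b.scores_pos, roc_b.scores_neg
    if paired:
        if len(a_pos) != len(b_pos) or len(a_neg) != len(b_neg):
            raise ValueError("paired comparison requires identical subject sets")
        m, n = len(a_pos), len(a_neg)
        v10a, v01a, auc_a = _structural_components(a_pos, a_neg)
        v10b, v01b, auc_b = _structural_components(b_pos, b_neg)
        s10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
        var = (
            s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]
        ) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        diff = auc_a - auc_b
        se = float(np.sqrt(max(var, 0.0)))
    else:
        diff = roc_a.auc - roc_b.auc
        se = float(np.sqrt(roc_a.auc_se**2 + roc_b.auc_se**2))
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(diff) / se))
    return float(diff), se, p


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float, float]:
    """Maximise J = sensitivity + specificity - 1 over candidate cutoffs.

    Candidates are the midpoints of consecutive sorted unique scores
    plus one cutoff below and above the score range; classification is
    "score strictly above cutoff -> recurrence".  Ties in J break
    toward higher specificity.  Returns
    ``(cutoff, sensitivity, specificity, J)`` on the oriented scale.
    """
    pos, neg = roc.scores_pos, roc.scores_neg
    s = np.unique(np.concatenate([pos, neg]))
    candidates = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    best = None
    for c in candidates:
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec, j))
    return best[1]


# ---------------------------------------------------------------------------
# biparametric rule


@dataclasses.dataclass(frozen=True)
class ClassifierRule:
    """Fixed operating point of the step-wise two-marker rule."""

    theta_tbr: float = 2.0
    theta_adc: float = 1254.0
    combination: str = "or_rule"  # {"tbr_only", "adc_only", "or_rule"}

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta_tbr) and np.isfinite(self.theta_adc)):
            raise ValueError("rule thresholds must be finite")
        if self.combination not in ("tbr_only", "adc_only", "or_rule"):
            raise ValueError("unknown combination")


DEFAULT_RULE = ClassifierRule()


def classify_biparametric(tbr_max: float, adc_mean: float, rule: ClassifierRule = DEFAULT_RULE) -> str:
    """Step-wise classification: each marker checked separately, one
    marker strictly above its threshold classifies as recurrence."""
    tbr_hit = tbr_max > rule.theta_tbr
    adc_hit = adc_mean > rule.theta_adc
    hit = {
        "tbr_only": tbr_hit,
        "adc_only": adc_hit,
        "or_rule": tbr_hit or adc_hit,
    }[rule.combination]
    return REC if hit else PTRE


@dataclasses.dataclass
class DiagnosticMeasures:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def diagnostic_measures(predictions, labels) -> DiagnosticMeasures:
    """Confusion-matrix summaries; undefined ratios reported as NaN."""
    pred = as_binary_labels(predictions)
    true = as_binary_labels(labels)
    if len(pred) != len(true):
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return DiagnosticMeasures(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


# ---------------------------------------------------------------------------
# bivariate OR-rule envelope


def _or_rule_points(tbr: np.ndarray, adc: np.ndarray, labels: np.ndarray):
    """All (fpr, tpr) operating points of the OR rule over threshold pairs."""
    y = as_binary_labels(labels)
    tbr = np.asarray(tbr, dtype=float)
    adc = np.asarray(adc, dtype=float)

    def candidates(s: np.ndarray) -> np.ndarray:
        u = np.unique(s)
        mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
        return np.concatenate([[-np.inf], mids, [np.inf]])

    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    tbr_hit = tbr[None, :] > candidates(tbr)[:, None]  # (ct, n)
    adc_hit = adc[None, :] > candidates(adc)[:, None]  # (ca, n)
    pred = tbr_hit[:, None, :] | adc_hit[None, :, :]  # (ct, ca, n)
    tpr = pred[:, :, y == 1].sum(axis=2) / n_pos
    fpr = pred[:, :, y == 0].sum(axis=2) / n_neg
    return np.column_stack([fpr.ravel(), tpr.ravel()])


def _envelope_auc(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Upper-left staircase envelope of achievable ROC points.

    Between consecutive envelope points the rule offers no operating
    point, so the envelope is the left-continuous step function through
    them; its area is the sum of ``tpr_k * (fpr_{k+1} - fpr_k)``.  For
    a tie-free single marker this reproduces the rank (Mann-Whitney)
    AUC exactly.
    """
    pts = np.vstack([points, [[0.0, 0.0], [1.0, 1.0]]])
    fpr_u = np.unique(pts[:, 0])
    tpr_u = np.array([pts[pts[:, 0] == f, 1].max() for f in fpr_u])
    tpr_u = np.maximum.accumulate(tpr_u)
    auc = float(np.sum(tpr_u[:-1] * np.diff(fpr_u)))
    return np.column_stack([fpr_u, tpr_u]), auc


def bivariate_roc(
    scores_tbr,
    scores_adc,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    metric: str = "TBRmax+ADCmean",
) -> ROCResult:
    """ROC envelope of the step-wise OR rule over both thresholds.

    Sweeps every pair of candidate cutoffs, keeps the attainable
    (1-specificity, sensitivity) points, takes their upper-left
    staircase envelope and integrates by trapezoid.  The SE is a
    stratified subject bootstrap (groups resampled separately) of the
    envelope AUC.
    """
    y = as_binary_labels(labels)
    tbr = np.asarray(scores_tbr, dtype=float)
    adc = np.asarray(scores_adc, dtype=float)
    env, auc = _envelope_auc(_or_rule_points(tbr, adc, y))

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        _, boot[b] = _envelope_auc(_or_rule_points(tbr[take], adc[take], y[take]))
    se = float(boot.std(ddof=1)) if n_boot > 1 else 0.0

    if se == 0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return ROCResult(
        metric=metric,
        direction="larger",
        thresholds=env[:, 0],  # envelope is parameterised by FPR, not a scalar cutoff
        sensitivities=env[:, 1],
        specificities=1.0 - env[:, 0],
        auc=auc,
        auc_se=se,
        ci95=_logit_ci(auc, se),
        p_value=p,
        scores_pos=None,
        scores_neg=None,
    )
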