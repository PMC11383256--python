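"""Two-group comparison and ROC diagnostic-performance analysis.

The workflow mirrors how diagnostic-imaging studies summarise a candidate
biomarker: for each parameter at each b-value, a nonparametric
Mann-Whitney U comparison of the two groups, then an ROC analysis
reporting AUC, its Hanley-McNeil standard error, a normal-theory p-value
against AUC = 0.5, and the cutoff that balances sensitivity and
specificity.

All rank-based quantities use the midrank convention for ties, which
makes the identity AUC = U / (n_pos * n_neg) exact on every input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RocResult",
    "mann_whitney",
    "roc_auc",
    "auc_se_hanley_mcneil",
    "auc_p_value",
    "select_cutoff",
    "roc_curve_points",
    "analyze_cohort",
    "validate_cohort",
]

#: pooled sample size at or below which the Mann-Whitney p-value is
#: computed by exact enumeration of all group labelings
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of two groups."""

    u_statistic: float  # U for the first group
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class RocResult:
    """One ROC row: a parameter's diagnostic performance at one b-value.

    ``direction`` is "greater" if larger scores indicate the positive
    class, "less" otherwise; it is chosen so the reported AUC is >= 0.5.
    """

    auc: float
    se: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str
    positive_label: str = ""


def _midrank_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a against group b, midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney(values_a, values_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midranks and tie correction.

    For pooled sample sizes up to 12 the p-value is exact, obtained by
    enumerating every way of assigning the pooled observations to the two
    groups and counting labelings at least as extreme (in |U - n1*n2/2|)
    as the observed one.  Larger samples use the normal approximation
    with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    u_obs = _midrank_u(a, b)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        idx = range(pooled.size)
        extreme = 0
        total = 0
        dev_obs = abs(u_obs - mu)
        for comb in combinations(idx, n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            u = _midrank_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        pooled = np.concatenate([a, b])
        n = pooled.size
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:  # all observations identical
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
            z = max(z, 0.0)
            p = min(2.0 * sps.norm.sf(z), 1.0)
        method = "normal"
    return GroupComparison(
        u_statistic=u_obs,
        p_value=float(p),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(n1),
        n_b=int(n2),
        method=method,
    )


def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels, direction: str = "greater") -> float:
    """Area under the empirical ROC curve, ties handled by midranks.

    Equals the Mann-Whitney U of the positive class divided by
    n_pos * n_neg: the probability that a random positive outranks a
    random negative, counting ties as half.  ``direction="less"`` scores
    the classifier that calls small values positive.
    """
    pos, neg = _split_scores(scores, labels)
    if direction == "less":
        pos, neg = -pos, -neg
    elif direction != "greater":
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    u = _midrank_u(pos, neg)
    return u / (pos.size * neg.size)


def auc_se_hanley_mcneil(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil (1982) standard error of an empirical AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one observation per class")
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return math.sqrt(max(var, 0.0))


def auc_p_value(auc: float, se: float) -> float:
    """Two-sided normal-theory p-value against the null AUC = 0.5."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0.0:
        return 1.0 if auc == 0.5 else float(np.nextafter(0, 1))
    z = (auc - 0.5) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _sens_spec(pos: np.ndarray, neg: np.ndarray, cutoff: float) -> tuple[float, float]:
    """Sensitivity/specificity calling scores above the cutoff positive."""
    sens = float(np.mean(pos > cutoff))
    spec = float(np.mean(neg <= cutoff))
    return sens, spec


def select_cutoff(scores, labels, direction: str = "greater"):
    """Cutoff minimising |sensitivity - specificity|.

    Candidate cutoffs are the midpoints between adjacent distinct sorted
    scores plus -inf/+inf sentinels.  Ties in the objective are broken by
    the larger sensitivity + specificity, then by the smaller cutoff, so
    the result is deterministic.  Returns (cutoff, sensitivity,
    specificity) as attained by applying the cutoff to the scores.
    """
    pos, neg = _split_scores(scores, labels)
    flip = direction == "less"
    if flip:
        pos, neg = -pos, -neg
    elif direction != "greater":
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")

    distinct = np.unique(np.concatenate([pos, neg]))
    candidates = [-math.inf, math.inf]
    candidates.extend(
        0.5 * (distinct[i] + distinct[i + 1]) for i in range(distinct.size - 1)
    )

    best = None
    for c in candidates:
        sens, spec = _sens_spec(pos, neg, c)
        key = (abs(sens - spec), -(sens + spec), c)
        if best is None or key < best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    if flip and math.isfinite(cutoff):
        cutoff = -cutoff
    return float(cutoff), sens, spec


def roc_curve_points(scores, labels, direction: str = "greater"):
    """(FPR, TPR) points of the empirical ROC curve, for plotting."""
    pos, neg = _split_scores(scores, labels)
    if direction == "less":
        pos, neg = -pos, -neg
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    return np.asarray(fpr), np.asarray(tpr)


def validate_cohort(table: pd.DataFrame) -> tuple[str, str]:
    """Check a long-format cohort table and return its two group labels.

    Required columns: subject_id, group, b_value, parameter, value.
    Exactly two groups, each with at least two subjects, and one value
    per (subject, b_value, parameter).
    """
    required = {"subject_id", "group", "b_value", "parameter", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    for g in groups:
        n = table.loc[table["group"] == g, "subject_id"].nunique()
        if n < 2:
            raise ValueError(f"group {g!r} has {n} subject(s); need >= 2")
    dup = table.duplicated(subset=["subject_id", "b_value", "parameter"])
    if dup.any():
        raise ValueError("duplicate (subject, b_value, parameter) entries")
    return groups[0], groups[1]


def analyze_cohort(
    table: pd.DataFrame,
    positive_label: str | None = None,
) -> pd.DataFrame:
    """Full group-comparison + ROC table, one row per (parameter, b-value).

    ``table`` is long format with columns subject_id, group, b_value,
    parameter, value.  The positive class defaults to the first group
    label in sorted order; for each row the score direction is chosen so
    the AUC is >= 0.5 and recorded in the ``direction`` column.  Output
    columns include the Mann-Whitney U and p, AUC with Hanley-McNeil SE
    and normal-theory p, and the balanced-sensitivity/specificity cutoff.
    """
    g0, g1 = validate_cohort(table)
    if positive_label is None:
        positive_label = g0
    if positive_label not in (g0, g1):
        raise ValueError(f"positive_label {positive_label!r} not a group label")
    negative_label = g1 if positive_label == g0 else g0

    rows = []
    for (param, b), sub in table.groupby(["parameter", "b_value"], sort=True):
        pos_vals = sub.loc[sub["group"] == positive_label, "value"].to_numpy(float)
        neg_vals = sub.loc[sub["group"] == negative_label, "value"].to_numpy(float)
        mw = mann_whitney(pos_vals, neg_vals)
        scores = np.concatenate([pos_vals, neg_vals])
        labels = np.concatenate(
            [np.ones(pos_vals.size, bool), np.zeros(neg_vals.size, bool)]
        )
        auc_g = roc_auc(scores, labels, "greater")
        direction = "greater" if auc_g >= 0.5 else "less"
        auc = auc_g if direction == "greater" else 1.0 - auc_g
        se = auc_se_hanley_mcneil(auc, pos_vals.size, neg_vals.size)
        p_auc = auc_p_value(auc, se)
        cutoff, sens, spec = select_cutoff(scores, labels, direction)
        rows.append(
            {
                "parameter": param,
                "b_value": b,
                "positive_group": positive_label,
                "n_positive": pos_vals.size,
                "n_negative": neg_vals.size,
                "direction": direction,
                "u_statistic": mw.u_statistic,
                "mw_p_value": mw.p_value,
                "auc": auc,
                "auc_se": se,
                "auc_p_value": p_auc,
                "cutoff": cutoff,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    return pd.DataFrame(rows)
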