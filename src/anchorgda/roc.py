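"""Two-group marker evaluation: expression difference and nonparametric ROC.

The AUC is the Mann-Whitney U statistic divided by n_neg * n_pos with ties
counted 1/2 (midranks), i.e. the probability that a random positive-group
sample outranks a random negative-group sample on the marker. The 95% CI
uses the Hanley-McNeil standard error; the test against AUC = 0.5 is the
normal approximation to U with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from anchorgda.core_io import ExpressionMatrix, normalize_symbol


@dataclass
class RocResult:
    marker: str
    auc: float
    ci_low: float
    ci_high: float
    p: float
    n_neg: int
    n_pos: int
    threshold_at_best: float | None = None
    accuracy_at_best: float | None = None   # fraction correct at the Youden threshold
    percent_error: float | None = None      # 100 * (1 - accuracy)


def _mann_whitney_auc(neg: np.ndarray, pos: np.ndarray) -> float:
    combined = np.concatenate([neg, pos])
    ranks = stats.rankdata(combined)  # midranks
    u_pos = ranks[len(neg):].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u_pos / (len(neg) * len(pos)))


def hanley_mcneil_se(auc: float, n_neg: int, n_pos: int) -> float:
    """Standard error of the AUC from the exponential-model approximation."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_neg * n_pos)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(values_neg, values_pos) -> pd.DataFrame:
    """ROC coordinates (threshold, fpr, tpr) with a 'predict positive if
    marker >= threshold' rule, one row per distinct observed value plus the
    (1, 1) origin-side endpoint."""
    neg = np.asarray(values_neg, dtype=float)
    pos = np.asarray(values_pos, dtype=float)
    thresholds = np.unique(np.concatenate([neg, pos]))[::-1]
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        rows.append(
            {
                "threshold": float(t),
                "fpr": float((neg >= t).mean()),
                "tpr": float((pos >= t).mean()),
            }
        )
    return pd.DataFrame(rows)


def roc_auc(values_neg, values_pos, marker: str = "marker",
            flip: bool = False) -> RocResult:
    """Nonparametric ROC of a marker separating a negative from a positive group.

    The positive class is the disease group and the orientation is taken as
    given (an up-regulated marker yields AUC > 0.5); set ``flip`` to score
    the marker inverted. Swapping the two groups yields 1 - AUC.
    """
    neg = np.asarray(values_neg, dtype=float)
    pos = np.asarray(values_pos, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("both groups need >=2 observations")
    if flip:
        neg, pos = -neg, -pos

    auc = _mann_whitney_auc(neg, pos)
    se = hanley_mcneil_se(auc, len(neg), len(pos))
    z = stats.norm.ppf(0.975)
    ci_low = max(0.0, min(auc, auc - z * se))
    ci_high = min(1.0, max(auc, auc + z * se))

    try:
        p = float(
            stats.mannwhitneyu(pos, neg, alternative="two-sided",
                               method="asymptotic").pvalue
        )
    except ValueError:  # all values identical -> zero-variance U
        p = 1.0
    if not np.isfinite(p):
        p = 1.0

    curve = roc_curve(neg, pos)
    youden = curve["tpr"] - curve["fpr"]
    best = curve.iloc[int(youden.to_numpy().argmax())]
    thr = float(best["threshold"])
    if np.isfinite(thr):
        correct = int((pos >= thr).sum()) + int((neg < thr).sum())
    else:
        correct = len(neg)  # degenerate: everything called negative
    accuracy = correct / (len(neg) + len(pos))

    return RocResult(
        marker=marker,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        n_neg=len(neg),
        n_pos=len(pos),
        threshold_at_best=thr,
        accuracy_at_best=accuracy,
        percent_error=round(100.0 * (1 - accuracy), 2),
    )


def group_difference(
    matrix: ExpressionMatrix, gene: str, groups: tuple[str, str]
) -> tuple[dict[str, float], dict[str, float], float]:
    """Per-group mean and SD of one gene plus the two-group ANOVA p-value."""
    gene = normalize_symbol(gene)
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    arrays = {}
    for g in groups:
        vals = matrix.values.loc[gene, matrix.samples_in_group(g)].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        arrays[g] = vals
    means = {g: float(v.mean()) for g, v in arrays.items()}
    sds = {g: float(v.std(ddof=1)) for g, v in arrays.items()}
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(p):
        p = 1.0
    return means, sds, float(p)
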