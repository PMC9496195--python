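"""Anchor-gene co-expression screen.

Every gene is Pearson-correlated to a chosen anchor gene across the samples
of one group; genes passing the positive threshold form the GSPC list
(significantly positively correlated, always containing the anchor itself)
and genes passing the negative threshold form the GSNC list.

By default membership requires both |r| >= 0.50 and a two-sided p < 0.05.
At small sample sizes (n = 10) an r of 0.50 alone is not significant at
0.05, so the two criteria genuinely differ; either can be disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from anchorgda.core_io import ExpressionMatrix, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """Membership thresholds for the positively/negatively correlated lists."""

    r_pos: float = 0.50
    r_neg: float = 0.50
    alpha: float = 0.05
    require_significance: bool = True  # additionally require p < alpha
    require_magnitude: bool = True     # additionally require |r| >= threshold

    def __post_init__(self) -> None:
        if not (0 <= self.r_pos <= 1 and 0 <= self.r_neg <= 1):
            raise ValueError("correlation thresholds must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not (self.require_significance or self.require_magnitude):
            raise ValueError("at least one membership criterion must be active")


@dataclass
class CorrelationScreenResult:
    """Per-gene correlation to the anchor plus the derived GSPC/GSNC lists."""

    anchor: str
    group: str
    records: pd.DataFrame  # index gene; columns r, p, n_samples, list
    gspc: list[str]
    gsnc: list[str]
    thresholds: ScreenThresholds
    n_excluded_constant: int = 0

    def r_range(self, which: str) -> tuple[float, float]:
        members = {"gspc": self.gspc, "gsnc": self.gsnc}[which.lower()]
        r = self.records.loc[members, "r"]
        return (float(r.min()), float(r.max()))


def pearson_p_value(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform, df = n - 2."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlate_to_anchor(
    matrix: ExpressionMatrix,
    anchor: str,
    group: str,
    thresholds: ScreenThresholds | None = None,
) -> CorrelationScreenResult:
    """Correlate every gene to the anchor within one sample group.

    Genes with zero variance in the group have undefined r and are excluded
    (counted, logged), never assigned r = 0.
    """
    thresholds = thresholds or ScreenThresholds()
    anchor = normalize_symbol(anchor)
    if anchor not in matrix.values.index:
        raise KeyError(f"anchor gene {anchor!r} not present in the matrix")
    sub = matrix.subset_group(group)  # raises KeyError on unknown group
    n = sub.shape[1]
    if n < 3:
        raise ValueError(f"group {group!r} has {n} samples; need >=3 for the screen")

    x = sub.to_numpy(dtype=float)
    a = sub.loc[anchor].to_numpy(dtype=float)
    if np.std(a) == 0:
        raise ValueError(f"anchor {anchor!r} is constant within group {group!r}")

    centred = x - x.mean(axis=1, keepdims=True)
    ss = (centred**2).sum(axis=1)
    constant = ss == 0
    n_constant = int(constant.sum())
    if n_constant:
        logger.warning(
            "correlation screen: excluded %d constant gene(s) in group %s",
            n_constant, group,
        )

    ac = a - a.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centred @ ac / np.sqrt(ss * (ac**2).sum())
    r = np.clip(r, -1.0, 1.0)

    genes = np.asarray(matrix.genes)[~constant]
    r = r[~constant]
    p = pearson_p_value(r, n)

    sig = p < thresholds.alpha if thresholds.require_significance else np.ones_like(r, bool)
    pos = r >= thresholds.r_pos if thresholds.require_magnitude else r > 0
    neg = r <= -thresholds.r_neg if thresholds.require_magnitude else r < 0
    in_gspc = pos & sig
    in_gsnc = neg & sig

    membership = np.where(in_gspc, "GSPC", np.where(in_gsnc, "GSNC", "none"))
    records = pd.DataFrame(
        {"r": r, "p": p, "n_samples": n, "list": membership},
        index=pd.Index(genes, name="gene"),
    )
    gspc = [g for g, flag in zip(genes, in_gspc) if flag]
    gsnc = [g for g, flag in zip(genes, in_gsnc) if flag]
    return CorrelationScreenResult(
        anchor=anchor,
        group=group,
        records=records,
        gspc=gspc,
        gsnc=gsnc,
        thresholds=thresholds,
        n_excluded_constant=n_constant,
    )
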