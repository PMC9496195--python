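"""Probe collapse, z-score standardisation and differential-expression screening.

The differential screen is a per-gene ordinary one-way ANOVA (for two groups
this is exactly the equal-variance t-test, F = t^2) with Benjamini-Hochberg
control of the false discovery rate across genes.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from anchorgda.core_io import ExpressionMatrix, normalize_symbol

logger = logging.getLogger(__name__)


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For a gene measured by several probes, the probe with the highest sample
    variance (n-1 denominator) is kept; variance ties break to the
    lexicographically smallest probe identifier. Probes absent from the
    mapping are dropped.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    mapping = {normalize_symbol(p): normalize_symbol(g) for p, g in probe_to_gene.items()}

    probes = [p for p in matrix.genes if p in mapping]
    n_unmapped = matrix.n_genes - len(probes)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probe rows", n_unmapped)
    if not probes:
        raise ValueError("no probe in the matrix is covered by the mapping")

    variances = matrix.values.loc[probes].var(axis=1, ddof=1)
    book = pd.DataFrame({"probe": probes, "gene": [mapping[p] for p in probes],
                         "variance": variances.to_numpy()})
    # highest variance first; ties resolved by probe id ascending
    book = book.sort_values(["variance", "probe"], ascending=[False, True], kind="mergesort")
    winners = book.groupby("gene", sort=False).head(1).set_index("probe")

    keep = [p for p in probes if p in winners.index]  # original row order
    collapsed = matrix.values.loc[keep].copy()
    collapsed.index = [winners.loc[p, "gene"] for p in keep]
    return ExpressionMatrix(values=collapsed, group_labels=dict(matrix.group_labels))


def zscore_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise every gene row to mean 0, sample sd 1 (n-1 denominator).

    Rows with zero variance carry no ordering information and are dropped
    with a log entry rather than silently mapped to zeros.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-score transform needs at least 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("zscore_transform: dropped %d constant rows", int(constant.sum()))
    kept = matrix.values.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return ExpressionMatrix(values=z, group_labels=dict(matrix.group_labels))


def sdeg(
    matrix: ExpressionMatrix,
    groups: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across sample groups with BH-adjusted q-values.

    Returns a DataFrame indexed by gene with columns ``statistic`` (F), ``p``,
    ``q``, ``direction`` (sign of mean(group2) - mean(group1) for two groups,
    NaN otherwise) and ``significant`` (q < alpha). Genes constant in every
    group are assigned p = 1.
    """
    if groups is None:
        groups = matrix.groups
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    blocks = []
    for g in groups:
        cols = matrix.samples_in_group(g)
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has {len(cols)} sample(s); need >=2")
        blocks.append(matrix.values[cols].to_numpy())

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*blocks, axis=1)
    degenerate = ~np.isfinite(p)  # zero within- and between-group variance
    p = np.where(degenerate, 1.0, p)
    f_stat = np.where(np.isfinite(f_stat), f_stat, 0.0)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    if len(groups) == 2:
        direction = np.sign(blocks[1].mean(axis=1) - blocks[0].mean(axis=1))
    else:
        direction = np.full(matrix.n_genes, np.nan)
    return pd.DataFrame(
        {
            "statistic": f_stat,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": q < alpha,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def tukey_pairwise(
    matrix: ExpressionMatrix, gene: str, groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one gene across >=2 groups."""
    gene = normalize_symbol(gene)
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    if groups is None:
        groups = matrix.groups
    groups = list(groups)
    samples = [matrix.values.loc[gene, matrix.samples_in_group(g)].to_numpy() for g in groups]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group1": groups[i],
                    "group2": groups[j],
                    "mean_diff": float(np.mean(samples[j]) - np.mean(samples[i])),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)
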