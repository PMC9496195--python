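"""Ranking of drug perturbations as candidate reversers of a query signature.

Each perturbation carries a signed similarity to the query signature
(negative = opposing/reversing, matching the convention of drug-repurposing
servers built on the LINCS-L1000 corpus), an enrichment p-value, a
standardized z and the combined score

    C = z * log10(p)

which is negative for a significant opposing drug (z > 0, p < 1); the most
negative C ranks first among candidate reversers.

``signature_similarity`` is local plumbing for building and testing ranked
tables offline: it scores reversal overlap between explicit up/down gene
sets with the hypergeometric tail from the deconvolution module. It is a
simple set-overlap score, not a reimplementation of any particular server's
corpus-based statistic.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from scipy import stats

from anchorgda.core_io import normalize_symbol
from anchorgda.deconvolution import hypergeom_upper_tail


def combined_score(z: float, p: float) -> float:
    """C = z * log10(p); zero when z = 0 or p = 1, negative for z > 0, p < 1."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return z * math.log10(p)


@dataclass
class DrugPerturbation:
    """One drug's perturbation record.

    ``combined_score`` is computed from z and p unless supplied explicitly
    (published tables often print C without the underlying p).
    """

    drug: str
    similarity: float
    z: float
    p: float = 1.0
    q: float = 1.0
    moa: str = ""
    indications: str = ""
    combined_score: float | None = None

    def __post_init__(self) -> None:
        if self.combined_score is None:
            self.combined_score = combined_score(self.z, self.p)


def rank_reversers(
    perturbations: Sequence[DrugPerturbation],
    q_threshold: float = 0.05,
    clinical_allowlist: Iterable[str] | None = None,
) -> list[DrugPerturbation]:
    """Filter to q < threshold (optionally to an allow-list of drugs already
    in clinical use) and sort by combined score ascending: the most negative
    score — the strongest predicted reverser — comes first. Ties break by
    drug name."""
    if not perturbations:
        raise ValueError("empty perturbation list")
    allowed = (
        None
        if clinical_allowlist is None
        else {d.strip().lower() for d in clinical_allowlist}
    )
    kept = [
        rec
        for rec in perturbations
        if rec.q < q_threshold
        and (allowed is None or rec.drug.strip().lower() in allowed)
    ]
    if not kept:
        warnings.warn("no perturbation passes the q threshold", stacklevel=2)
        return []
    return sorted(kept, key=lambda rec: (rec.combined_score, rec.drug.lower()))


def signature_similarity(
    query_up: Iterable[str],
    query_down: Iterable[str],
    pert_up: Iterable[str],
    pert_down: Iterable[str],
    N: int,
) -> tuple[float, float, float]:
    """Signed reversal similarity between a query and a perturbation signature.

    Returns ``(similarity, z, p)``. With q = query, t = perturbation:

        raw = (|qU & tD| + |qD & tU| - |qU & tU| - |qD & tD|) / (|qU| + |qD|)
        similarity = -raw

    so a perfect reverser (tU = qD, tD = qU) scores -1 and a perfect mimic
    +1: opposing drugs carry negative similarity. p is the hypergeometric
    upper tail of the reversal overlap count against universe N; z carries
    the magnitude of the standard-normal quantile of p and is positive for
    opposing perturbations, so the combined score z * log10(p) is strongly
    negative exactly for significant reversers.
    """
    qU = {normalize_symbol(g) for g in query_up}
    qD = {normalize_symbol(g) for g in query_down}
    tU = {normalize_symbol(g) for g in pert_up}
    tD = {normalize_symbol(g) for g in pert_down}
    if qU & qD:
        raise ValueError("query up and down sets overlap")
    if tU & tD:
        raise ValueError("perturbation up and down sets overlap")
    n_query = len(qU) + len(qD)
    if n_query == 0:
        raise ValueError("empty query signature")

    reversal = len(qU & tD) + len(qD & tU)
    concordance = len(qU & tU) + len(qD & tD)
    raw = (reversal - concordance) / n_query
    similarity = -raw

    p = hypergeom_upper_tail(reversal, n=n_query, D=len(tU) + len(tD), N=N)
    p = max(p, 1e-300)  # keep log10(p) finite when the tail underflows
    # magnitude: standard-normal quantile of p, floored at 0 so that p >= 0.5
    # (no evidence of excess reversal) yields z = 0 rather than a spurious sign
    quantile = max(float(stats.norm.isf(max(p, 1e-300))), 0.0)
    sign = -1.0 if similarity > 0 else 1.0 if similarity < 0 else 0.0
    z = sign * quantile if quantile > 0 else abs(quantile)
    return similarity, float(z), float(p)
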