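"""Gene-signature over-representation ("genomic deconvolution") scoring.

For a query gene list of size n intersected with a signature of size D in a
universe of N genes, the expected overlap is n*D/N, the representation
factor is RF = x / expected (RF > 1 means more overlap than chance), and the
significance of an observed overlap x is the exact hypergeometric upper
tail P(X >= x). The point probability

    P(X = x) = C(D, x) * C(N - D, n - x) / C(N, n)

is also reported for transparency. Computations go through scipy's
hypergeometric distribution, which works in log space and is stable for
genome-scale N.
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from anchorgda.core_io import SignatureCollection, normalize_symbol


def expected_overlap(n: int, D: int, N: int) -> float:
    """Expected number of shared genes between a random n-list and a D-list."""
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if n < 0 or D < 0:
        raise ValueError("list sizes must be non-negative")
    if n > N or D > N:
        raise ValueError(f"list sizes (n={n}, D={D}) cannot exceed the universe N={N}")
    return n * D / N


def representation_factor(x: int, n: int, D: int, N: int) -> float:
    """Observed over expected overlap: x * N / (n * D).

    Symmetric in n and D. RF > 1 iff x exceeds the chance expectation.
    """
    if x < 0 or x > min(n, D):
        raise ValueError(f"overlap x={x} outside [0, min(n, D)={min(n, D)}]")
    exp = expected_overlap(n, D, N)
    if exp == 0:
        raise ValueError("expected overlap is zero; representation factor undefined")
    return x / exp


def _support(n: int, D: int, N: int) -> tuple[int, int]:
    return max(0, n + D - N), min(n, D)


def hypergeom_point(x, n: int, D: int, N: int):
    """Exact probability of an overlap of exactly x genes.

    ``x`` may be a scalar or an array (scipy-style broadcasting over x).
    Outside the feasible support the probability is 0, not an error.
    """
    _check_domain(n, D, N)
    lo, hi = _support(n, D, N)
    xs = np.asarray(x)
    out = np.where(
        (xs < lo) | (xs > hi), 0.0, stats.hypergeom.pmf(np.clip(xs, lo, hi), N, D, n)
    )
    return float(out) if np.isscalar(x) else out


def hypergeom_upper_tail(x, n: int, D: int, N: int):
    """P(X >= x): the over-representation p-value for an observed overlap x.

    ``x`` may be a scalar or an array.
    """
    _check_domain(n, D, N)
    lo, hi = _support(n, D, N)
    xs = np.asarray(x)
    out = np.where(
        xs <= lo,
        1.0,
        np.where(xs > hi, 0.0, stats.hypergeom.sf(np.clip(xs, lo, hi) - 1, N, D, n)),
    )
    return float(out) if np.isscalar(x) else out


def _neglog10_upper_tail(x: int, n: int, D: int, N: int) -> float:
    p = hypergeom_upper_tail(x, n, D, N)
    if p > 0:
        return -math.log10(p)
    # underflow below the smallest double: recover the magnitude in log space
    with np.errstate(divide="ignore"):
        logsf = float(stats.hypergeom.logsf(x - 1, N, D, n))
    return -logsf / math.log(10)


def _check_domain(n: int, D: int, N: int) -> None:
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= n <= N and 0 <= D <= N):
        raise ValueError(f"need 0 <= n, D <= N; got n={n}, D={D}, N={N}")


def overlap_percent(x: int, D: int) -> float:
    """Overlap as a percentage of the signature, 100*x/D.

    Reported truncated to two decimals (exact integer arithmetic, so e.g.
    37/78 -> 47.43), the display convention of enrichment reports this
    package interoperates with.
    """
    if D <= 0:
        raise ValueError("signature size D must be positive")
    if x < 0 or x > D:
        raise ValueError(f"overlap x={x} outside [0, D={D}]")
    return ((10000 * int(x)) // int(D)) / 100.0


@dataclass
class SignatureOverlap:
    """Enrichment record for one signature against one query gene list."""

    signature_name: str
    category: str
    x: int            # overlap count
    n: int            # query-list size
    D: int            # signature size
    N: int            # universe size
    expected: float   # n*D/N
    rf: float         # x / expected
    p_point: float    # P(X = x)
    p_tail: float     # P(X >= x)
    neglog10_p: float
    percent: float    # 100*x/D
    overlap_genes: tuple[str, ...]
    enriched: bool
    q_tail: float | None = None  # BH-adjusted tail p, when requested


def deconvolve(
    query: Iterable[str],
    collection: SignatureCollection,
    alpha: float = 0.05,
    adjust: bool = False,
    measured_genes: Iterable[str] | None = None,
) -> list[SignatureOverlap]:
    """Score every signature in the collection against one query gene list.

    The query is deduplicated and uppercased first, so the result is
    invariant to ordering and repeated symbols. By default the universe size
    is taken from the collection (fixed N, signatures used as supplied); if
    ``measured_genes`` is given, query and signatures are first intersected
    with that set and N becomes its cardinality (strict-universe mode).

    ``enriched`` requires RF > 1 and tail p (BH-adjusted across the
    collection when ``adjust``) below ``alpha``.
    """
    query_set = {normalize_symbol(g) for g in query if str(g).strip()}
    if not query_set:
        raise ValueError("query gene list is empty")
    if not len(collection):
        raise ValueError("signature collection is empty")

    if measured_genes is not None:
        universe = {normalize_symbol(g) for g in measured_genes}
        if not universe:
            raise ValueError("measured-gene universe is empty")
        query_set &= universe
        if not query_set:
            raise ValueError("query has no genes in the measured universe")
        N = len(universe)
    else:
        universe = None
        N = collection.universe_size

    n = len(query_set)
    results = []
    for sig in collection:
        genes = sig.genes if universe is None else sig.genes & universe
        D = len(genes)
        overlap = tuple(sorted(query_set & genes))
        x = len(overlap)
        exp = expected_overlap(n, D, N)
        rf = x / exp if exp > 0 else 0.0
        p_point = hypergeom_point(x, n, D, N)
        p_tail = hypergeom_upper_tail(x, n, D, N)
        results.append(
            SignatureOverlap(
                signature_name=sig.name,
                category=sig.category,
                x=x,
                n=n,
                D=D,
                N=N,
                expected=exp,
                rf=rf,
                p_point=p_point,
                p_tail=p_tail,
                neglog10_p=_neglog10_upper_tail(x, n, D, N),
                percent=overlap_percent(x, D) if D > 0 else 0.0,
                overlap_genes=overlap,
                enriched=False,
            )
        )

    tail = np.array([r.p_tail for r in results])
    if adjust:
        _, q, _, _ = multipletests(tail, method="fdr_bh")
    else:
        q = tail
    for rec, rec_q in zip(results, q):
        rec.q_tail = float(rec_q) if adjust else None
        rec.enriched = bool(rec.rf > 1 and rec_q < alpha)
    return results


def overlap_table(results: list[SignatureOverlap]) -> "pd.DataFrame":
    """Tabular report, display fields rounded to two decimals."""
    import pandas as pd

    return pd.DataFrame(
        {
            "signature": [r.signature_name for r in results],
            "category": [r.category for r in results],
            "x": [r.x for r in results],
            "n": [r.n for r in results],
            "D": [r.D for r in results],
            "N": [r.N for r in results],
            "expected": [round(r.expected, 2) for r in results],
            "RF": [round(r.rf, 2) for r in results],
            "p_point": [r.p_point for r in results],
            "p_tail": [r.p_tail for r in results],
            "neglog10_p": [round(r.neglog10_p, 2) for r in results],
            "percent": [r.percent for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
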