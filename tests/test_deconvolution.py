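import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from anchorgda.core_io import GeneSignature, SignatureCollection
from anchorgda.deconvolution import (
    deconvolve,
    expected_overlap,
    hypergeom_point,
    hypergeom_upper_tail,
    overlap_percent,
    representation_factor,
)
from anchorgda.synthetic_data import SimulationConfig, generate_dataset
from anchorgda.correlation_screen import correlate_to_anchor


def exact_point(x: int, n: int, D: int, N: int) -> Fraction:
    """Independent oracle: rational hypergeometric point probability."""
    if x < max(0, n + D - N) or x > min(n, D):
        return Fraction(0)
    return Fraction(math.comb(D, x) * math.comb(N - D, n - x), math.comb(N, n))


def exact_tail(x: int, n: int, D: int, N: int) -> Fraction:
    return sum(
        (exact_point(k, n, D, N) for k in range(max(x, 0), min(n, D) + 1)),
        Fraction(0),
    )


class TestExpectedAndRf:
    def test_expected_overlap_worked_example(self):
        # n=2542 query genes, D=118 signature genes, N=20203 universe
        assert expected_overlap(2542, 118, 20203) == pytest.approx(14.8471, abs=1e-4)

    def test_expected_edge_cases(self):
        assert expected_overlap(100, 0, 20203) == 0.0
        assert expected_overlap(20203, 77, 20203) == 77.0
        with pytest.raises(ValueError):
            expected_overlap(10, 5, 0)
        with pytest.raises(ValueError):
            expected_overlap(30, 5, 20)

    def test_rf_worked_example(self):
        assert representation_factor(70, 2542, 118, 20203) == pytest.approx(
            70 / (2542 * 118 / 20203), rel=1e-12
        )
        assert representation_factor(70, 2542, 118, 20203) == pytest.approx(4.7147, abs=1e-4)

    def test_rf_one_at_expectation_and_zero_overlap(self):
        # x = n*D/N exactly integral: n=100, D=50, N=1000 -> expected 5
        assert representation_factor(5, 100, 50, 1000) == pytest.approx(1.0)
        assert representation_factor(0, 100, 50, 1000) == 0.0

    def test_rf_symmetric_in_n_and_D(self):
        assert representation_factor(7, 40, 90, 500) == pytest.approx(
            representation_factor(7, 90, 40, 500)
        )

    def test_rf_interpretation_exhaustive_small_grid(self):
        """RF > 1 iff x > expected; RF < 1 iff x < expected (N <= 30)."""
        for N in (5, 12, 30):
            for D in range(1, N + 1):
                for n in range(1, N + 1):
                    exp = expected_overlap(n, D, N)
                    for x in range(max(0, n + D - N), min(n, D) + 1):
                        rf = representation_factor(x, n, D, N)
                        assert (rf > 1) == (x > exp)
                        assert (rf < 1) == (x < exp)


class TestHypergeometric:
    def test_point_brute_force_example(self):
        # C(4,2)*C(6,3)/C(10,5) = 6*20/252
        assert hypergeom_point(2, 5, 4, 10) == pytest.approx(120 / 252, rel=1e-12)

    def test_tail_brute_force_example(self):
        # P(X >= 3) = (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5) = (60+6)/252
        assert hypergeom_upper_tail(3, 5, 4, 10) == pytest.approx(66 / 252, rel=1e-12)

    def test_degenerate_and_boundary_cases(self):
        assert hypergeom_point(4, 4, 4, 4) == pytest.approx(1.0)
        assert hypergeom_upper_tail(0, 13, 7, 50) == 1.0
        assert hypergeom_upper_tail(min(13, 7) + 1, 13, 7, 50) == 0.0
        assert hypergeom_point(9, 5, 4, 10) == 0.0  # beyond support

    def test_point_probabilities_sum_to_one(self):
        total = sum(hypergeom_point(x, 13, 7, 50) for x in range(0, 8))
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.integers(1, 60).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(0, N), st.integers(0, N))
    ))
    def test_matches_rational_oracle(self, nDn):
        N, D, n = nDn
        for x in range(max(0, n + D - N), min(n, D) + 1):
            p = hypergeom_point(x, n, D, N)
            t = hypergeom_upper_tail(x, n, D, N)
            assert p == pytest.approx(float(exact_point(x, n, D, N)), rel=1e-10)
            assert t == pytest.approx(float(exact_tail(x, n, D, N)), rel=1e-10)

    def test_tail_monotone_nonincreasing_in_x(self):
        n, D, N = 40, 25, 200
        tails = [hypergeom_upper_tail(x, n, D, N) for x in range(0, 26)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestOverlapPercent:
    @pytest.mark.parametrize(
        "x,D,expected",
        [(19, 45, 42.22), (37, 78, 47.43), (0, 10, 0.0), (160, 160, 100.0)],
    )
    def test_printed_precision(self, x, D, expected):
        assert overlap_percent(x, D) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            overlap_percent(1, 0)
        with pytest.raises(ValueError):
            overlap_percent(11, 10)


class TestDeconvolve:
    def test_query_identical_to_signature(self, small_collection):
        sig = small_collection.get("setA")
        res = deconvolve(sorted(sig.genes), small_collection)
        rec = {r.signature_name: r for r in res}["setA"]
        assert rec.x == rec.D == sig.size
        assert rec.percent == 100.0
        assert rec.rf > 1
        assert rec.enriched

    def test_disjoint_query(self, small_collection):
        res = deconvolve(["ZZ1", "ZZ2"], small_collection)
        assert all(r.x == 0 and r.rf == 0.0 and not r.enriched for r in res)

    def test_invariant_to_order_case_and_duplication(self, small_collection):
        a = deconvolve(["g1", "G2", "g3"], small_collection)
        b = deconvolve(["G3", "G2", "G1", "g2", "g2"], small_collection)
        for ra, rb in zip(a, b):
            assert (ra.x, ra.n, ra.p_tail, ra.overlap_genes) == (
                rb.x, rb.n, rb.p_tail, rb.overlap_genes
            )

    def test_empty_query_is_error(self, small_collection):
        with pytest.raises(ValueError, match="empty"):
            deconvolve([], small_collection)

    def test_bh_adjustment_only_raises_p(self, small_collection):
        raw = deconvolve(["G1", "G2", "G3"], small_collection, adjust=False)
        adj = deconvolve(["G1", "G2", "G3"], small_collection, adjust=True)
        for r_raw, r_adj in zip(raw, adj):
            assert r_adj.q_tail >= r_raw.p_tail - 1e-15

    def test_strict_universe_mode_restricts_counts(self, small_collection):
        measured = ["G1", "G2", "G3", "G4", "X1", "X2"]
        res = deconvolve(["G1", "G2", "X9"], small_collection,
                         measured_genes=measured)
        rec = {r.signature_name: r for r in res}["setB"]
        assert rec.N == 6
        assert rec.D == 2  # only G3, G4 measured
        assert rec.n == 2  # X9 not measured

    def test_planted_signature_recovery_end_to_end(self):
        cfg = SimulationConfig(seed=42)
        matrix, collection, _ = generate_dataset(cfg)
        screen = correlate_to_anchor(matrix, cfg.anchor_name, cfg.pos_group)
        pos_hits = {r.signature_name: r for r in deconvolve(screen.gspc, collection)}
        neg_hits = {r.signature_name: r for r in deconvolve(screen.gsnc, collection)}
        assert pos_hits["microglia_like"].enriched
        assert not pos_hits["neuron_like"].enriched
        assert neg_hits["neuron_like"].enriched
        assert not neg_hits["microglia_like"].enriched
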