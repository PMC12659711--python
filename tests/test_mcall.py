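"""Binomial methylcytosine calling, replicate consensus and dynamics."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from methdyn._util import MethdynError
from methdyn import mcall
from methdyn.mcall import (
    ConsensusSet,
    binomial_pvalue,
    call_methylated_sites,
    classify_dynamics,
    estimate_conversion_error,
    intersect_replicates,
    methylation_difference_density,
    overlap_mC,
)


def exact_upper_tail(k: int, n: int, e: Fraction) -> float:
    """Independent oracle: exact-arithmetic sum of binomial pmf terms."""
    return float(sum(comb(n, i) * e**i * (1 - e) ** (n - i) for i in range(k, n + 1)))


def counts_frame(rows):
    """rows: (chrom, pos, strand, context, meth, unmeth)"""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
    )


class TestBinomialPvalue:
    @pytest.mark.parametrize(
        "k, n, e, expected",
        [
            (0, 5, 0.014, 1.0),                      # P(X >= 0) = 1
            (5, 5, 0.014, 5.37824e-10),              # 0.014 ** 5
            (2, 5, 0.0144, 2.014522815849431e-3),    # exact pmf sum, frozen
            (1, 20, 0.014, 0.24571008904764802),     # 1 - 0.986 ** 20
        ],
    )
    def test_pinned_values(self, k, n, e, expected):
        assert binomial_pvalue(k, n, e) == pytest.approx(expected, rel=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(MethdynError):
            binomial_pvalue(6, 5, 0.014)

    def test_agrees_with_exact_oracle(self):
        for e_frac in (Fraction(1, 1000), Fraction(14, 1000)):
            e = float(e_frac)
            for n in (1, 5, 17, 50):
                for k in range(n + 1):
                    expected = exact_upper_tail(k, n, e_frac)
                    assert binomial_pvalue(k, n, e) == pytest.approx(
                        expected, rel=1e-12
                    )

    def test_stable_at_large_n(self):
        p = binomial_pvalue(9_000, 10_000, 0.014)
        assert 0.0 <= p < 1e-300 or p == 0.0  # deep tail, no overflow/nan


class TestConversionError:
    def test_pooled_ratio(self):
        counts = counts_frame(
            [("chrC", i, "+", "CHH", m, u) for i, (m, u) in
             enumerate([(100, 4900), (40, 4960)])]
        )
        err = estimate_conversion_error(counts, {"chrC"}, "s")
        assert err.e == pytest.approx(140 / 10_000)
        assert err.total_chloroplast_coverage == 10_000

    def test_zero_ratio_floored(self, caplog):
        counts = counts_frame([("chrC", 1, "+", "CHH", 0, 5000)])
        err = estimate_conversion_error(counts, {"chrC"}, "s")
        assert err.e == 1e-4 and err.floored

    def test_requires_chloroplast_and_coverage(self):
        counts = counts_frame([("chrC", 1, "+", "CHH", 0, 0)])
        with pytest.raises(MethdynError):
            estimate_conversion_error(counts, set(), "s")
        with pytest.raises(MethdynError, match="coverage"):
            estimate_conversion_error(counts, {"chrC"}, "s")

    def test_recovers_true_rate_in_seeded_simulation(self):
        from methdyn.synthetic import simulate_chloroplast_counts

        e_true = 0.0142
        counts = simulate_chloroplast_counts(5000, 20.0, e_true, seed=7)
        err = estimate_conversion_error(counts, {"chrC"}, "s")
        total = err.total_chloroplast_coverage
        se = np.sqrt(e_true * (1 - e_true) / total)
        assert abs(err.e - e_true) < 3 * se


class TestCalling:
    def test_threshold_behaviour(self):
        counts = counts_frame(
            [
                ("chr1", 10, "+", "CpG", 5, 0),    # p ~ 5e-10 -> methylated
                ("chr1", 20, "+", "CpG", 1, 19),   # p ~ 0.246 -> not
                ("chr1", 30, "+", "CpG", 4, 0),    # depth 4 -> no call
            ]
        )
        calls = call_methylated_sites(counts, 0.014)
        assert calls["pos"].tolist() == [10, 20]
        assert calls["methylated"].tolist() == [True, False]

    def test_alpha_monotonicity(self, rng):
        counts = counts_frame(
            [("chr1", i, "+", "CHH", int(k), int(20 - k))
             for i, k in enumerate(rng.integers(0, 8, 300))]
        )
        loose = call_methylated_sites(counts, 0.014, alpha=0.05)
        strict = call_methylated_sites(counts, 0.014, alpha=0.005)
        assert strict["methylated"].sum() <= loose["methylated"].sum()

    def test_min_depth_monotonicity(self, rng):
        depth = rng.integers(0, 30, 300)
        k = rng.binomial(depth, 0.3)
        counts = counts_frame(
            [("chr1", i, "+", "CHH", int(ki), int(d - ki))
             for i, (ki, d) in enumerate(zip(k, depth))]
        )
        shallow = call_methylated_sites(counts, 0.014, min_depth=5)
        deep = call_methylated_sites(counts, 0.014, min_depth=10)
        assert len(deep) <= len(shallow)
        assert deep["methylated"].sum() <= shallow["methylated"].sum()


def calls_from(rows):
    """rows: (pos, k, n, methylated) on chr1 + strand CpG"""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [r[0] for r in rows],
            "strand": "+",
            "context": "CpG",
            "k": [r[1] for r in rows],
            "n": [r[2] for r in rows],
            "level": [r[1] / r[2] for r in rows],
            "p": 0.0,
            "methylated": [r[3] for r in rows],
        }
    )


class TestConsensus:
    def test_intersection_semantics(self):
        r1 = calls_from([(1, 5, 5, True), (2, 6, 6, True), (3, 7, 7, True), (4, 0, 9, False)])
        r2 = calls_from([(2, 3, 6, True), (3, 7, 7, True), (4, 9, 9, True)])
        cons = intersect_replicates(r1, r2, "s")
        assert sorted(cons.sites["pos"]) == [2, 3]

    def test_consensus_level_is_coverage_weighted(self):
        r1 = calls_from([(1, 5, 10, True)])
        r2 = calls_from([(1, 20, 20, True)])
        cons = intersect_replicates(r1, r2, "s")
        assert cons.sites["level"].iloc[0] == pytest.approx(25 / 30)

    def test_disjoint_replicates_empty_consensus(self, caplog):
        r1 = calls_from([(1, 5, 5, True)])
        r2 = calls_from([(2, 5, 5, True)])
        assert len(intersect_replicates(r1, r2, "s")) == 0


def consensus_of(positions, contexts=None):
    n = len(positions)
    return ConsensusSet(
        "s",
        pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": list(positions),
                "strand": "+",
                "context": contexts or ["CpG"] * n,
                "level": 0.8,
            }
        ),
    )


class TestOverlapAndDynamics:
    def test_identity_and_disjoint_overlap(self):
        a = consensus_of(range(10))
        assert overlap_mC(a, a)["pct_of_a"] == 100.0
        b = consensus_of(range(100, 110))
        res = overlap_mC(a, b)
        assert res["shared"] == 0 and res["pct_of_b"] == 0.0

    def test_constructed_70pct_overlap_recovered(self):
        a = consensus_of(range(100))
        b = consensus_of(list(range(70)) + list(range(1000, 1030)))
        res = overlap_mC(a, b)
        assert res["pct_of_a"] == pytest.approx(70.0)
        comp = res["context_composition"]
        assert sum(comp.values()) == pytest.approx(100.0)

    def test_dynamics_partition(self):
        control = consensus_of([1, 2, 3])
        stress = consensus_of([3, 4])
        dy = classify_dynamics(control, stress)
        by_pos = dy.set_index("pos")["class"]
        assert by_pos[1] == "DI" and by_pos[2] == "DI"
        assert by_pos[4] == "DII"
        assert by_pos[3] == "maintained"
        # classes are mutually exclusive and exhaustive
        assert len(dy) == 4


class TestDifferenceDensity:
    def test_integrates_to_one(self, rng):
        a = rng.uniform(0.2, 0.8, 2000)
        b = rng.uniform(0.2, 0.8, 2000)
        dens = methylation_difference_density(a, b)
        area = np.trapezoid(dens["density"], dens["diff"])
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_antisymmetric_under_swap(self, rng):
        a = rng.uniform(0.2, 0.9, 500)
        b = rng.uniform(0.1, 0.8, 500)
        d1 = methylation_difference_density(a, b)["density"].to_numpy()
        d2 = methylation_difference_density(b, a)["density"].to_numpy()
        assert np.allclose(d1, d2[::-1], atol=1e-9)

    def test_degenerate_all_zero_differences(self):
        a = np.full(100, 0.5)
        dens = methylation_difference_density(a, a)
        assert dens.loc[dens["density"].idxmax(), "diff"] == pytest.approx(0.0, abs=0.01)

    def test_mode_recovers_planted_shift(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.1, 0.05, 5000)
        a = np.clip(0.5 + diffs, 0, 1)
        b = np.full(5000, 0.5)
        dens = methylation_difference_density(a, b)
        mode = dens.loc[dens["density"].idxmax(), "diff"]
        assert abs(mode - 0.1) < 0.02

    def test_too_few_sites_rejected(self):
        with pytest.raises(MethdynError):
            methylation_difference_density(np.ones(10), np.ones(10))
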