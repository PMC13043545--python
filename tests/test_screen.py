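"""Normalization, dispersion, NB guide tests, alpha-RRA, and hit calling.

Oracles: the median-ratio hand example, brute-force NB mass summation,
and the binomial-sum closed form of the Beta order-statistic CDF.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from toxscreen import (
    CountMatrix,
    RraConfig,
    ScreenSimConfig,
    alpha_rra,
    call_hits,
    estimate_dispersion,
    gene_scores,
    normalize_median_ratio,
    sgrna_test,
    simulate_library,
    simulate_screen_counts,
    volcano_table,
)
from toxscreen.screen import _nb_tails


def _matrix(values, samples=("c1", "c2"), conditions=None):
    n = len(values)
    counts = pd.DataFrame(
        np.asarray(values), columns=list(samples),
        index=pd.Index([f"sg{i}" for i in range(n)], name="sgrna"),
    )
    genes = pd.Series([f"g{i}" for i in range(n)], index=counts.index)
    conditions = conditions or {s: "control" for s in samples}
    return CountMatrix(counts=counts, genes=genes, conditions=conditions)


class TestNormalization:
    def test_hand_computed_example(self):
        cm = _matrix([[10, 20], [30, 60]])
        norm = normalize_median_ratio(cm)
        np.testing.assert_allclose(norm.size_factors, [0.70711, 1.41421], rtol=1e-4)
        np.testing.assert_allclose(
            norm.values.to_numpy(), [[14.142, 14.142], [42.426, 42.426]], rtol=1e-4
        )

    def test_identical_samples_unchanged(self):
        cm = _matrix([[5, 5], [9, 9], [2, 2]])
        norm = normalize_median_ratio(cm)
        np.testing.assert_allclose(norm.size_factors, [1.0, 1.0])
        np.testing.assert_allclose(norm.values, cm.counts)

    def test_scaled_column_equalized(self):
        base = np.array([[10, 20], [30, 60], [7, 14], [100, 200]])
        norm = normalize_median_ratio(_matrix(base))
        np.testing.assert_allclose(norm.values["c1"], norm.values["c2"])

    @given(
        st.integers(min_value=2, max_value=20).flatmap(
            lambda n: st.tuples(
                st.lists(
                    st.lists(st.integers(1, 1000), min_size=3, max_size=3),
                    min_size=n, max_size=n,
                ),
                st.sampled_from([2, 3, 5]),
            )
        )
    )
    def test_column_scaling_absorbed_by_size_factors(self, data):
        # rescaling one sample changes normalized values only by a single
        # global factor: all cross-sample structure is preserved
        values, k = data
        cm = _matrix(values, samples=("a", "b", "c"))
        scaled = np.asarray(values, dtype=int)
        scaled[:, 1] *= k
        cm2 = _matrix(scaled, samples=("a", "b", "c"))
        n1 = normalize_median_ratio(cm).values.to_numpy()
        n2 = normalize_median_ratio(cm2).values.to_numpy()
        ratio = n2 / n1
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_total_count_fallback(self):
        # every row touches zero, so no reference row exists
        cm = _matrix([[0, 5], [4, 0], [3, 0]])
        norm = normalize_median_ratio(cm)
        assert norm.method == "total-count"
        np.testing.assert_allclose(
            norm.size_factors, np.array([7, 5]) / 6.0
        )


class TestDispersion:
    def test_poisson_data_near_identity(self):
        cfg = ScreenSimConfig(n_genes=5000, dispersion=0.0, mean_depth=500,
                              frac_sensitive=0, frac_resistant=0, seed=6)
        cm, _ = simulate_screen_counts(simulate_library(cfg), cfg)
        norm = normalize_median_ratio(cm)
        fit = estimate_dispersion(norm)
        m = norm.values[norm.samples_in("control")].mean(axis=1)
        ratio = (fit.sigma2 / m).to_numpy()
        assert np.median(ratio) < 1.1
        assert np.percentile(ratio, 95) < 1.15

    def test_nb_dispersion_recovered(self):
        cfg = ScreenSimConfig(n_genes=10_000, dispersion=0.1,
                              frac_sensitive=0, frac_resistant=0, seed=5)
        cm, _ = simulate_screen_counts(simulate_library(cfg), cfg)
        fit = estimate_dispersion(normalize_median_ratio(cm))
        assert fit.method == "trend"
        assert abs(fit.exponent - 2.0) < 0.25
        assert abs(fit.scale - 0.1) / 0.1 < 0.25

    def test_underdispersed_input_clamped(self):
        # constant columns: every variance is 0 <= mean, pooled phi = 0
        cm = _matrix([[50, 50, 50], [80, 80, 80]], samples=("a", "b", "c"))
        fit = estimate_dispersion(normalize_median_ratio(cm))
        assert fit.method == "pooled"
        np.testing.assert_allclose(fit.sigma2, [50 * (1 + 1e-6), 80 * (1 + 1e-6)])


def _nb_pmf(k, mu, phi):
    r = 1.0 / phi
    p = r / (r + mu)
    return math.exp(
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log(1 - p)
    )


class TestSgrnaTest:
    @pytest.mark.parametrize("x", range(0, 16, 3))
    def test_tails_match_mass_summation(self, x):
        mu, phi = 5.0, 0.2
        var = mu + phi * mu**2
        p_low, p_high = _nb_tails(np.array([mu]), np.array([var]), np.array([x]))
        lo = sum(_nb_pmf(k, mu, phi) for k in range(0, x + 1))
        hi = 1.0 - sum(_nb_pmf(k, mu, phi) for k in range(0, x))
        np.testing.assert_allclose(p_low[0], lo, rtol=1e-9)
        np.testing.assert_allclose(p_high[0], hi, rtol=1e-9)

    def test_poisson_limit_tail(self):
        p_low, p_high = _nb_tails(np.array([500.0]), np.array([500.0 * (1 + 1e-6)]),
                                  np.array([0.0]))
        np.testing.assert_allclose(p_low[0], math.exp(-500), rtol=1e-6)
        assert p_high[0] == 1.0

    def test_discrete_tail_overlap_at_observed_mean(self):
        mu, phi = 20.0, 0.1
        var = mu + phi * mu**2
        p_low, p_high = _nb_tails(np.array([mu]), np.array([var]), np.array([mu]))
        pmf = _nb_pmf(20, mu, phi)
        assert p_low[0] + p_high[0] >= 1
        assert p_low[0] >= pmf and p_high[0] >= pmf

    def test_ranks_are_permutations_and_percentiles_positive(self, small_screen):
        _, _, cm, _ = small_screen
        norm = normalize_median_ratio(cm)
        sg = sgrna_test(norm, estimate_dispersion(norm))
        m = len(sg)
        for col in ("rank_low", "rank_high"):
            assert sorted(sg[col]) == list(range(1, m + 1))
        assert (sg["percentile_low"] > 0).all()
        assert (sg[["p_low", "p_high"]] > 0).all().all()
        assert (sg[["p_low", "p_high"]] <= 1).all().all()

    def test_zero_control_mean_uses_pseudocount(self):
        cm = _matrix(
            [[0, 0, 0, 40, 40, 40], [100, 100, 100, 100, 100, 100],
             [50, 60, 55, 50, 60, 55]],
            samples=("c1", "c2", "c3", "e1", "e2", "e3"),
            conditions={"c1": "control", "c2": "control", "c3": "control",
                        "e1": "exposed", "e2": "exposed", "e3": "exposed"},
        )
        norm = normalize_median_ratio(cm)
        sg = sgrna_test(norm, estimate_dispersion(norm), pseudocount=1.0)
        row = sg.set_index("sgrna").loc["sg0"]
        assert np.isfinite(row["log2fc"]) and row["log2fc"] > 0
        assert 0 < row["p_high"] < 1e-6  # 40 observed vs null mean 1


class TestAlphaRra:
    def test_single_guide_uniform_closed_form(self):
        assert alpha_rra([0.05], 0.25) == pytest.approx(0.05)

    def test_two_guide_example(self):
        rho = alpha_rra([0.01, 0.02], 0.25)
        assert rho == pytest.approx(4e-4, rel=1e-6)
        # intermediate scores: 1-(0.99)^2 and 0.02^2
        assert rho == pytest.approx(min(0.0199, 0.0004), rel=1e-6)

    def test_no_guide_past_cutoff_scores_one(self):
        assert alpha_rra([0.5, 0.9], 0.25) == 1.0

    @pytest.mark.parametrize("j", [1, 2, 3, 4])
    def test_matches_binomial_sum_oracle(self, j, rng):
        # P(Beta(k, J-k+1) <= r) equals the upper binomial sum
        # sum_{i>=k} C(J,i) r^i (1-r)^(J-i): enumerate every prefix k
        for _ in range(25):
            r = np.sort(rng.uniform(0.001, 1.0, size=j))
            alpha = rng.uniform(0.05, 1.0)
            expected = 1.0
            for k in range(1, j + 1):
                if r[k - 1] > alpha:
                    break
                tail = sum(
                    math.comb(j, i) * r[k - 1] ** i * (1 - r[k - 1]) ** (j - i)
                    for i in range(k, j + 1)
                )
                expected = min(expected, tail)
            assert alpha_rra(r, alpha) == pytest.approx(expected, rel=1e-9)

    @given(
        st.integers(1, 6).flatmap(
            lambda j: st.tuples(
                st.lists(st.floats(1e-6, 1.0), min_size=j, max_size=j),
                st.lists(st.floats(0.0, 0.5), min_size=j, max_size=j),
                st.floats(0.05, 1.0),
            )
        )
    )
    def test_monotone_in_percentiles(self, data):
        r, bumps, alpha = data
        r = np.asarray(r)
        worse = np.minimum(r + np.asarray(bumps), 1.0)
        assert alpha_rra(r, alpha) <= alpha_rra(worse, alpha) + 1e-12
        assert 0 < alpha_rra(r, alpha) <= 1

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            alpha_rra([0.0, 0.5], 0.25)
        with pytest.raises(ValueError):
            alpha_rra([1.5], 0.25)


@pytest.fixture(scope="module")
def scored(small_screen):
    _, _, cm, truth = small_screen
    norm = normalize_median_ratio(cm)
    sg = sgrna_test(norm, estimate_dispersion(norm))
    g = gene_scores(sg, RraConfig(n_permutations=20_000, seed=3))
    return sg, g, truth


class TestGenePermutation:
    def test_p_floor_and_fdr_dominance(self, scored):
        _, g, _ = scored
        floor = 1.0 / (20_000 + 1)
        assert (g["p_low"] >= floor - 1e-15).all()
        assert (g["fdr_low"] >= g["p_low"] - 1e-15).all()
        assert (g["fdr_high"] >= g["p_high"] - 1e-15).all()

    def test_score_beating_every_permutation_hits_floor(self):
        from toxscreen.screen import _permutation_p

        rng = np.random.default_rng(4)
        pool = (np.arange(1, 401) / 400.0)
        cfg = RraConfig(n_permutations=5000, seed=5)
        p = _permutation_p(np.array([1e-12]), np.array([2]), pool, cfg, rng)
        assert p[0] == pytest.approx(1.0 / 5001)

    def test_permutation_deterministic_per_seed(self, scored):
        sg, g, _ = scored
        g2 = gene_scores(sg, RraConfig(n_permutations=20_000, seed=3))
        pd.testing.assert_frame_equal(g, g2)

    def test_direction_consistent_with_thresholds(self, scored):
        _, g, _ = scored
        sens = g[g["direction"] == "sensitive"]
        assert (sens["p_low"] < 0.01).all() and (sens["gene_log2fc"] < -0.6).all()
        res = g[g["direction"] == "resistant"]
        assert (res["p_high"] < 0.01).all() and (res["gene_log2fc"] > 0.6).all()


class TestCallHits:
    @pytest.fixture
    def frame(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d", "e"],
                "p_low": [0.005, 0.005, 0.02, 0.9, 0.001],
                "p_high": [0.9, 0.9, 0.9, 0.005, 0.9],
                "gene_log2fc": [-0.7, -0.6, -2.0, 2.0, -1.0],
            }
        )

    def test_threshold_rules_are_strict(self, frame):
        sens, res = call_hits(frame)
        assert list(sens["gene"]) == ["e", "a"]  # b fails lfc==-0.6, c fails p
        assert list(res["gene"]) == ["d"]

    def test_sorted_by_p_then_effect(self, frame):
        frame.loc[0, "p_low"] = 0.001  # tie with e; |lfc| e=1.0 > a=0.7
        sens, _ = call_hits(frame)
        assert list(sens["gene"]) == ["e", "a"]

    def test_volcano_classes(self, frame):
        v = volcano_table(frame)
        assert list(v["class"]) == ["sensitive", "other", "other", "resistant",
                                    "sensitive"]
        assert np.isfinite(v["minus_log10_p"]).all()
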