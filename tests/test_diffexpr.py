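"""Normalization, dispersion, NB Wald testing, BH and the call rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import two_group_counts
from mirgrn.diffexpr import (
    ComparisonSpec,
    assign_direction,
    benjamini_hochberg,
    call_differential,
    estimate_dispersions,
    low_count_filter,
    nb_wald_test,
    size_factors,
)
from mirgrn.io_formats import CountMatrix, SampleMetadata, ValidationError


def _cm(data, features, samples):
    return CountMatrix(pd.DataFrame(data, index=features, columns=samples))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[10, 10], [50, 50]], ["a", "b"], ["S1", "S2"])
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_sample_splits_geometrically(self):
        # sample2 = 2 x sample1: ratios to the geometric-mean reference are
        # 1/sqrt(2) and sqrt(2) for every feature, hence for the median
        cm = _cm([[10, 20], [50, 100], [7, 14]], ["a", "b", "c"], ["S1", "S2"])
        sf = size_factors(cm)
        assert np.allclose(sf.values, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_unit_factor(self):
        cm = _cm([[10], [5]], ["a", "b"], ["S1"])
        assert np.allclose(size_factors(cm), 1.0)

    def test_no_all_positive_feature_is_an_error(self):
        cm = _cm([[0, 5], [5, 0]], ["a", "b"], ["S1", "S2"])
        with pytest.raises(ValidationError, match="median-of-ratios"):
            size_factors(cm)


class TestDispersions:
    def _md(self, samples, groups):
        order = sorted(set(groups), key=groups.index)
        return SampleMetadata(dict(zip(samples, groups)), order)

    def test_constant_feature_hits_floor(self):
        samples = ["s1", "s2", "s3", "s4"]
        cm = _cm([[7, 7, 7, 7]], ["a"], samples)
        md = self._md(samples, ["g1", "g1", "g2", "g2"])
        phi = estimate_dispersions(cm, md)
        assert phi["a"] == pytest.approx(1e-8)

    def test_poisson_feature_estimates_near_zero(self):
        rng = np.random.default_rng(11)
        n = 1000
        counts = rng.poisson(1000.0, size=(1, n))
        samples = [f"s{i}" for i in range(n)]
        cm = _cm(counts, ["a"], samples)
        md = self._md(samples, ["g1"] * (n // 2) + ["g2"] * (n // 2))
        phi = estimate_dispersions(cm, md, sf=pd.Series(1.0, index=samples))
        assert 0.0 <= phi["a"] <= 0.05

    def test_nb_feature_recovers_true_dispersion(self):
        rng = np.random.default_rng(7)
        n, true_phi, mean = 1000, 0.5, 1000.0
        r = 1 / true_phi
        counts = rng.negative_binomial(r, r / (r + mean), size=(1, n))
        samples = [f"s{i}" for i in range(n)]
        cm = _cm(counts, ["a"], samples)
        md = self._md(samples, ["g1"] * (n // 2) + ["g2"] * (n // 2))
        phi = estimate_dispersions(cm, md, sf=pd.Series(1.0, index=samples))
        assert 0.4 <= phi["a"] <= 0.6

    def test_single_replicate_group_rejected(self):
        samples = ["s1", "s2", "s3"]
        cm = _cm([[5, 6, 7]], ["a"], samples)
        md = self._md(samples, ["g1", "g1", "g2"])
        with pytest.raises(ValidationError, match="fewer than 2"):
            estimate_dispersions(cm, md)


def _nb_loglik(x, mean, phi):
    r = 1.0 / phi
    return stats.nbinom.logpmf(x, r, r / (r + mean)).sum()


def _lrt_oracle(a, b, phi):
    """Likelihood-ratio NB test with known dispersion: for fixed shape the
    MLE of the mean is the sample mean, so the LRT reduces to plugging in
    group and pooled means."""
    pooled = np.concatenate([a, b])
    ll1 = _nb_loglik(a, a.mean(), phi) + _nb_loglik(b, b.mean(), phi)
    ll0 = _nb_loglik(pooled, pooled.mean(), phi)
    return stats.chi2.sf(2 * (ll1 - ll0), df=1)


class TestWald:
    def test_identical_group_means_null(self):
        samples = ["a1", "a2", "b1", "b2"]
        cm = _cm([[100, 100, 100, 100]], ["f"], samples)
        md = SampleMetadata(dict(zip(samples, ["T0", "T0", "T1", "T1"])), ["T0", "T1"])
        res = nb_wald_test(cm, md, ComparisonSpec("T1", "T0"), pd.Series({"f": 0.05}))
        assert res.loc["f", "log2fc"] == 0.0
        assert res.loc["f", "pvalue"] == 1.0

    def test_strong_effect_significant_and_agrees_with_lrt(self):
        rng = np.random.default_rng(3)
        cm, md = two_group_counts(rng, n_features=1, mean=1000.0, phi=0.05, log2fc=2.0)
        res = nb_wald_test(
            cm, md, ComparisonSpec("T1", "T0"), pd.Series(0.05, index=cm.feature_ids),
            sf=pd.Series(1.0, index=cm.sample_ids),
        )
        p_wald = res["pvalue"].iloc[0]
        assert p_wald < 0.01
        a = cm.counts.iloc[0, :4].to_numpy()
        b = cm.counts.iloc[0, 4:].to_numpy()
        assert _lrt_oracle(a, b, 0.05) < 0.01

    def test_all_zero_feature_degenerate(self):
        samples = ["a1", "a2", "b1", "b2"]
        cm = _cm([[0, 0, 0, 0], [10, 10, 10, 10]], ["z", "f"], samples)
        md = SampleMetadata(dict(zip(samples, ["T0", "T0", "T1", "T1"])), ["T0", "T1"])
        res = nb_wald_test(cm, md, ComparisonSpec("T1", "T0"), pd.Series(0.05, index=["z", "f"]))
        assert res.loc["z", "fc"] == 1.0
        assert res.loc["z", "pvalue"] == 1.0
        assert bool(res.loc["z", "degenerate"])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up(self):
        # sorted: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_ties_all_equal(self):
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_definitional_oracle(self, pvals):
        def oracle(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            adj = [None] * m
            for rank_pos in range(m - 1, -1, -1):
                i = order[rank_pos]
                val = min(
                    min(1.0, len(p) * p[order[k]] / (k + 1))
                    for k in range(rank_pos, m)
                )
                adj[i] = val
            return adj

        got = benjamini_hochberg(pvals)
        assert np.allclose(got, oracle(pvals), atol=1e-12)


class TestLowCountFilter:
    def _setup(self, means_per_tp):
        # 4 time points x 2 replicates with exact per-time-point means
        samples, groups, row = [], {}, []
        for t, m in enumerate(means_per_tp):
            for r in range(2):
                s = f"P{t}_r{r}"
                samples.append(s)
                groups[s] = f"P{t}"
                row.append(int(m))
        cm = _cm([row], ["f"], samples)
        md = SampleMetadata(groups, [f"P{t}" for t in range(len(means_per_tp))])
        return cm, md

    @pytest.mark.parametrize(
        "means, kept",
        [
            ((250, 250, 250, 250), False),  # below threshold everywhere
            ((250, 250, 400, 250), True),  # one time point rescues it
            ((300, 300, 300, 300), True),  # boundary is inclusive
        ],
    )
    def test_all_time_points_rule(self, means, kept):
        cm, md = self._setup(means)
        assert ("f" in low_count_filter(cm, md)) is kept


class TestCallDifferential:
    @pytest.mark.parametrize(
        "fc, fdr, expected",
        [
            (1.79, 0.001, "ns"),
            (1.80, 0.005, "up"),
            (2.5, 0.005, "up"),
            (1 / 2.5, 0.005, "down"),
            (2.5, 0.02, "ns"),
        ],
    )
    def test_direction_rule(self, fc, fdr, expected):
        assert assign_direction(fc, fdr) == expected

    def test_direction_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        lfc = np.where(np.arange(30) < 10, 2.0, 0.0) * rng.choice([-1, 1], 30)
        cm, md = two_group_counts(rng, n_features=30, mean=1000.0, phi=0.05, log2fc=lfc)
        fwd = nb_wald_test(cm, md, ComparisonSpec("T1", "T0"), pd.Series(0.05, index=cm.feature_ids))
        md_rev = SampleMetadata(md.time_point, ["T1", "T0"])
        rev = nb_wald_test(cm, md_rev, ComparisonSpec("T0", "T1"), pd.Series(0.05, index=cm.feature_ids))
        assert np.allclose(fwd["fc"] * rev["fc"], 1.0)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)

    def test_sorted_by_fdr_then_effect(self):
        rng = np.random.default_rng(8)
        lfc = np.zeros(50)
        lfc[:5] = 2.5
        cm, md = two_group_counts(rng, n_features=50, mean=800.0, phi=0.05, log2fc=lfc)
        res = call_differential(cm, md, ComparisonSpec("T1", "T0"))
        fdr = res["fdr"].to_numpy()
        assert np.all(np.diff(fdr[~np.isnan(fdr)]) >= -1e-15)
        assert set(res.loc[res["direction"] == "up", "feature"]) == {
            f"f{i:04d}" for i in range(5)
        }

    def test_wald_statistic_monotone_in_effect_size(self):
        rng = np.random.default_rng(17)
        zs = []
        for lfc in (0.5, 1.0, 2.0, 3.0):
            cm, md = two_group_counts(
                rng, n_features=200, mean=1000.0, phi=0.05, log2fc=lfc
            )
            res = nb_wald_test(
                cm, md, ComparisonSpec("T1", "T0"), pd.Series(0.05, index=cm.feature_ids),
                sf=pd.Series(1.0, index=cm.sample_ids),
            )
            # mean |z| recovered from the two-sided p-value
            z = stats.norm.isf(res["pvalue"].clip(lower=1e-300) / 2)
            zs.append(float(np.mean(z)))
        assert zs == sorted(zs)
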