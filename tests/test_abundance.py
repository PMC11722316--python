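"""Abundance classification, group comparison and deviation analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from defensim.abundance import (
    InvestmentSizeRegression,
    MCMCConfig,
    classify_abundance,
    choose_threshold,
    compare_groups,
    deviation_pvalues,
    quadrant_classify,
)
from defensim.synth import SyntheticConfig, gen_rank_abundance


def _table(species_ranks: dict, n_samples: int = 120) -> pd.DataFrame:
    """Long rank table where each species has constant rank across samples
    (or a list of ranks cycled over samples)."""
    rows = []
    for sp, ranks in species_ranks.items():
        ranks = ranks if hasattr(ranks, "__len__") else [ranks]
        for j in range(n_samples):
            rows.append((sp, f"smp{j}", ranks[j % len(ranks)]))
    return pd.DataFrame(rows, columns=["species", "sample", "rank"])


class TestClassifyAbundance:
    def test_all_ranks_above_threshold_is_high(self):
        cls = classify_abundance(_table({"sp": 15}), Ta=10)
        assert cls.high == ["sp"]

    def test_rank_exactly_at_threshold_is_intermediate(self):
        cls = classify_abundance(_table({"sp": 10}), Ta=10)
        assert cls.high == [] and cls.low == []
        assert cls.intermediate == ["sp"]

    def test_sparse_species_excluded(self):
        cls = classify_abundance(_table({"sp": 15}, n_samples=99), Ta=10)
        assert cls.excluded == ["sp"] and cls.high == []

    def test_low_classification_uses_third_quartile(self):
        cls = classify_abundance(_table({"sp": [1, 2, 3, 4]}), Ta=10)
        assert cls.low == ["sp"]

    def test_monotone_in_threshold(self):
        # raising Ta can only move species toward "low", never low -> high
        rng = np.random.default_rng(7)
        ranks = {f"sp{k}": list(rng.integers(1, 40, size=8)) for k in range(30)}
        table = _table(ranks, n_samples=104)
        prev_high, prev_low = None, None
        for ta in range(1, 41):
            cls = classify_abundance(table, ta)
            if prev_high is not None:
                assert set(cls.high) <= prev_high
                assert set(prev_low) <= set(cls.low)
            prev_high, prev_low = set(cls.high), cls.low

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classify_abundance(pd.DataFrame(columns=["species", "sample", "rank"]),
                               Ta=5)


class TestChooseThreshold:
    def test_planted_separation_recovered(self):
        cfg = SyntheticConfig(seed=5, n_ranked_species=60, n_high=15, n_low=15,
                              n_samples=150, class_separation=6.0)
        table, truth = gen_rank_abundance(cfg, return_truth=True)
        genomes = set(table["species"])
        ta = choose_threshold(table, genomes, range(1, 61))
        cls = classify_abundance(table, ta)
        assert set(truth["high"]) <= set(cls.high)
        assert set(truth["low"]) <= set(cls.low)
        # exhaustive-scan oracle over the full range
        def score(t):
            c = classify_abundance(table, t)
            return min(len(genomes & set(c.high)), len(genomes & set(c.low)))
        best = max(score(t) for t in range(1, 61))
        assert score(ta) == best

    def test_tie_breaks_to_smallest(self):
        table = _table({"sp": 5})  # single species: min group always 0
        assert choose_threshold(table, {"sp"}, range(3, 10)) == 3


def _exact_mw_p(x, y):
    """Enumerate all rank arrangements for the exact two-sided p."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    mu = n1 * (n - n1) / 2
    return np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-9)


class TestCompareGroups:
    def test_separated_groups_maximal_u(self):
        u, p = compare_groups([4, 5, 6], [1, 2, 3])
        assert u == 9.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            u, p = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0 and u == 2.0

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 7):
            for n2 in range(1, 9 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                _, p = compare_groups(x, y)
                assert p == pytest.approx(_exact_mw_p(x, y), abs=1e-10)

    def test_type_one_calibration(self):
        # same-distribution groups: p approximately uniform
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(400):
            _, p = compare_groups(rng.normal(size=12), rng.normal(size=12))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSizeRegression:
    def test_noiseless_collinear_identified(self):
        x = np.linspace(2e6, 6e6, 60)
        y = 1e-3 + 2e-10 * x
        res = InvestmentSizeRegression(y + 1e-9 * np.random.default_rng(0).normal(size=60),
                                       x).fit(MCMCConfig(seed=1))
        assert res.slope.mean() == pytest.approx(2e-10, rel=0.05)
        assert res.sigma.mean() < 1e-7

    def test_posterior_matches_ols_and_recovers_slope(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.lognormal(np.log(3.5e6), 0.3, size=n)
        b0, b1, sig = 2e-3, 4e-10, 8e-4
        y = b0 + b1 * x + rng.normal(0, sig, size=n)
        res = InvestmentSizeRegression(y, x).fit(MCMCConfig(seed=2))
        ols = np.polyfit(x, y, 1)
        assert res.slope.mean() == pytest.approx(ols[0], abs=3 * res.slope.std())
        assert abs(res.slope.mean() - b1) < 3 * res.slope.std()
        assert res.rhat.max() < 1.1

    def test_zero_slope_credible_interval_covers(self):
        rng = np.random.default_rng(21)
        hits = 0
        for k in range(10):
            x = rng.lognormal(np.log(3.5e6), 0.3, size=300)
            y = 1e-3 + rng.normal(0, 5e-4, size=300)
            res = InvestmentSizeRegression(y, x).fit(
                MCMCConfig(seed=100 + k, n_iterations=4000, burn_in=1000)
            )
            lo, hi = np.percentile(res.slope, [2.5, 97.5])
            hits += lo <= 0 <= hi
        assert hits >= 9

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            InvestmentSizeRegression([1, 2, 3], [1, 2, 3])


@pytest.fixture(scope="module")
def fitted_posterior():
    rng = np.random.default_rng(17)
    x = rng.lognormal(np.log(3.5e6), 0.3, size=1500)
    y = 1e-3 + 3e-10 * x + rng.normal(0, 6e-4, size=1500)
    res = InvestmentSizeRegression(y, x).fit(MCMCConfig(seed=4))
    return res, x, y


class TestDeviation:
    def test_seed_reproducible(self, fitted_posterior):
        post, x, _ = fitted_posterior
        kw = dict(sizes_high=x[:40], sizes_low=x[40:80],
                  observed_mean_high=2.5e-3, observed_mean_low=2.0e-3,
                  n_ensembles=2000, seed=9)
        d1 = deviation_pvalues(post, **kw)
        d2 = deviation_pvalues(post, **kw)
        assert d1.p_high == d2.p_high and d1.p_low == d2.p_low

    def test_floor_when_observed_exceeds_all(self, fitted_posterior):
        post, x, _ = fitted_posterior
        dev = deviation_pvalues(post, x[:40], x[40:80], 1.0, 1.0,
                                n_ensembles=2000, seed=0)
        assert dev.p_high == pytest.approx(1 / 2000)
        assert dev.sign_high == "+"
        assert dev.signed_log_p_high == pytest.approx(np.log10(2000))

    def test_median_observation_near_half(self, fitted_posterior):
        post, x, _ = fitted_posterior
        probe = deviation_pvalues(post, x[:60], x[60:120], 0.0, 0.0,
                                  n_ensembles=4000, seed=2)
        med_h = np.median(probe.sim_means_high)
        med_l = np.median(probe.sim_means_low)
        dev = deviation_pvalues(post, x[:60], x[60:120], med_h, med_l,
                                n_ensembles=4000, seed=2)
        assert dev.p_high == pytest.approx(0.5, abs=0.03)
        assert abs(dev.signed_log_p_high) == pytest.approx(0.301, abs=0.05)

    def test_null_calibration_uniform(self, fitted_posterior):
        # observations drawn from the fitted model itself => uniform p
        post, x, _ = fitted_posterior
        rng = np.random.default_rng(33)
        ps = []
        for _ in range(150):
            b0, b1, sig = post.samples[rng.integers(post.samples.shape[0])]
            sizes = x[:40]
            obs = (b0 + b1 * sizes + rng.normal(0, sig, 40)).mean()
            dev = deviation_pvalues(post, sizes, x[40:80], obs, 0.0,
                                    n_ensembles=800, seed=int(rng.integers(2**31)))
            # one-sided folded p ~ U(0, 0.5); unfold with the sign
            ps.append(dev.p_high if dev.sign_high == "+" else 1 - dev.p_high)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestQuadrants:
    @pytest.mark.parametrize(
        "sign_low,sign_high,label",
        [
            ("+", "+", "high-high"),
            ("-", "-", "low-low"),
            ("-", "+", "low-high"),  # PCD's category: over in high-abundant
            ("+", "-", "high-low"),
        ],
    )
    def test_labels(self, fitted_posterior, sign_low, sign_high, label):
        post, x, _ = fitted_posterior
        base = deviation_pvalues(post, x[:40], x[40:80], 1.0, 1.0,
                                 n_ensembles=500, seed=1)
        base.sign_low, base.sign_high = sign_low, sign_high
        assert quadrant_classify(base) == label
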