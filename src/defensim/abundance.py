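"""Microbiome abundance classes and genome-size-conditional deviations.

Species observed across many gut metagenome samples are classified as
consistently high- or low-abundant from their within-sample abundance
*ranks* (larger rank = more abundant within the sample): a species is
high-abundant if the 1st quartile of its rank distribution across samples
exceeds an integer threshold ``Ta``, low-abundant if the 3rd quartile falls
below ``Ta``; everything else is intermediate and discarded.  The threshold
is chosen to maximize the size of the smaller of the two groups among
species with genomes available.

Group comparisons use the Mann-Whitney U test.  Because high-abundant gut
species carry systematically larger genomes, per-system investments are
additionally scored against the expectation from genome size alone: a
Bayesian linear regression (random-walk Metropolis, flat priors) of
investment on genome size is fitted to all species, and posterior-
predictive ensembles of group means yield one-sided empirical p-values,
signed log10 p-values, and a quadrant label per system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceClasses",
    "classify_abundance",
    "choose_threshold",
    "compare_groups",
    "MCMCConfig",
    "SizeRegressionResults",
    "InvestmentSizeRegression",
    "fit_size_regression",
    "DeviationResult",
    "deviation_pvalues",
    "quadrant_classify",
]


@dataclass
class AbundanceClasses:
    """Species partitioned by consistent rank abundance."""

    Ta: int
    high: list[str]
    low: list[str]
    intermediate: list[str]
    excluded: list[str]  # detected in fewer than min_samples samples


def _rank_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Long (species, sample, rank) records -> species x sample matrix."""
    if {"species", "sample", "rank"} <= set(table.columns):
        return table.pivot_table(index="species", columns="sample",
                                 values="rank", aggfunc="first")
    return table


def classify_abundance(
    table: pd.DataFrame, Ta: int, min_samples: int = 100
) -> AbundanceClasses:
    """Classify species by their across-sample rank-abundance quartiles.

    ``table`` is either a species x sample rank matrix (NaN = not
    detected) or a long frame with columns species/sample/rank.  Quartiles
    use linear interpolation; comparisons with ``Ta`` are strict both ways,
    so a species sitting exactly at the threshold is intermediate.
    """
    if int(Ta) != Ta or Ta < 1:
        raise ValueError("Ta must be an integer >= 1")
    mat = _rank_matrix(table)
    if mat.size == 0:
        raise ValueError("empty rank-abundance table")
    high, low, mid, excluded = [], [], [], []
    counts = mat.notna().sum(axis=1)
    for sp in mat.index:
        if counts[sp] < min_samples:
            excluded.append(sp)
            continue
        ranks = mat.loc[sp].dropna().to_numpy(float)
        q1, q3 = np.percentile(ranks, [25, 75])
        if q1 > Ta:
            high.append(sp)
        elif q3 < Ta:
            low.append(sp)
        else:
            mid.append(sp)
    return AbundanceClasses(Ta=int(Ta), high=high, low=low,
                            intermediate=mid, excluded=excluded)


def choose_threshold(
    table: pd.DataFrame,
    genome_set,
    Ta_range,
    min_samples: int = 100,
) -> int:
    """Integer Ta maximizing min(|high ∩ genomes|, |low ∩ genomes|);
    ties break to the smallest Ta."""
    genome_set = set(genome_set)
    best_ta, best_score = None, -1
    for ta in sorted(int(t) for t in Ta_range):
        cls = classify_abundance(table, ta, min_samples=min_samples)
        score = min(len(genome_set & set(cls.high)),
                    len(genome_set & set(cls.low)))
        if score > best_score:
            best_ta, best_score = ta, score
    if best_ta is None:
        raise ValueError("empty Ta_range")
    return best_ta


def compare_groups(high_invest, low_invest) -> tuple[float, float]:
    """Mann-Whitney U (high vs low) with two-sided p.

    Exact null distribution for small untied samples, normal approximation
    with tie correction otherwise.  All-tied input returns p = 1.
    """
    x = np.asarray(high_invest, float)
    y = np.asarray(low_invest, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        import warnings

        warnings.warn("all observations tied; p-value is 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "asymptotic" if (has_ties or x.size + y.size > 20) else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Bayesian regression of investment on genome size


@dataclass
class MCMCConfig:
    """Random-walk Metropolis settings for the size regression."""

    seed: int = 0
    n_chains: int = 4
    n_iterations: int = 10_000
    burn_in: int = 2_000
    rhat_threshold: float = 1.1


@dataclass
class SizeRegressionResults:
    """Posterior samples for investment ~ intercept + slope * genome_size."""

    samples: np.ndarray  # (n_draws, 3): intercept, slope, sigma
    rhat: np.ndarray
    acceptance: float
    x_scale: float
    x_center: float

    @property
    def intercept(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def slope(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def sigma(self) -> np.ndarray:
        return self.samples[:, 2]

    def summary(self) -> str:
        names = ["intercept", "slope", "sigma"]
        lines = [
            "Bayesian linear regression: investment ~ genome size",
            "=" * 58,
            f"{'param':<10}{'mean':>14}{'sd':>14}{'2.5%':>14}{'97.5%':>14}",
        ]
        for k, name in enumerate(names):
            s = self.samples[:, k]
            lo, hi = np.percentile(s, [2.5, 97.5])
            lines.append(
                f"{name:<10}{s.mean():>14.6g}{s.std():>14.6g}{lo:>14.6g}{hi:>14.6g}"
            )
        lines.append(
            f"draws: {self.samples.shape[0]}   split-Rhat max: "
            f"{self.rhat.max():.4f}   acceptance: {self.acceptance:.2f}"
        )
        return "\n".join(lines)

    def predictive_means(self, rng: np.random.Generator, sizes: np.ndarray,
                         n_ensembles: int) -> np.ndarray:
        """Posterior-predictive group means at the given genome sizes."""
        idx = rng.integers(self.samples.shape[0], size=n_ensembles)
        draws = self.samples[idx]
        means = np.empty(n_ensembles)
        m = sizes.size
        for k in range(n_ensembles):
            b0, b1, sig = draws[k]
            sim = b0 + b1 * sizes + rng.normal(0.0, sig, size=m)
            means[k] = sim.mean()
        return means


class InvestmentSizeRegression:
    """Gaussian linear model of per-species investment on genome size,
    sampled by random-walk Metropolis with flat (improper) priors."""

    def __init__(self, investment, genome_size):
        y = np.asarray(investment, float)
        x = np.asarray(genome_size, float)
        if y.size != x.size:
            raise ValueError("investment and genome_size lengths differ")
        if y.size < 10:
            raise ValueError("need at least 10 species")
        self.y = y
        self.x = x

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, invest_col: str = "I_PCD",
                       size_col: str = "genome_length"):
        return cls(frame[invest_col], frame[size_col])

    def fit(self, config: MCMCConfig | None = None) -> SizeRegressionResults:
        cfg = config or MCMCConfig()
        rng = np.random.default_rng(cfg.seed)
        x, y = self.x, self.y
        n = x.size
        # center/scale x internally for a well-conditioned sampler
        xc, xs = x.mean(), x.std() or 1.0
        z = (x - xc) / xs
        # OLS initialisation and proposal scales
        A = np.column_stack([np.ones(n), z])
        coef, res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        s2 = float(resid @ resid) / max(n - 2, 1)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(A.T @ A)))
        log_s = 0.5 * math.log(s2)
        prop = np.array([se[0], se[1], 1.0 / math.sqrt(2.0 * n)]) * 2.4

        def logpost(theta):
            b0, b1, ls = theta
            sig2 = np.exp(2.0 * ls)
            r = y - b0 - b1 * z
            # flat priors on (b0, b1, sigma): Jacobian of log-sigma is +ls
            return -0.5 * n * np.log(2 * np.pi * sig2) - (r @ r) / (2 * sig2) + ls

        keep = cfg.n_iterations - cfg.burn_in
        chains = np.empty((cfg.n_chains, keep, 3))
        accepted = 0
        for c in range(cfg.n_chains):
            theta = np.array([coef[0], coef[1], log_s]) + prop * rng.normal(size=3)
            lp = logpost(theta)
            steps = rng.normal(size=(cfg.n_iterations, 3)) * prop
            unif = np.log(rng.random(cfg.n_iterations))
            for it in range(cfg.n_iterations):
                cand = theta + steps[it]
                lp_cand = logpost(cand)
                if lp_cand - lp > unif[it]:
                    theta, lp = cand, lp_cand
                    accepted += 1
                if it >= cfg.burn_in:
                    chains[c, it - cfg.burn_in] = theta
        rhat = _split_rhat(chains)
        if np.any(rhat > cfg.rhat_threshold):
            raise RuntimeError(
                f"MCMC failed to converge: split-Rhat={rhat} "
                f"(threshold {cfg.rhat_threshold})"
            )
        flat = chains.reshape(-1, 3)
        samples = np.column_stack(
            [flat[:, 0] - flat[:, 1] * xc / xs, flat[:, 1] / xs,
             np.exp(flat[:, 2])]
        )
        return SizeRegressionResults(
            samples=samples,
            rhat=rhat,
            acceptance=accepted / (cfg.n_chains * cfg.n_iterations),
            x_scale=xs,
            x_center=xc,
        )


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter for chains shaped (n_chains, n_keep, dim)."""
    c, n, d = chains.shape
    half = n // 2
    splits = chains[:, : 2 * half].reshape(2 * c, half, d)
    means = splits.mean(axis=1)
    vars_ = splits.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    return np.sqrt(var_hat / W)


def fit_size_regression(investment, genome_size,
                        mcmc_config: MCMCConfig | None = None
                        ) -> SizeRegressionResults:
    """Convenience wrapper around :class:`InvestmentSizeRegression`."""
    return InvestmentSizeRegression(investment, genome_size).fit(mcmc_config)


# ---------------------------------------------------------------------------
# Deviation from genome-size expectation


@dataclass
class DeviationResult:
    """Posterior-predictive deviation of group-mean investments."""

    observed_mean_high: float
    observed_mean_low: float
    p_high: float
    p_low: float
    sign_high: str  # '+': overinvested relative to size expectation
    sign_low: str
    signed_log_p_high: float
    signed_log_p_low: float
    p_diff: float
    sign_diff: str
    quadrant: str = ""
    sim_means_high: np.ndarray = field(default_factory=lambda: np.empty(0))
    sim_means_low: np.ndarray = field(default_factory=lambda: np.empty(0))


def _one_sided(sim: np.ndarray, obs: float, n: int) -> tuple[float, str]:
    """Empirical one-sided p in the direction of the observed deviation,
    floored at 1/n."""
    p_ge = np.count_nonzero(sim >= obs) / n
    p_le = np.count_nonzero(sim <= obs) / n
    if p_ge <= p_le:
        return max(p_ge, 1.0 / n), "+"
    return max(p_le, 1.0 / n), "-"


def deviation_pvalues(
    posterior: SizeRegressionResults,
    sizes_high,
    sizes_low,
    observed_mean_high: float,
    observed_mean_low: float,
    n_ensembles: int = 10_000,
    seed: int = 0,
) -> DeviationResult:
    """Compare observed group-mean investments with posterior-predictive
    ensembles simulated at the groups' genome sizes.

    Each of ``n_ensembles`` draws one posterior sample, simulates
    investments at every genome size in each group, and records the group
    means and their difference (high minus low).  One-sided p-values follow
    the direction of the observed deviation (floor 1/n_ensembles); signed
    log p is -log10(p) for positive deviations and +log10(p) for negative.
    """
    if n_ensembles < 100:
        import warnings

        warnings.warn("fewer than 100 ensembles gives unstable p-values")
    sizes_high = np.asarray(sizes_high, float)
    sizes_low = np.asarray(sizes_low, float)
    if sizes_high.size == 0 or sizes_low.size == 0:
        raise ValueError("both groups need at least one genome size")
    rng = np.random.default_rng(seed)
    sim_h = posterior.predictive_means(rng, sizes_high, n_ensembles)
    sim_l = posterior.predictive_means(rng, sizes_low, n_ensembles)
    p_h, s_h = _one_sided(sim_h, observed_mean_high, n_ensembles)
    p_l, s_l = _one_sided(sim_l, observed_mean_low, n_ensembles)
    obs_diff = observed_mean_high - observed_mean_low
    p_d, s_d = _one_sided(sim_h - sim_l, obs_diff, n_ensembles)
    res = DeviationResult(
        observed_mean_high=float(observed_mean_high),
        observed_mean_low=float(observed_mean_low),
        p_high=p_h,
        p_low=p_l,
        sign_high=s_h,
        sign_low=s_l,
        signed_log_p_high=_signed_log(p_h, s_h),
        signed_log_p_low=_signed_log(p_l, s_l),
        p_diff=p_d,
        sign_diff=s_d,
        sim_means_high=sim_h,
        sim_means_low=sim_l,
    )
    res.quadrant = quadrant_classify(res)
    return res


def _signed_log(p: float, sign: str) -> float:
    lp = np.log10(p)
    return float(-lp if sign == "+" else lp)


def quadrant_classify(dev: DeviationResult, significance: float = 0.05) -> str:
    """Quadrant label as (status in low-abundant, status in high-abundant).

    ``high`` = overinvested relative to the genome-size expectation,
    ``low`` = underinvested; e.g. ``low-high`` means underinvested among
    low-abundant species and overinvested among high-abundant ones.
    ``significance`` is informational (see :attr:`DeviationResult.p_high` /
    ``p_low`` for whether either deviation is individually significant).
    """
    lab = {"+": "high", "-": "low"}
    return f"{lab[dev.sign_low]}-{lab[dev.sign_high]}"
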