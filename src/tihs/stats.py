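"""Statistical validation suite for composite-vs-single-metric benchmarking.

Covers the exact paired McNemar test on discordant prediction pairs, exact
one-sided binomial tests, bootstrap confidence intervals for directional
accuracy, permutation null tests on drug ranks, top-decile enrichment, and
χ² tests on metric-weight distributions.

All Monte-Carlo operations take an explicit seed and are bit-reproducible;
permutation p-values use the add-one estimator (1 + b) / (m + 1), which can
never return zero and keeps the test valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .hubness import WeightVector

log = logging.getLogger("tihs")


@dataclass(frozen=True)
class PairedPredictionTable:
    """2×2 paired-prediction counts for two scoring methods.

    n11 both correct, n10 composite-only correct, n01 single-only correct,
    n00 both wrong.
    """
    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class RankRecord:
    """A validated drug's observed rank among N candidates."""
    rank_obs: int
    n_cand: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank_obs <= self.n_cand:
            raise ValueError("need 1 <= rank_obs <= n_cand")

    @property
    def direct_p(self) -> float:
        return self.rank_obs / self.n_cand


def mcnemar_exact_one_sided(t: PairedPredictionTable) -> float:
    """Exact one-sided McNemar test on the discordant pairs.

    Under H0 each discordant pair is equally likely to favour either method;
    the alternative is that the composite wins more often.  Returns the
    binomial upper tail p = Σ_{k=n10}^{n} C(n,k) (1/2)^n with n = n10 + n01.
    With n01 = 0 this is exactly 0.5**n10.
    """
    n = t.n10 + t.n01
    if n == 0:
        raise ValueError("McNemar test undefined with zero discordant pairs")
    return float(sps.binom.sf(t.n10 - 1, n, 0.5))


def binomial_one_sided(successes: int, trials: int, p0: float) -> float:
    """Exact one-sided (greater) binomial tail P(X >= successes | n, p0)."""
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(sps.binom.sf(successes - 1, trials, p0))


def bootstrap_accuracy_ci(outcomes,
                          iterations: int = 10_000,
                          seed: int | None = None,
                          level: float = 0.95) -> tuple[float, float, float]:
    """Percentile bootstrap CI for a proportion of 0/1 outcomes.

    Resamples the outcome vector with replacement at full length
    ``iterations`` times and returns (point estimate, lower, upper) at the
    requested confidence level.  Deterministic for a fixed seed.
    """
    x = np.asarray(outcomes, dtype=float)
    if x.size == 0:
        raise ValueError("outcomes must be nonempty")
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(iterations, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)


def permutation_rank_pvalue(r: RankRecord,
                            iterations: int = 10_000,
                            seed: int | None = None) -> float:
    """Permutation p-value of an observed rank against a uniform-rank null.

    Compares the direct p-value rank_obs/N_cand with ``iterations`` uniform
    draws on [0, 1]; p = (1 + #{u_i <= direct_p}) / (iterations + 1).
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    rng = np.random.default_rng(seed)
    u = rng.random(iterations)
    return float((1 + int(np.sum(u <= r.direct_p))) / (iterations + 1))


def topdecile_enrichment(hits: int,
                         total: int,
                         fraction: float = 0.10,
                         method: str = "exact_binomial",
                         iterations: int = 10_000,
                         seed: int | None = None) -> float:
    """Enrichment of validated drugs in the top rank fraction.

    ``exact_binomial`` returns the closed-form upper binomial tail
    P(X >= hits | total, fraction).  ``permutation`` simulates ``total``
    uniform rank fractions per iteration, counts iterations achieving at
    least ``hits`` in the top ``fraction``, and returns the add-one
    estimate (1 + exceed) / (iterations + 1).
    """
    if not 0 <= hits <= total:
        raise ValueError("need 0 <= hits <= total")
    if method == "exact_binomial":
        if hits == 0:
            return 1.0
        return binomial_one_sided(hits, total, fraction)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        draws = rng.random((iterations, total))
        exceed = int(np.sum((draws <= fraction).sum(axis=1) >= hits))
        return float((1 + exceed) / (iterations + 1))
    raise ValueError(f"unknown method {method!r}")


def chisq_weight_gof(w: WeightVector,
                     pseudo_n: int) -> tuple[float, int, float]:
    """χ² goodness-of-fit of a weight vector against the uniform null.

    Weights are converted to pseudo-counts O_j = w_j · pseudo_n and compared
    with E_j = pseudo_n / k (the 0.2 null for five metrics); df = k − 1.
    The statistic scales linearly with ``pseudo_n``, which has no principled
    value for proportions — it is reported alongside the statistic and
    results should be read as descriptive.
    """
    k = len(w.weights)
    if pseudo_n < 5 * k:
        log.warning("chisq_weight_gof: pseudo_n=%d gives expected counts "
                    "below 5 — χ² approximation unreliable", pseudo_n)
    observed = np.array(list(w.weights.values())) * pseudo_n
    expected = np.full(k, pseudo_n / k)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = k - 1
    return stat, df, float(sps.chi2.sf(stat, df))


def chisq_homogeneity(weight_matrix,
                      pseudo_n: int) -> tuple[float, int, float]:
    """χ² homogeneity test across dataset-specific weight distributions.

    ``weight_matrix`` is datasets × metrics proportions (rows sum to 1);
    each row is scaled to ``pseudo_n`` pseudo-counts and a standard
    contingency χ² computed, df = (rows − 1)(cols − 1).
    """
    m = np.asarray(weight_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 dataset rows")
    counts = m * pseudo_n
    if np.allclose(counts, counts[0]):
        df = (m.shape[0] - 1) * (m.shape[1] - 1)
        return 0.0, df, 1.0
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def directional_accuracy(pairs) -> tuple[int, int]:
    """Count correct directional predictions among validation pairs.

    A pair is correct when predicted_effect equals actual_effect;
    ``not_observed`` predictions count as incorrect.  Returns
    (n_correct, n_total).
    """
    pairs = list(pairs)
    correct = sum(1 for p in pairs if p.predicted_effect == p.actual_effect)
    return correct, len(pairs)


def fold_difference(a: float, b: float) -> float:
    """Ratio of two positive readouts (e.g. IC50s), larger over smaller."""
    if a <= 0 or b <= 0:
        raise ValueError("fold difference needs positive values")
    return max(a, b) / min(a, b)
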