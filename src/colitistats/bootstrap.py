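"""Bootstrap hypothesis test for the absolute difference in group means.

The test statistic is ``|mean(a) - mean(b)|``.  A bootstrap null
distribution is built by drawing, for each iteration, a resample of size
``len(a)`` and one of size ``len(b)`` with replacement; the p-value is the
fraction of resampled statistics greater than or equal to the observed
one,

    p = #{stat_i >= observed, i = 1..B} / B

with the comparison inclusive and no (B+1) smoothing, so the minimum
attainable p is 0.

Two resampling strategies are provided.  ``"pooled"`` (default) draws both
resamples from the combined sample, which imposes the null hypothesis of
no group difference and makes the procedure a valid test; ``"per_group"``
resamples each group from itself, which measures the sampling variability
of the statistic rather than its null distribution, and is kept for
comparison because published descriptions of this test are often ambiguous
on the point.

An exact enumeration oracle (:func:`exact_p_oracle`) computes the same
pooled-null probability by enumerating every equally likely resample pair;
it is feasible only for small samples and exists to verify the Monte Carlo
estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

DEFAULT_ITERATIONS = 10_000

#: relative tolerance used when comparing resampled statistics with the
#: observed one, so mathematically tied values are not dropped by last-ulp
#: floating-point noise.  The comparison stays inclusive (>=).
TIE_RTOL = 1e-9

_STRATEGIES = ("pooled", "per_group")


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of one bootstrap hypothesis test."""

    observed_test_stat: float
    n_iterations: int
    p_bootstrap: float
    seed: int | None
    strategy: str = "pooled"
    bootstrap_stats_summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bootstrap <= 1.0:
            raise ValueError("p_bootstrap must be in [0, 1]")
        if self.observed_test_stat < 0:
            raise ValueError("observed_test_stat must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "observed_test_stat": self.observed_test_stat,
            "n_iterations": self.n_iterations,
            "p_bootstrap": self.p_bootstrap,
            "seed": self.seed,
            "strategy": self.strategy,
            "bootstrap_stats_summary": dict(self.bootstrap_stats_summary),
        }


def _as_sample(x, name: str, min_size: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_size:
        raise ValueError(f"sample {name} needs >= {min_size} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def observed_stat(group_a, group_b) -> float:
    """Absolute difference in sample means, ``|mean(a) - mean(b)|``."""
    a = _as_sample(group_a, "a", 1)
    b = _as_sample(group_b, "b", 1)
    return abs(float(a.mean()) - float(b.mean()))


def p_from_stats(bootstrap_stats, observed: float) -> float:
    """P value from a vector of bootstrap statistics.

    Counts the statistics greater than or equal to ``observed`` (within
    :data:`TIE_RTOL` so exact ties are kept) and divides by their number.
    """
    stats = np.asarray(bootstrap_stats, dtype=float).ravel()
    if stats.size < 1:
        raise ValueError("need at least one bootstrap statistic")
    if observed < 0:
        raise ValueError("observed statistic must be >= 0")
    threshold = observed - TIE_RTOL * (1.0 + observed)
    return float(np.count_nonzero(stats >= threshold)) / stats.size


def bootstrap_p(
    group_a,
    group_b,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    strategy: str = "pooled",
) -> BootstrapResult:
    """Bootstrap test of no difference in means between two groups.

    Parameters
    ----------
    group_a, group_b
        Samples of at least 2 finite values each.
    n_iterations
        Number of bootstrap resamples (default 10,000).
    seed
        Seed for the resampling RNG; identical inputs and seed give an
        identical result.
    strategy
        ``"pooled"`` (null-imposing, default) or ``"per_group"``.

    Returns
    -------
    BootstrapResult
        With the observed statistic, ``p_bootstrap`` and quantiles of the
        resampled statistics.
    """
    a = _as_sample(group_a, "a", 2)
    b = _as_sample(group_b, "b", 2)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if strategy not in _STRATEGIES:
        raise ValueError(f"strategy must be one of {_STRATEGIES}, got {strategy!r}")

    obs = abs(float(a.mean()) - float(b.mean()))
    rng = np.random.default_rng(seed)

    if strategy == "pooled":
        pool = np.concatenate([a, b])
        idx = rng.integers(0, pool.size, size=(n_iterations, a.size + b.size))
        draws = pool[idx]
        means_a = draws[:, : a.size].mean(axis=1)
        means_b = draws[:, a.size :].mean(axis=1)
    else:
        idx_a = rng.integers(0, a.size, size=(n_iterations, a.size))
        idx_b = rng.integers(0, b.size, size=(n_iterations, b.size))
        means_a = a[idx_a].mean(axis=1)
        means_b = b[idx_b].mean(axis=1)

    stats = np.abs(means_a - means_b)
    quantiles = np.quantile(stats, [0.025, 0.25, 0.5, 0.75, 0.975])
    return BootstrapResult(
        observed_test_stat=obs,
        n_iterations=int(n_iterations),
        p_bootstrap=p_from_stats(stats, obs),
        seed=seed,
        strategy=strategy,
        bootstrap_stats_summary={
            "q2.5": float(quantiles[0]),
            "q25": float(quantiles[1]),
            "median": float(quantiles[2]),
            "q75": float(quantiles[3]),
            "q97.5": float(quantiles[4]),
        },
    )


def _mean_distribution(pool: np.ndarray, k: int) -> Counter:
    """Counter mapping resample sum -> number of index tuples producing it.

    Built by convolving the pool's value multiset k times; sums are kept
    (not means) so integer inputs stay exact.
    """
    base = Counter(float(v) for v in pool)
    dist = Counter({0.0: 1})
    for _ in range(k):
        nxt: Counter = Counter()
        for s, c in dist.items():
            for v, m in base.items():
                nxt[s + v] += c * m
        dist = nxt
    return dist


def exact_p_oracle(group_a, group_b, max_outcomes: float = 1e7) -> float:
    """Exact pooled-null probability by full enumeration.

    Enumerates every equally likely pair of with-replacement resamples
    from the pooled sample (``N**(na+nb)`` outcomes, ``N = na + nb``) and
    returns the exact fraction whose absolute difference in means is
    greater than or equal to the observed statistic.  Serves as ground
    truth for :func:`bootstrap_p` on small instances.
    """
    a = _as_sample(group_a, "a", 1)
    b = _as_sample(group_b, "b", 1)
    n = a.size + b.size
    total_outcomes = float(n) ** n
    if total_outcomes > max_outcomes:
        raise ValueError(
            f"instance too large for exact enumeration: {n}**{n} = "
            f"{total_outcomes:.3g} outcomes exceeds the bound {max_outcomes:.3g}"
        )
    obs = abs(float(a.mean()) - float(b.mean()))
    pool = np.concatenate([a, b])

    dist_a = _mean_distribution(pool, a.size)
    dist_b = _mean_distribution(pool, b.size)
    threshold = obs - TIE_RTOL * (1.0 + obs)

    hits = 0
    for sa, ca in dist_a.items():
        ma = sa / a.size
        for sb, cb in dist_b.items():
            if abs(ma - sb / b.size) >= threshold:
                hits += ca * cb
    return hits / (n ** a.size * n ** b.size)
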