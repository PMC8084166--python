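"""Gene-level overlap test for parallel evolution between two transects.

The null model draws two independent gene sets of the observed sizes
uniformly without replacement from the genome-wide gene universe and
records their intersection size.  The exceedance p-value uses the
``(count + 1) / (n_perm + 1)`` convention with a Wilson 95% confidence
interval, and the exact hypergeometric distribution of the intersection
serves as the analytic oracle (mean ``nA * nB / G``; upper tail from the
hypergeometric survival function).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class OverlapTest:
    """Result record of one permutation overlap test."""

    n_universe: int
    n_set_a: int
    n_set_b: int
    observed: int | None
    n_perm: int
    expected_perm: float
    p_perm: float | None
    p_ci: tuple[float, float] | None
    hyper_mean: float
    hyper_tail_p: float | None
    seed: int
    replicates: np.ndarray = field(default_factory=lambda: np.array([], dtype=int),
                                   repr=False)

    def to_json(self, path: str | None = None) -> str:
        obj = {
            k: v
            for k, v in vars(self).items()
            if k != "replicates"
        }
        if obj["p_ci"] is not None:
            obj["p_ci"] = list(obj["p_ci"])
        text = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def observed_overlap(genes_a, genes_b, universe=None) -> int:
    """Size of the intersection of two outlier gene sets.

    If a universe is supplied, ids outside it raise an error naming the
    offenders.
    """
    a, b = set(genes_a), set(genes_b)
    if universe is not None:
        uni = set(universe)
        bad = sorted((a | b) - uni)
        if bad:
            raise ValueError(f"gene ids outside the declared universe: {bad[:10]}")
    return len(a & b)


def hypergeometric_oracle(
    n_a: int, n_b: int, universe_size: int, observed: int | None = None
) -> tuple[float, float | None]:
    """Exact mean and upper-tail probability of the null intersection size.

    The intersection of two independent uniform subsets of sizes ``n_a``
    and ``n_b`` is ``Hypergeometric(G, n_a, n_b)``; the mean is
    ``n_a * n_b / G`` and the tail is ``P(X >= observed)``.
    """
    _check_sizes(n_a, n_b, universe_size, observed)
    mean = n_a * n_b / universe_size
    tail = None
    if observed is not None:
        tail = float(stats.hypergeom.sf(observed - 1, universe_size, n_a, n_b))
    return mean, tail


def pvalue_ci(exceed_count: int, n_perm: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval on the exceedance proportion
    ``(exceed_count + 1) / (n_perm + 1)``."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if not 0 <= exceed_count <= n_perm:
        raise ValueError("exceed_count must lie in [0, n_perm]")
    lo, hi = proportion_confint(
        exceed_count + 1, n_perm + 1, alpha=1.0 - level, method="wilson"
    )
    return float(lo), float(hi)


def permutation_overlap_test(
    n_a: int,
    n_b: int,
    universe_size: int,
    observed: int | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> OverlapTest:
    """Monte-Carlo null distribution of the gene-set overlap.

    Each replicate draws a size-``n_a`` subset and an independent
    size-``n_b`` subset, both uniformly without replacement from the
    universe, and records the intersection size.  ``p_perm`` is
    ``(#{overlap >= observed} + 1) / (n_perm + 1)``.
    """
    _check_sizes(n_a, n_b, universe_size, observed)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int32)
    mask = np.zeros(universe_size, dtype=bool)
    for r in range(n_perm):
        set_a = np.argpartition(rng.random(universe_size), n_a - 1)[:n_a]
        set_b = np.argpartition(rng.random(universe_size), n_b - 1)[:n_b]
        mask[set_a] = True
        counts[r] = int(mask[set_b].sum())
        mask[set_a] = False
    expected = float(counts.mean())
    hyper_mean, hyper_tail = hypergeometric_oracle(n_a, n_b, universe_size, observed)
    p_perm = ci = None
    if observed is not None:
        exceed = int((counts >= observed).sum())
        p_perm = (exceed + 1) / (n_perm + 1)
        ci = pvalue_ci(exceed, n_perm)
    return OverlapTest(
        n_universe=universe_size,
        n_set_a=n_a,
        n_set_b=n_b,
        observed=observed,
        n_perm=n_perm,
        expected_perm=expected,
        p_perm=p_perm,
        p_ci=ci,
        hyper_mean=hyper_mean,
        hyper_tail_p=hyper_tail,
        seed=seed,
        replicates=counts,
    )


def _check_sizes(n_a, n_b, universe_size, observed) -> None:
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set sizes cannot exceed the universe size")
    if min(n_a, n_b, universe_size) < 0:
        raise ValueError("sizes must be nonnegative")
    if observed is not None and not 0 <= observed <= min(n_a, n_b):
        raise ValueError("observed overlap must lie in [0, min(n_a, n_b)]")
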