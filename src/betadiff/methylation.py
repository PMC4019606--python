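"""Beta posteriors for per-position methylation levels and their comparison.

A bisulfite experiment covering one genomic position in one sample yields k
non-converted reads (evidence of methylation) out of n total.  With the
methylation level p given a uniform Beta(1,1) prior, the posterior is
Beta(k+1, n-k+1).  Comparing two samples at the same position then reduces to
the exact Beta inequality P(p1 > p2) computed by :mod:`betadiff.core_beta`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_beta import BetaParams, prob_beta_greater, prob_beta_greater_quadrature

__all__ = [
    "SampleCounts",
    "DiffResult",
    "posterior_from_counts",
    "posterior_moments",
    "diff_methylation",
    "filter_by_variance",
]

#: Uniform prior: one pseudo-count for each of the non-converted and
#: converted states.
UNIFORM_PRIOR = (1.0, 1.0)


@dataclass(frozen=True)
class SampleCounts:
    """Read counts at one position for one sample.

    ``non_converted`` reads support methylation; ``converted`` reads support
    non-methylation.  Zero depth is valid (the posterior is then the prior).
    """

    non_converted: int
    converted: int

    def __post_init__(self) -> None:
        for name in ("non_converted", "converted"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def depth(self) -> int:
        return int(self.non_converted + self.converted)


@dataclass(frozen=True)
class DiffResult:
    """P(p1 > p2) plus the posterior moments of both samples at one position."""

    prob_greater: float
    mean1: float
    mean2: float
    var1: float
    var2: float


def posterior_from_counts(
    counts: SampleCounts, prior: tuple[float, float] = UNIFORM_PRIOR
) -> BetaParams:
    """Posterior Beta(k + prior_nc, n - k + prior_c) of the methylation level.

    With the default uniform prior this is Beta(k+1, n-k+1).
    """
    return BetaParams(counts.non_converted + prior[0], counts.converted + prior[1])


def posterior_moments(params: BetaParams) -> tuple[float, float]:
    """Closed-form (mean, variance) of a Beta distribution.

    mean = a/(a+b); variance = ab / ((a+b)^2 (a+b+1)).
    """
    return params.mean, params.variance


def diff_methylation(
    counts1: SampleCounts,
    counts2: SampleCounts,
    prior: tuple[float, float] = UNIFORM_PRIOR,
) -> DiffResult:
    """Exact P(p1 > p2) between the two samples' posterior methylation levels.

    Integer priors (the default) go through the exact recursive engine;
    non-integer pseudo-counts fall back to the quadrature oracle.
    """
    post1 = posterior_from_counts(counts1, prior)
    post2 = posterior_from_counts(counts2, prior)
    if post1.is_integer and post2.is_integer:
        g = prob_beta_greater(post1.alpha, post1.beta, post2.alpha, post2.beta)
    else:
        g = prob_beta_greater_quadrature(
            post1.alpha, post1.beta, post2.alpha, post2.beta
        )
    m1, v1 = posterior_moments(post1)
    m2, v2 = posterior_moments(post2)
    return DiffResult(prob_greater=g, mean1=m1, mean2=m2, var1=v1, var2=v2)


def _as_result(item) -> DiffResult:
    if isinstance(item, DiffResult):
        return item
    # allow (position/key, DiffResult) pairs so positional metadata can travel
    return item[-1]


def filter_by_variance(results: Iterable, max_variance: float) -> list:
    """Keep positions whose *worse* posterior variance is below a ceiling.

    A position is only as certain as its less-covered sample, so the filter
    retains exactly the entries with max(var1, var2) <= ``max_variance``,
    preserving order.  This is the certainty filter appropriate when equal
    read depth does not mean equal uncertainty: at the same depth, extreme
    count splits give tighter posteriors than balanced ones.

    ``results`` items may be :class:`DiffResult` objects or
    ``(key, DiffResult)`` tuples.
    """
    if not (0.0 < max_variance <= 0.25):
        raise ValueError(f"max_variance must lie in (0, 1/4], got {max_variance}")
    return [
        item
        for item in results
        if max(_as_result(item).var1, _as_result(item).var2) <= max_variance
    ]
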