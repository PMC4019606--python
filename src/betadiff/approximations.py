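"""Approximate comparators: one-tailed Fisher's exact test and Z test.

Both are the standard stand-ins for the exact Beta inequality.  Fisher's test
conditions on the margins of the 2x2 read-count table and sums the
hypergeometric upper tail; the Z test moment-matches each Beta posterior with
a Gaussian and compares the two Gaussians.  Both are one-tailed with the
alternative "sample 1 more methylated", matching the g = P(p1 > p2)
convention of the exact method.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .methylation import SampleCounts, posterior_from_counts, posterior_moments

__all__ = ["ContingencyTable", "fisher_one_tailed", "z_score_test"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 read-count table: rows = samples, columns = non-converted/converted."""

    nc1: int
    c1: int
    nc2: int
    c2: int

    def __post_init__(self) -> None:
        for name in ("nc1", "c1", "nc2", "c2"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_counts(cls, counts1: SampleCounts, counts2: SampleCounts) -> "ContingencyTable":
        return cls(counts1.non_converted, counts1.converted,
                   counts2.non_converted, counts2.converted)

    @property
    def degenerate(self) -> bool:
        """True iff a row or column sum is zero — Fisher's test is then uninformative."""
        return (
            self.nc1 + self.c1 == 0
            or self.nc2 + self.c2 == 0
            or self.nc1 + self.nc2 == 0
            or self.c1 + self.c2 == 0
        )


def fisher_one_tailed(table: ContingencyTable) -> tuple[float, bool]:
    """One-tailed Fisher's exact test: P(NC1 cell >= observed | fixed margins).

    Tests enrichment of non-converted reads in sample 1 (alternative: sample 1
    more methylated).  Degenerate tables (a zero row or column sum) carry no
    information and return ``(1.0, True)`` rather than raising, so streaming
    callers can process every site.

    Returns ``(p_value, degenerate_flag)``.
    """
    if table.degenerate:
        return 1.0, True
    total = table.nc1 + table.c1 + table.nc2 + table.c2
    n_nonconverted = table.nc1 + table.nc2
    depth1 = table.nc1 + table.c1
    # upper tail includes the observed table: P(X >= nc1) = sf(nc1 - 1)
    p = float(stats.hypergeom.sf(table.nc1 - 1, total, n_nonconverted, depth1))
    return min(max(p, 0.0), 1.0), False


def z_score_test(counts1: SampleCounts, counts2: SampleCounts) -> float:
    """One-tailed Z test on moment-matched Gaussians of the Beta posteriors.

    z = (mean1 - mean2) / sqrt(var1 + var2) with the posterior Beta moments
    (counts + 1 under the uniform prior); returns the upper-tail p-value
    1 - Φ(z) for the alternative p1 > p2.  Beta posterior variances are always
    strictly positive, so z is always finite.
    """
    m1, v1 = posterior_moments(posterior_from_counts(counts1))
    m2, v2 = posterior_moments(posterior_from_counts(counts2))
    z = (m1 - m2) / (v1 + v2) ** 0.5
    return float(stats.norm.sf(z))
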