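"""Simulation benchmark: ROC comparison of the exact Beta method vs Fisher and Z.

Negative-control sites draw both samples' counts from the same binomial
process (p1 = p2 = p_null); positive sites use markedly different underlying
probabilities.  Each site pair is scored by all three methods on a common
"evidence of any difference" scale in [0, 1], and ROC curves are built by
sweeping a threshold over that scale.

Score folding
-------------
The three methods natively report on different scales (a posterior
probability g = P(p1 > p2) vs one-tailed p-values), so scores are folded to
two-sided evidence with higher = more different:

* beta_exact:  2 * |g - 1/2|
* fisher, z_score:  1 - 2 * min(p, 1 - p)  for the one-tailed p

Folding is monotone in each method's own ranking of sites, so it changes no
ROC ordering.  Degenerate Fisher tables (a zero row or column in the 2x2
table, where the test breaks down) score 0 — no evidence — which is what
drives Fisher's false-negative accumulation at low coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .approximations import ContingencyTable, fisher_one_tailed, z_score_test
from .methylation import SampleCounts, diff_methylation

__all__ = [
    "METHODS",
    "COVERAGE_GRID",
    "SimulationConfig",
    "RocTable",
    "ScoreHistogram",
    "BenchmarkResult",
    "simulate_site_pairs",
    "score_sites",
    "roc_curve",
    "run_benchmark",
    "compare_histogram2d",
    "export_roc_tsv",
    "export_histograms_tsv",
]

METHODS = ("beta_exact", "fisher", "z_score")

#: Read depths at which the benchmark is typically run: from sparse coverage,
#: where the discreteness of count data bites, to depths where all methods
#: converge.
COVERAGE_GRID = (5, 10, 20, 50)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one benchmark run.

    Defaults: null sites at p = 0.5, positives at 0.7 vs 0.3 (markedly
    different methylation levels), equal coverage in both samples, 2000 sites
    per class.
    """

    p_null: float = 0.5
    p1_alt: float = 0.7
    p2_alt: float = 0.3
    depth1: int = 20
    depth2: int = 20
    n_sites: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_null", "p1_alt", "p2_alt"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.p1_alt == self.p2_alt:
            raise ValueError("p1_alt and p2_alt must differ (positive class)")
        if self.depth1 < 1 or self.depth2 < 1:
            raise ValueError("depths must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class RocTable:
    """(threshold, FPR, TPR) triples for one scoring method."""

    method: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def auc(self) -> float:
        """Area under the ROC curve by trapezoidal integration over FPR."""
        order = np.argsort(self.fpr, kind="stable")
        return float(np.trapezoid(self.tpr[order], self.fpr[order]))

    def tpr_at_fpr(self, max_fpr: float) -> float:
        """Best TPR attainable while keeping FPR <= max_fpr."""
        ok = self.fpr <= max_fpr
        return float(self.tpr[ok].max()) if ok.any() else 0.0


@dataclass(frozen=True)
class ScoreHistogram:
    """Binned score distribution for one method and one site class."""

    method: str
    site_class: str  # "positive" or "control"
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class BenchmarkResult:
    config: SimulationConfig
    roc: dict = field(default_factory=dict)  # method -> RocTable
    scores: dict = field(default_factory=dict)  # (method, class) -> np.ndarray
    histograms: list = field(default_factory=list)  # list[ScoreHistogram]


def simulate_site_pairs(
    p1: float,
    p2: float,
    depth1: int,
    depth2: int,
    n_sites: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[SampleCounts, SampleCounts]]:
    """Draw per-site counts: non_converted ~ Binomial(depth_i, p_i) per sample.

    Converted counts are depth - non_converted.  Deterministic for a fixed
    integer seed.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of range: {p}")
    if depth1 < 1 or depth2 < 1 or n_sites < 1:
        raise ValueError("depths and n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nc1 = rng.binomial(depth1, p1, size=n_sites)
    nc2 = rng.binomial(depth2, p2, size=n_sites)
    return [
        (SampleCounts(int(k1), int(depth1 - k1)), SampleCounts(int(k2), int(depth2 - k2)))
        for k1, k2 in zip(nc1, nc2)
    ]


def score_sites(pairs, method: str) -> np.ndarray:
    """Fold each method's output into two-sided evidence of difference in [0,1].

    Higher score = more evidence that the two samples differ, uniformly
    across methods.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if not pairs:
        raise ValueError("pairs must be non-empty")
    scores = np.empty(len(pairs))
    for i, (c1, c2) in enumerate(pairs):
        if method == "beta_exact":
            g = diff_methylation(c1, c2).prob_greater
            s = 2.0 * abs(g - 0.5)
        elif method == "fisher":
            p, degenerate = fisher_one_tailed(ContingencyTable.from_counts(c1, c2))
            s = 0.0 if degenerate else 1.0 - 2.0 * min(p, 1.0 - p)
        else:  # z_score
            p = z_score_test(c1, c2)
            s = 1.0 - 2.0 * min(p, 1.0 - p)
        scores[i] = min(max(s, 0.0), 1.0)
    return scores


def roc_curve(pos_scores, neg_scores, thresholds) -> RocTable:
    """TPR/FPR at each threshold: the fraction of scores >= threshold."""
    pos = np.sort(np.asarray(pos_scores, dtype=float))
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("score lists must be non-empty")
    t = np.asarray(thresholds, dtype=float)
    tpr = 1.0 - np.searchsorted(pos, t, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, t, side="left") / neg.size
    return RocTable(method="", thresholds=t, fpr=fpr, tpr=tpr)


def _threshold_grid(*score_arrays: np.ndarray) -> np.ndarray:
    # even grid for resolution + every attained score so ROC steps are exact
    return np.union1d(np.linspace(0.0, 1.0, 512), np.concatenate(score_arrays))


def run_benchmark(config: SimulationConfig, n_hist_bins: int = 50) -> BenchmarkResult:
    """Full benchmark: simulate both classes, score by all methods, build ROCs.

    Per-class random streams are derived deterministically from the single
    master seed, so identical configs give bit-identical results.
    """
    s_pos, s_neg = (int(s) % 2**31 for s in
                    np.random.SeedSequence(config.seed).generate_state(2))
    positives = simulate_site_pairs(
        config.p1_alt, config.p2_alt, config.depth1, config.depth2,
        config.n_sites, seed=s_pos,
    )
    controls = simulate_site_pairs(
        config.p_null, config.p_null, config.depth1, config.depth2,
        config.n_sites, seed=s_neg,
    )
    roc: dict[str, RocTable] = {}
    scores: dict[tuple[str, str], np.ndarray] = {}
    histograms: list[ScoreHistogram] = []
    edges = np.linspace(0.0, 1.0, n_hist_bins + 1)
    for method in METHODS:
        pos_scores = score_sites(positives, method)
        neg_scores = score_sites(controls, method)
        scores[(method, "positive")] = pos_scores
        scores[(method, "control")] = neg_scores
        grid = _threshold_grid(pos_scores, neg_scores)
        table = roc_curve(pos_scores, neg_scores, grid)
        roc[method] = RocTable(method, table.thresholds, table.fpr, table.tpr)
        for label, arr in (("positive", pos_scores), ("control", neg_scores)):
            counts, _ = np.histogram(arr, bins=edges)
            histograms.append(ScoreHistogram(method, label, edges, counts))
    return BenchmarkResult(config=config, roc=roc, scores=scores, histograms=histograms)


def compare_histogram2d(pairs, method: str, bins: int = 50):
    """2-D histogram of the exact probability g vs a comparator's p-value.

    Orientation: x = g = P(p1 > p2) from the Beta model, y = the comparator's
    one-tailed p-value (alternative p1 > p2).  Under broad agreement the mass
    concentrates near the anti-diagonal y ≈ 1 - x.

    Returns ``(counts, g_edges, p_edges)``.
    """
    if method not in ("fisher", "z_score"):
        raise ValueError("comparator must be 'fisher' or 'z_score'")
    g = np.empty(len(pairs))
    p = np.empty(len(pairs))
    for i, (c1, c2) in enumerate(pairs):
        g[i] = diff_methylation(c1, c2).prob_greater
        if method == "fisher":
            p[i], _ = fisher_one_tailed(ContingencyTable.from_counts(c1, c2))
        else:
            p[i] = z_score_test(c1, c2)
    counts, g_edges, p_edges = np.histogram2d(g, p, bins=bins, range=[[0, 1], [0, 1]])
    return counts, g_edges, p_edges


def export_roc_tsv(result: BenchmarkResult, path) -> None:
    """Write all ROC tables as TSV with columns method, threshold, FPR, TPR."""
    frames = [
        pd.DataFrame({
            "method": table.method,
            "threshold": table.thresholds,
            "FPR": table.fpr,
            "TPR": table.tpr,
        })
        for table in result.roc.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def export_histograms_tsv(result: BenchmarkResult, path) -> None:
    """Write score histograms as TSV: method, class, bin_left, bin_right, count."""
    rows = []
    for h in result.histograms:
        for left, right, count in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
            rows.append((h.method, h.site_class, left, right, int(count)))
    pd.DataFrame(
        rows, columns=["method", "class", "bin_left", "bin_right", "count"]
    ).to_csv(path, sep="\t", index=False)
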