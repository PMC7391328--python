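"""Combining replicated plots and the method-reliability statistics.

Replicated 5 m x 5 m plots are combined into a single weighted pair
correlation function, each replicate weighted by its squared point count
(pair-count weighting, the natural weight for a second-order statistic).
The reliability protocol compares two measurements of the same plants —
e.g. photograph-derived versus ruler-measured coordinates — with paired
t tests on matched coordinates and on the per-bin g(r) values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .nullmodels import EnvelopeResult, classify_bins
from .ppcore import PointPattern, SummaryFunction

__all__ = [
    "PairedComparison",
    "combine_weighted_pcf",
    "combine_weighted_envelope",
    "match_point_sets",
    "paired_t",
    "compare_pcf",
]


@dataclass(frozen=True)
class PairedComparison:
    """Classical paired t test summary (mean difference, sd, se, t, df, p).

    ``infinite`` flags the degenerate case sd = 0 with nonzero mean, where
    the statistic is unbounded and p is reported as 0.
    """

    mean: float
    sd: float
    se: float
    t: float
    df: int
    p: float
    infinite: bool = False


def _common_grid(summaries: list[SummaryFunction]) -> None:
    g0 = summaries[0].rgrid
    for s in summaries[1:]:
        if len(s.rgrid) != len(g0) or not np.allclose(
            s.rgrid.values, g0.values, rtol=0, atol=1e-12
        ):
            raise ValueError("summary functions are on different distance grids")


def replicate_weights(counts: np.ndarray, scheme: str = "n2") -> np.ndarray:
    """Convex weights across replicates: w_i ∝ n_i^2 (default) or ∝ n_i."""
    counts = np.asarray(counts, dtype=float)
    if scheme == "n2":
        w = counts**2
    elif scheme == "n":
        w = counts
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("all replicates are empty")
    return w / total


def combine_weighted_pcf(
    summaries: list[SummaryFunction], scheme: str = "n2"
) -> SummaryFunction:
    """Weighted average of replicate pair correlation functions.

    g-bar(r) = sum_i w_i g_i(r) with w_i = n_i^2 / sum_j n_j^2; the weights
    form a convex combination, so the result lies bin-wise between the
    replicate extremes.
    """
    if not summaries:
        raise ValueError("need at least one replicate")
    _common_grid(summaries)
    w = replicate_weights(np.array([s.n for s in summaries]), scheme)
    vals = np.einsum("i,ij->j", w, np.vstack([s.values for s in summaries]))
    return SummaryFunction(
        summaries[0].statistic, summaries[0].rgrid, vals, int(sum(s.n for s in summaries))
    )


def combine_weighted_envelope(
    envelopes: list[EnvelopeResult], scheme: str = "n2"
) -> EnvelopeResult:
    """Combine replicate envelope tests with the same weights as the pcf.

    Observed curves and both envelope bounds are averaged with w_i ∝ n_i^2
    (counts taken from each replicate's observed pattern via nsim metadata),
    then the combined observed curve is re-classified against the combined
    bounds.
    """
    if not envelopes:
        raise ValueError("need at least one replicate")
    g0 = envelopes[0].rgrid
    for e in envelopes[1:]:
        if len(e.rgrid) != len(g0) or not np.allclose(
            e.rgrid.values, g0.values, rtol=0, atol=1e-12
        ):
            raise ValueError("envelopes are on different distance grids")
    counts = np.array([e.n for e in envelopes])
    w = replicate_weights(counts, scheme)
    obs = np.einsum("i,ij->j", w, np.vstack([e.observed for e in envelopes]))
    lo = np.einsum("i,ij->j", w, np.vstack([e.lower for e in envelopes]))
    hi = np.einsum("i,ij->j", w, np.vstack([e.upper for e in envelopes]))
    labels = tuple(classify_bins(obs, lo, hi))
    return EnvelopeResult(
        g0, obs, lo, hi, labels, envelopes[0].nsim, envelopes[0].spec,
        n=int(counts.sum()),
    )


def match_point_sets(
    a: PointPattern, b: PointPattern, max_dist: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair up two measurements of the same individuals.

    Greedy matching over candidate pairs within ``max_dist``, taken in
    increasing-distance order (ties broken by index), each point used at
    most once — every accepted pair is mutually nearest among the points
    still unmatched, and the result is symmetric in a and b.

    Returns (pairs, unmatched_a, unmatched_b): pairs is an (m, 2) array of
    indices into a and b.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if a.n == 0 or b.n == 0:
        return (
            np.empty((0, 2), dtype=int),
            np.arange(a.n),
            np.arange(b.n),
        )
    dist = cKDTree(a.points).sparse_distance_matrix(
        cKDTree(b.points), max_dist, output_type="ndarray"
    )
    order = np.lexsort((dist["j"], dist["i"], dist["v"]))
    used_a = np.zeros(a.n, dtype=bool)
    used_b = np.zeros(b.n, dtype=bool)
    pairs = []
    for k in order:
        i, j = int(dist["i"][k]), int(dist["j"][k])
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((i, j))
    pairs_arr = np.array(pairs, dtype=int).reshape(-1, 2)
    return pairs_arr, np.flatnonzero(~used_a), np.flatnonzero(~used_b)


def paired_t(differences: np.ndarray) -> PairedComparison:
    """Classical paired t test on a vector of per-item differences.

    t = mean / (sd / sqrt(n)) with df = n - 1 and a two-sided p from the t
    distribution.  All-zero differences give t = 0, p = 1 by convention;
    sd = 0 with nonzero mean is flagged infinite with p = 0.
    """
    d = np.asarray(differences, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(mean, 0.0, 0.0, 0.0, df, 1.0)
        t = np.inf if mean > 0 else -np.inf
        return PairedComparison(mean, 0.0, 0.0, float(t), df, 0.0, infinite=True)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedComparison(mean, sd, se, float(t), df, p)


def compare_pcf(g1: SummaryFunction, g2: SummaryFunction) -> PairedComparison:
    """Paired t test over per-bin differences g1(r) - g2(r).

    With the default 50-bin grid this is the df = 49 comparison used to
    check that two measurement methods yield the same spatial structure.
    """
    _common_grid([g1, g2])
    return paired_t(g1.values - g2.values)
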