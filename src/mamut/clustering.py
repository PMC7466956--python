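"""Multinucleotide-mutation (MNM) clustering and Poisson dispersion tests.

If every mutation were an independent event, per-line mutation counts across
MA lines would be Poisson.  Mutations falling within a short window (50 bp by
default) of each other in the same line are instead likely products of a
single mutational event (e.g. error-prone double-strand-break repair), which
inflates the apparent dispersion.  This module chains nearby mutations into
clusters, collapses each cluster to one event, computes the chance
probability of such proximity under uniform placement, and runs a binned
chi-square goodness-of-fit test of per-line counts against a Poisson law.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import MNMCluster, Mutation

__all__ = [
    "detect_mnms",
    "expected_mnm_probability",
    "poisson_gof",
    "PoissonFit",
]


def detect_mnms(
    mutations: Iterable[Mutation],
    window: int = 50,
    strict: bool = False,
) -> tuple[list[MNMCluster], dict[str, int]]:
    """Chain nearby same-line mutations into clusters; collapse to events.

    Per line and chromosome, mutations are sorted by position and chained
    whenever the gap to the previous one is at most ``window`` bp
    (single-linkage, so a cluster's total span may exceed the window).  With
    ``strict=True`` a chain is broken as soon as its span would exceed the
    window, so all pairwise distances stay within it.

    Returns the clusters (size >= 2) and the corrected event count per line:
    singletons plus one per cluster.  Indels participate through their
    anchored position.
    """
    by_group: dict[tuple[str, str], list[Mutation]] = {}
    lines: set[str] = set()
    for m in mutations:
        lines.add(m.line_id)
        by_group.setdefault((m.line_id, m.chrom), []).append(m)

    clusters: list[MNMCluster] = []
    events = {line_id: 0 for line_id in lines}
    for (line_id, chrom), muts in by_group.items():
        muts.sort(key=lambda m: m.pos)
        chain: list[Mutation] = [muts[0]]
        for m in muts[1:]:
            gap_ok = m.pos - chain[-1].pos <= window
            if strict:
                gap_ok = m.pos - chain[0].pos <= window
            if gap_ok:
                chain.append(m)
            else:
                if len(chain) >= 2:
                    clusters.append(MNMCluster(line_id, chrom, tuple(chain)))
                events[line_id] += 1
                chain = [m]
        if len(chain) >= 2:
            clusters.append(MNMCluster(line_id, chrom, tuple(chain)))
        events[line_id] += 1
    return clusters, events


def expected_mnm_probability(
    m: int, n: int, window: int = 50
) -> float:
    """Chance probability that >= 2 of ``m`` uniform mutations fall within
    ``window`` bp of each other on ``n`` callable sites.

    Birthday-type approximation: placing mutations one at a time, the k-th
    placement avoids the ``2 * window`` bp neighbourhood of each of the k
    previous ones, so

        P = 1 - prod_{k=1}^{m-1} (1 - 2 * window * k / n),

    clipped to [0, 1].  With ``m <= 1`` (or ``window = 0``, since distinct
    sites cannot be 0 apart) the probability is 0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    if m <= 1 or window <= 0:
        return 0.0
    log_q = 0.0
    for k in range(1, m):
        term = 1.0 - 2.0 * window * k / n
        if term <= 0.0:
            return 1.0
        log_q += math.log(term)
    return min(1.0, max(0.0, 1.0 - math.exp(log_q)))


class PoissonFit:
    """Result of the binned Poisson goodness-of-fit test."""

    def __init__(self, lam, chi_square, df, p_value, bins, observed, expected):
        self.lam = lam
        self.chi_square = chi_square
        self.df = df
        self.p_value = p_value
        self.bins = bins  # labels; last one is a pooled right tail
        self.observed = observed
        self.expected = expected

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PoissonFit(lambda={self.lam:.3g}, chi2={self.chi_square:.3g}, "
            f"df={self.df}, p={self.p_value:.3g})"
        )


def poisson_gof(per_line_event_counts) -> PoissonFit:
    """Chi-square test of per-line event counts against Poisson(lambda-hat).

    lambda-hat is the sample mean.  Count values are pooled into contiguous
    bins (accumulating adjacent values, plus an open right tail) so that
    every bin's expected count ``n_lines * Pois(bin; lambda-hat)`` is at
    least 1; df = bins - 2 (one for normalization, one for the estimated
    lambda).  With fewer than 3 bins, or lambda-hat = 0, the test is
    undefined and NaNs are reported.
    """
    if isinstance(per_line_event_counts, Mapping):
        counts = np.asarray(list(per_line_event_counts.values()), dtype=int)
    else:
        counts = np.asarray(list(per_line_event_counts), dtype=int)
    n = counts.size
    if n < 5:
        raise ValueError("need at least 5 lines for the Poisson test")
    lam = float(counts.mean())
    if lam == 0.0:
        return PoissonFit(0.0, math.nan, 0, math.nan, ["0"], [n], [n])

    kmax = int(max(counts.max(), math.ceil(lam + 10 * math.sqrt(lam))))
    # contiguous bins [lo, hi] accumulated until the expectation reaches 1
    bins: list[tuple[int, int | None]] = []  # hi=None marks the open tail
    expected: list[float] = []
    lo, acc = 0, 0.0
    for k in range(kmax + 1):
        acc += n * stats.poisson.pmf(k, lam)
        if acc >= 1.0:
            bins.append((lo, k))
            expected.append(acc)
            lo, acc = k + 1, 0.0
    tail = n * stats.poisson.sf(kmax, lam) + acc
    if bins and tail < 1.0:
        last_lo, _ = bins[-1]
        bins[-1] = (last_lo, None)
        expected[-1] += tail
    else:
        bins.append((lo, None))
        expected.append(tail)

    observed, labels = [], []
    for b_lo, b_hi in bins:
        if b_hi is None:
            observed.append(int(np.sum(counts >= b_lo)))
            labels.append(f">={b_lo}")
        else:
            observed.append(int(np.sum((counts >= b_lo) & (counts <= b_hi))))
            labels.append(str(b_lo) if b_lo == b_hi else f"{b_lo}-{b_hi}")

    observed_a = np.asarray(observed, dtype=float)
    expected_a = np.asarray(expected, dtype=float)
    chi2 = float(np.sum((observed_a - expected_a) ** 2 / expected_a))
    df = len(labels) - 2
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else math.nan
    return PoissonFit(lam, chi2, max(df, 0), p, labels, observed, expected_a.tolist())
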