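"""Mutation-rate estimation for mutation-accumulation experiments.

The per-line base-substitution rate is ``mu = m / (n T)`` with ``m`` observed
substitutions, ``n`` callable sites and ``T`` generations.  The experiment
rate is the unweighted mean of per-line rates with its standard error across
lines; 95% intervals come from a BCa (bias-corrected and accelerated)
bootstrap that resamples whole lines, so variation in ``n`` and ``T`` is
resampled jointly with the counts.

Conditional rates split the substitutions that change the genomic GC content
by the base type of the mutated site: ``mu_AT->GC`` uses only A:T sites in the
denominator and ``mu_GC->AT`` only G:C sites.  The GC-conservative classes
(A:T->T:A and G:C->C:G) contribute to neither.  From the two conditional rates
follow the equilibrium GC content ``mu_AT->GC / (mu_GC->AT + mu_AT->GC)`` and
the GC-direction mutation bias ``mu_AT->GC / mu_GC->AT``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .model import MALine, Mutation, RateEstimate, SpectrumCounts

__all__ = [
    "per_line_bs_rate",
    "per_line_counts",
    "experiment_rate",
    "pooled_rate",
    "bca_bootstrap_ci",
    "conditional_rates",
    "equilibrium_gc",
    "bias_ratio",
    "ts_tv_ratio",
    "indel_rates",
    "IndelRates",
]


def per_line_bs_rate(m: int, n: int, T: float) -> float:
    """Per-site per-generation rate ``m / (n T)`` for one line."""
    if n <= 0:
        raise ValueError("callable sites n must be > 0")
    if T <= 0:
        raise ValueError("generations T must be > 0")
    if m < 0:
        raise ValueError("mutation count m must be >= 0")
    return m / (n * T)


def per_line_counts(
    lines: Sequence[MALine], mutations: Iterable[Mutation], mclass=None
) -> dict[str, int]:
    """Count mutations per line, optionally restricted to one or more classes."""
    if isinstance(mclass, str):
        mclass = (mclass,)
    counts = {line.line_id: 0 for line in lines}
    for m in mutations:
        if mclass is not None and m.mclass not in mclass:
            continue
        if m.line_id in counts:
            counts[m.line_id] += 1
    return counts


def bca_bootstrap_ci(
    values,
    statistic: Callable = np.mean,
    n_boot: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """BCa bootstrap interval for a statistic of a line-level sample.

    Resamples the values with replacement ``n_boot`` times.  The bias
    correction ``z0`` is the normal quantile of the fraction of bootstrap
    replicates below the point estimate; the acceleration ``a`` comes from the
    jackknife skewness formula.  Degenerate situations (all resampled
    statistics identical, or all on one side of the point estimate) fall back
    to a collapsed or percentile interval with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("BCa bootstrap needs at least 3 lines")
    rng = np.random.default_rng(seed)
    theta = float(statistic(x))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.asarray([statistic(x[row]) for row in idx], dtype=float)
    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap distribution; interval collapsed")
        return theta, theta
    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    frac_below = float(np.mean(boot < theta))
    if frac_below in (0.0, 1.0):
        warnings.warn("point estimate outside bootstrap range; percentile interval")
        lo, hi = np.quantile(boot, [lo_q, hi_q])
        return float(lo), float(hi)
    z0 = stats.norm.ppf(frac_below)
    jack = np.asarray(
        [statistic(np.delete(x, i)) for i in range(n)], dtype=float
    )
    d = jack.mean() - jack
    denom = 6.0 * (d**2).sum() ** 1.5
    a = float((d**3).sum() / denom) if denom > 0 else 0.0
    zq = stats.norm.ppf([lo_q, hi_q])
    adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def experiment_rate(
    per_line_rates: Sequence[float],
    n_boot: int = 1000,
    seed=None,
) -> RateEstimate:
    """Experiment-wide rate: unweighted mean of per-line rates.

    The SE is the standard deviation of per-line rates over sqrt(n_lines);
    with a single line both SE and CI are undefined (NaN).
    """
    r = np.asarray(per_line_rates, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one line")
    point = float(r.mean())
    if r.size == 1:
        return RateEstimate(point=point, n_lines=1, method="per_line_mean")
    se = float(r.std(ddof=1) / math.sqrt(r.size))
    lo = hi = math.nan
    if r.size >= 3:
        lo, hi = bca_bootstrap_ci(r, np.mean, n_boot=n_boot, seed=seed)
    return RateEstimate(
        point=point,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_lines=int(r.size),
        method="per_line_mean+bca",
    )


def pooled_rate(ms: Sequence[int], lines: Sequence[MALine]) -> float:
    """Alternative estimator: total mutations over total site-generations."""
    denom = sum(l.callable_sites * l.generations for l in lines)
    if denom <= 0:
        raise ValueError("zero site-generations")
    return sum(ms) / denom


def conditional_rates(
    spectrum: SpectrumCounts, lines: Sequence[MALine]
) -> tuple[float, float]:
    """GC-changing conditional rates (mu_AT->GC, mu_GC->AT).

    Numerators pool the transition and transversion counts that move an A:T
    pair to G:C (resp. G:C to A:T); denominators pool callable A/T (resp.
    G/C) site-generations across lines.
    """
    denom_at = sum(l.callable_AT_sites * l.generations for l in lines)
    denom_gc = sum(l.callable_GC_sites * l.generations for l in lines)
    if denom_at <= 0 or denom_gc <= 0:
        raise ValueError("zero A/T or G/C site-generations in denominator")
    mu_at_gc = (spectrum.AT_to_GC_ts + spectrum.AT_to_CG_tv) / denom_at
    mu_gc_at = (spectrum.GC_to_AT_ts + spectrum.GC_to_TA_tv) / denom_gc
    return mu_at_gc, mu_gc_at


def equilibrium_gc(mu_ATtoGC: float, mu_GCtoAT: float) -> float:
    """GC content at mutation equilibrium.

    The stationary GC fraction under the two conditional rates alone:
    ``mu_AT->GC / (mu_GC->AT + mu_AT->GC)``.
    """
    if mu_ATtoGC < 0 or mu_GCtoAT < 0:
        raise ValueError("rates must be non-negative")
    total = mu_ATtoGC + mu_GCtoAT
    if total == 0:
        raise ValueError("both conditional rates are zero")
    return mu_ATtoGC / total


def bias_ratio(mu_ATtoGC: float, mu_GCtoAT: float) -> tuple[float, float]:
    """Mutation bias in the G/C direction and its reciprocal (A/T direction)."""
    if mu_GCtoAT <= 0:
        raise ValueError("mu_GC->AT must be positive")
    gc_bias = mu_ATtoGC / mu_GCtoAT
    at_bias = math.inf if gc_bias == 0 else 1.0 / gc_bias
    return gc_bias, at_bias


def ts_tv_ratio(spectrum: SpectrumCounts) -> float:
    """Transition/transversion ratio (random expectation 0.5)."""
    if spectrum.transversions == 0:
        warnings.warn("no transversions observed; Ts/Tv reported as infinite")
        return math.inf
    return spectrum.transitions / spectrum.transversions


@dataclass
class IndelRates:
    """Indel rate estimates plus the between-lab comparison."""

    total: RateEstimate
    insertion: RateEstimate
    deletion: RateEstimate
    lab_t: float = math.nan
    lab_p: float = math.nan


def indel_rates(
    lines: Sequence[MALine],
    mutations: Iterable[Mutation],
    n_boot: int = 1000,
    seed=None,
) -> IndelRates:
    """Per-line m/(nT) estimator restricted to indels.

    Emits total, insertion-only and deletion-only rates, plus a Welch
    two-sample t-test on per-line total indel rates between the two largest
    lab groups (NaN when fewer than two labs with >= 2 lines each).
    """
    muts = list(mutations)
    out = {}
    for key, classes in [
        ("total", ("insertion", "deletion")),
        ("insertion", ("insertion",)),
        ("deletion", ("deletion",)),
    ]:
        counts = per_line_counts(lines, muts, classes)
        rates = [
            per_line_bs_rate(counts[l.line_id], l.callable_sites, l.generations)
            for l in lines
        ]
        out[key] = experiment_rate(rates, n_boot=n_boot, seed=seed)
        if key == "total":
            total_rates = dict(zip([l.line_id for l in lines], rates))
    labs: dict[str, list[float]] = {}
    for l in lines:
        labs.setdefault(l.lab, []).append(total_rates[l.line_id])
    groups = sorted(labs.values(), key=len, reverse=True)[:2]
    t = p = math.nan
    if len(groups) == 2 and min(len(g) for g in groups) >= 2:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return IndelRates(
        total=out["total"],
        insertion=out["insertion"],
        deletion=out["deletion"],
        lab_t=t,
        lab_p=p,
    )
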