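"""Effective population size, full-pipeline assembly and report building.

For neutrally evolving sites in a haploid population the expected per-site
nucleotide diversity is ``theta = 2 Ne mu``, so an MA-derived mutation rate
``mu`` together with a published ``theta`` yields ``Ne = theta / (2 mu)``.
``run_analysis`` chains every stage of the pipeline (SSR context, rates,
spectrum, MNM clustering, Poisson fit, coding effects, indel accounting, Ne)
and ``build_report`` renders the result deterministically as JSON and a
summary-table TSV.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .clustering import detect_mnms, expected_mnm_probability, poisson_gof
from .effects import (
    CodonUsageTable,
    annotate_effects,
    effect_summary,
    expected_ns_ratio,
    indel_accounting,
    ns_observed_test,
    ssr_enrichment_test,
)
from .intervals import GenomeMask
from .model import MALine, Mutation, NeEstimate, RateEstimate, SpectrumCounts
from .rates import (
    bias_ratio,
    conditional_rates,
    equilibrium_gc,
    experiment_rate,
    indel_rates,
    per_line_bs_rate,
    per_line_counts,
    pooled_rate,
    ts_tv_ratio,
)
from .ssr import annotate_variants_ssr, find_ssrs, ssr_genome_fraction

__all__ = ["estimate_ne", "run_analysis", "build_report"]


def estimate_ne(theta: float, mu_estimate: RateEstimate) -> NeEstimate:
    """Effective population size ``Ne = theta / (2 mu)`` for haploids.

    When the rate estimate carries a 95% CI, the Ne bounds are the same
    monotone transform with the order reversed (a larger mu implies a smaller
    Ne for fixed diversity).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    mu = mu_estimate.point
    if mu <= 0:
        raise ValueError("mu must be positive to estimate Ne")
    ne = theta / (2.0 * mu)
    lo = hi = math.nan
    if not math.isnan(mu_estimate.ci_low) and mu_estimate.ci_low > 0:
        lo = theta / (2.0 * mu_estimate.ci_high)
        hi = theta / (2.0 * mu_estimate.ci_low)
    return NeEstimate(theta=theta, mu=mu, ne=ne, ci_low=lo, ci_high=hi)


def _union_mask(lines: Sequence[MALine]) -> GenomeMask:
    ivs: dict[str, list] = {}
    for line in lines:
        if line.mask is None:
            continue
        for chrom in line.mask.chromosomes:
            ivs.setdefault(chrom, []).extend(
                map(tuple, line.mask.intervals(chrom))
            )
    return GenomeMask(ivs)


def run_analysis(
    reference: Mapping[str, str],
    lines: Sequence[MALine],
    mutations: Sequence[Mutation],
    gene_models: Sequence = (),
    ssr_loci: Sequence | None = None,
    codon_usage: CodonUsageTable | None = None,
    theta: float = 0.00076,
    window: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
    min_copies: int = 3,
    min_tract_bp: int = 8,
    max_unit: int = 10,
) -> dict:
    """Run the complete downstream analysis and return a nested result dict."""
    mutations = list(mutations)
    if ssr_loci is None:
        ssr_loci = find_ssrs(
            reference,
            min_copies=min_copies,
            min_tract_bp=min_tract_bp,
            max_unit=max_unit,
        )
    annotate_variants_ssr(mutations, ssr_loci)
    if gene_models:
        annotate_effects(mutations, gene_models, reference)
        if codon_usage is None:
            codon_usage = CodonUsageTable.from_genes(reference, gene_models)

    subs = [m for m in mutations if m.mclass == "substitution"]
    indels = [m for m in mutations if m.mclass != "substitution"]

    # --- per-line rates -------------------------------------------------
    m_bs = per_line_counts(lines, subs)
    bs_rates = [
        per_line_bs_rate(m_bs[l.line_id], l.callable_sites, l.generations)
        for l in lines
    ]
    bs_rate = experiment_rate(bs_rates, n_boot=n_boot, seed=seed)
    ind = indel_rates(lines, indels, n_boot=n_boot, seed=seed + 1)

    # --- spectrum -------------------------------------------------------
    spectrum = SpectrumCounts.from_mutations(subs)
    tstv = ts_tv_ratio(spectrum) if spectrum.total else math.nan
    mu_at_gc = mu_gc_at = eq_gc = gc_bias = math.nan
    if spectrum.total:
        mu_at_gc, mu_gc_at = conditional_rates(spectrum, lines)
        if mu_at_gc + mu_gc_at > 0:
            eq_gc = equilibrium_gc(mu_at_gc, mu_gc_at)
        if mu_gc_at > 0:
            gc_bias = bias_ratio(mu_at_gc, mu_gc_at)[0]

    # --- MNM clustering and Poisson fit ---------------------------------
    raw_counts = {l.line_id: m_bs[l.line_id] for l in lines}
    clusters, corrected = detect_mnms(subs, window=window)
    corrected_full = {l.line_id: corrected.get(l.line_id, 0) for l in lines}
    mnm_p = [
        expected_mnm_probability(m_bs[l.line_id], l.callable_sites, window)
        for l in lines
    ]
    gof_raw = poisson_gof(list(raw_counts.values())) if len(lines) >= 5 else None
    gof_corr = (
        poisson_gof(list(corrected_full.values())) if len(lines) >= 5 else None
    )

    # --- SSR context ----------------------------------------------------
    union = _union_mask(lines)
    ssr_frac = ssr_genome_fraction(ssr_loci, union) if union else math.nan
    n_sub_ssr = sum(m.in_ssr for m in subs)
    n_ind_ssr = sum(m.in_ssr for m in indels)
    enrich_sub = enrich_ind = math.nan
    if subs and 0 < ssr_frac < 1:
        enrich_sub = ssr_enrichment_test(n_sub_ssr, len(subs), ssr_frac)
    if indels and 0 < ssr_frac < 1:
        enrich_ind = ssr_enrichment_test(n_ind_ssr, len(indels), ssr_frac)

    # --- coding effects -------------------------------------------------
    summary = effect_summary(mutations)
    exp_ns = obs_ns = ns_chi2 = ns_p = math.nan
    if gene_models and codon_usage is not None and spectrum.total:
        if tstv and tstv > 0 and math.isfinite(tstv):
            exp_ns = expected_ns_ratio(codon_usage, tstv)
            if summary.n_synonymous + summary.n_nonsynonymous > 0:
                obs_ns, ns_chi2, ns_p = ns_observed_test(
                    summary.n_nonsynonymous, summary.n_synonymous, exp_ns
                )
    acct = indel_accounting(indels, lines)

    # --- Ne -------------------------------------------------------------
    ne = estimate_ne(theta, bs_rate) if bs_rate.point > 0 else None

    per_lab: dict[str, dict] = {}
    for lab in sorted({l.lab for l in lines}):
        lab_lines = [l for l in lines if l.lab == lab]
        ids = {l.line_id for l in lab_lines}
        lab_muts = [m for m in mutations if m.line_id in ids]
        lab_subs = [m for m in lab_muts if m.mclass == "substitution"]
        lab_rates = [
            per_line_bs_rate(m_bs[l.line_id], l.callable_sites, l.generations)
            for l in lab_lines
        ]
        lab_ind_counts = per_line_counts(
            lab_lines, lab_muts, ("insertion", "deletion")
        )
        lab_ind_rates = [
            per_line_bs_rate(
                lab_ind_counts[l.line_id], l.callable_sites, l.generations
            )
            for l in lab_lines
        ]
        lab_spec = SpectrumCounts.from_mutations(lab_subs)
        per_lab[lab] = {
            "n_lines": len(lab_lines),
            "sites_surveyed": int(sum(l.callable_sites for l in lab_lines)),
            "summary": vars(effect_summary(lab_muts)),
            "ts_tv": ts_tv_ratio(lab_spec) if lab_spec.total else math.nan,
            "bs_rate": float(np.mean(lab_rates)) if lab_rates else math.nan,
            "indel_rate": float(np.mean(lab_ind_rates))
            if lab_ind_rates
            else math.nan,
        }

    return {
        "n_lines": len(lines),
        "sites_surveyed": int(sum(l.callable_sites for l in lines)),
        "per_line": {
            l.line_id: {
                "lab": l.lab,
                "generations": l.generations,
                "n": l.callable_sites,
                "n_AT": l.callable_AT_sites,
                "n_GC": l.callable_GC_sites,
                "m_bs": m_bs[l.line_id],
                "m_bs_corrected": corrected_full[l.line_id],
                "bs_rate": bs_rates[i],
            }
            for i, l in enumerate(lines)
        },
        "bs_rate": vars(bs_rate),
        "bs_rate_pooled": pooled_rate(list(m_bs.values()), lines),
        "indel_rate": vars(ind.total),
        "insertion_rate": vars(ind.insertion),
        "deletion_rate": vars(ind.deletion),
        "lab_indel_ttest": {"t": ind.lab_t, "p": ind.lab_p},
        "spectrum": spectrum.as_dict(),
        "ts_tv": tstv,
        "conditional_rates": {
            "mu_AT_to_GC": mu_at_gc,
            "mu_GC_to_AT": mu_gc_at,
        },
        "equilibrium_gc": eq_gc,
        "gc_bias_ratio": gc_bias,
        "mnm": {
            "window": window,
            "n_clusters": len(clusters),
            "n_clustered_mutations": int(sum(c.size for c in clusters)),
            "expected_probability_per_line_mean": float(np.mean(mnm_p))
            if mnm_p
            else math.nan,
        },
        "poisson_fit_raw": _gof_dict(gof_raw),
        "poisson_fit_corrected": _gof_dict(gof_corr),
        "ssr": {
            "n_loci": len(ssr_loci),
            "callable_fraction_in_ssr": ssr_frac,
            "substitutions_in_ssr": int(n_sub_ssr),
            "indels_in_ssr": int(n_ind_ssr),
            "enrichment_p_substitutions": enrich_sub,
            "enrichment_p_indels": enrich_ind,
        },
        "effects": vars(summary),
        "ns_ratio": {
            "expected": exp_ns,
            "observed": obs_ns,
            "chi_square": ns_chi2,
            "p": ns_p,
        },
        "indel_accounting": vars(acct),
        "ne": vars(ne) if ne is not None else None,
        "theta": theta,
        "per_lab": per_lab,
    }


def _gof_dict(fit):
    if fit is None:
        return None
    return {
        "lambda": fit.lam,
        "chi_square": fit.chi_square,
        "df": fit.df,
        "p": fit.p_value,
        "bins": fit.bins,
        "observed": fit.observed,
        "expected": fit.expected,
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_TABLE_ROWS = [
    ("No. of sites surveyed", lambda g: g["sites_surveyed"]),
    ("No. of base-substitutions", lambda g: g["summary"]["n_substitutions"]),
    ("No. of indels", lambda g: g["summary"]["n_indels"]),
    ("Transitions/Transversions", lambda g: _fmt(g["ts_tv"], 2)),
    ("No. of synonymous substitutions", lambda g: g["summary"]["n_synonymous"]),
    (
        "No. of nonsynonymous substitutions",
        lambda g: g["summary"]["n_nonsynonymous"],
    ),
    (
        "No. of noncoding substitutions",
        lambda g: g["summary"]["n_noncoding_subs"],
    ),
    ("No. of base substitutions in SSRs", lambda g: g["summary"]["n_subs_in_ssr"]),
    ("No. of indels in SSRs", lambda g: g["summary"]["n_indels_in_ssr"]),
    ("No. of indels in coding regions", lambda g: g["summary"]["n_indels_coding"]),
    (
        "No. of indels in noncoding regions",
        lambda g: g["summary"]["n_indels_noncoding"],
    ),
    (
        "Base-substitution mutation rate (x 10^-11)",
        lambda g: _fmt(g["bs_rate"] * 1e11, 2),
    ),
    (
        "Insertion-deletion rate (x 10^-11)",
        lambda g: _fmt(g["indel_rate"] * 1e11, 2),
    ),
]


def _fmt(x, nd):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


def build_report(
    result: dict,
    per_lab: Mapping[str, dict] | None = None,
    out_dir=None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> tuple[str, str]:
    """Render an analysis result as (stable JSON, summary-table TSV).

    JSON keys are sorted and floats rendered by ``json`` defaults, so the
    report is byte-identical when regenerated from the same inputs.  The TSV
    mirrors the classic MA summary-table layout: one column per lab group
    plus an overall column.
    """
    meta = {
        "tool": "mamut",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash,
    }
    payload = {"metadata": meta, "results": result}
    json_text = json.dumps(payload, sort_keys=True, indent=2, allow_nan=True)

    groups: dict[str, dict] = {}
    if per_lab is None:
        per_lab = result.get("per_lab")
    if per_lab:
        groups.update(per_lab)
    overall = {
        "sites_surveyed": result["sites_surveyed"],
        "summary": result["effects"],
        "ts_tv": result["ts_tv"],
        "bs_rate": result["bs_rate"]["point"],
        "indel_rate": result["indel_rate"]["point"],
    }
    groups["Overall"] = overall
    cols = [c for c in groups if c != "Overall"] + ["Overall"]
    lines_out = ["Statistic\t" + "\t".join(cols)]
    for label, getter in _TABLE_ROWS:
        cells = []
        for c in cols:
            try:
                cells.append(str(getter(groups[c])))
            except (KeyError, TypeError):
                cells.append("NA")
        lines_out.append(label + "\t" + "\t".join(cells))
    tsv_text = "\n".join(lines_out) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json_text)
        (out / "summary_table.tsv").write_text(tsv_text)
    return json_text, tsv_text
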