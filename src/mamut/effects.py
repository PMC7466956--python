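"""Coding-effect classification, neutral NS/S expectation and indel accounting.

Substitutions falling in a CDS are translated in place to decide synonymous
versus nonsynonymous; everything outside annotated CDS is noncoding.  The
neutral expectation for the nonsynonymous/synonymous ratio weights every
possible single-base change of every sense codon by codon usage and by the
observed transition/transversion bias, so a departure of the observed ratio
from this expectation is evidence of selection during the experiment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .model import GeneModel, MALine, Mutation

__all__ = [
    "CodonUsageTable",
    "EffectCall",
    "classify_effect",
    "annotate_effects",
    "expected_ns_ratio",
    "ns_observed_test",
    "ssr_enrichment_test",
    "indel_accounting",
    "indel_balance",
    "IndelSummary",
    "EffectSummary",
    "effect_summary",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_PURINES = {"A", "G"}


def standard_code() -> dict[str, str]:
    """Codon -> amino acid map of the standard genetic code, stops as '*'."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def _is_transition(b1: str, b2: str) -> bool:
    return (b1 in _PURINES) == (b2 in _PURINES)


@dataclass
class CodonUsageTable:
    """Relative usage of the 64 codons (normalized to sum to 1).

    Stop codons may carry nonzero usage only when ``allow_stops`` is set;
    they are never counted as mutational opportunities either way.
    """

    frequencies: dict[str, float]
    allow_stops: bool = False

    def __post_init__(self) -> None:
        code = standard_code()
        freqs = {}
        for codon, f in self.frequencies.items():
            codon = codon.upper().replace("U", "T")
            if len(codon) != 3 or any(b not in _BASES for b in codon):
                raise ValueError(f"bad codon {codon!r}")
            if f < 0:
                raise ValueError(f"negative usage for {codon}")
            if code[codon] == "*" and f > 0 and not self.allow_stops:
                raise ValueError(
                    f"stop codon {codon} has nonzero usage (allow_stops=False)"
                )
            freqs[codon] = float(f)
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError("codon usage sums to zero")
        self.frequencies = {c: f / total for c, f in freqs.items()}

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        code = standard_code()
        sense = [c for c, aa in code.items() if aa != "*"]
        return cls({c: 1.0 / len(sense) for c in sense})

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        freqs: dict[str, float] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{ln}: expected codon<TAB>frequency")
                freqs[parts[0]] = float(parts[1])
        return cls(freqs)

    @classmethod
    def from_genes(
        cls, reference: Mapping[str, str], gene_models: Sequence[GeneModel]
    ) -> "CodonUsageTable":
        """Empirical usage counted from the reference coding sequences."""
        counts: dict[str, int] = {}
        for g in gene_models:
            cds = _cds_sequence(g, reference)
            for i in range(0, len(cds) - len(cds) % 3, 3):
                codon = cds[i : i + 3]
                if "N" in codon:
                    continue
                counts[codon] = counts.get(codon, 0) + 1
        code = standard_code()
        counts = {c: k for c, k in counts.items() if code[c] != "*"}
        if not counts:
            raise ValueError("no sense codons found in gene models")
        return cls({c: float(k) for c, k in counts.items()})


@dataclass
class EffectCall:
    """Outcome of classifying one mutation against the gene models."""

    region: str  # coding | noncoding
    effect: str  # synonymous | nonsynonymous | noncoding | NA
    gene_id: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    frameshift: bool | None = None  # indels in CDS only
    ambiguous: bool = False  # event spans a CDS boundary


def _cds_sequence(gene: GeneModel, reference: Mapping[str, str]) -> str:
    seq = "".join(
        reference[gene.chrom][s:e] for s, e in gene.segments
    ).upper()
    if gene.strand == "-":
        seq = "".join(_COMP[b] for b in reversed(seq))
    return seq


def _cds_offset(gene: GeneModel, pos0: int) -> int | None:
    """Offset of 0-based genomic position within the coding sequence."""
    off = 0
    for s, e in gene.segments:
        if s <= pos0 < e:
            genomic = off + (pos0 - s)
            if gene.strand == "+":
                return genomic
            return gene.cds_length - 1 - genomic
        off += e - s
    return None


def classify_effect(
    mutation: Mutation,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
    code: Mapping[str, str] | None = None,
) -> EffectCall:
    """Classify one mutation by genomic context and coding effect.

    Substitutions inside a CDS are synonymous iff the mutant codon translates
    to the same symbol (stops compare as '*').  Indels inside a CDS are
    flagged frameshift when their length is not a multiple of 3.  Events whose
    anchored base is coding but whose span crosses a CDS boundary are
    classified by the anchored base and flagged ambiguous.
    """
    code = dict(code) if code is not None else standard_code()
    pos0 = mutation.pos - 1
    gene = None
    for g in gene_models:
        if g.chrom == mutation.chrom and _cds_offset(g, pos0) is not None:
            gene = g
            break
    if gene is None:
        return EffectCall(region="noncoding", effect="noncoding")

    a, b = mutation.affected_interval()
    inside = all(_cds_offset(gene, p) is not None for p in range(a, b))
    if mutation.mclass != "substitution":
        return EffectCall(
            region="coding",
            effect="NA",
            gene_id=gene.gene_id,
            frameshift=mutation.indel_length % 3 != 0,
            ambiguous=not inside,
        )

    off = _cds_offset(gene, pos0)
    cds = _cds_sequence(gene, reference)
    codon_idx, within = divmod(off, 3)
    codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    alt_base = (
        mutation.alt_allele
        if gene.strand == "+"
        else _COMP[mutation.alt_allele]
    )
    mutant = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = code.get(codon, "X")
    aa_alt = code.get(mutant, "X")
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return EffectCall(
        region="coding",
        effect=effect,
        gene_id=gene.gene_id,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
    )


def annotate_effects(
    mutations: Iterable[Mutation],
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
    code: Mapping[str, str] | None = None,
) -> list[EffectCall]:
    """Classify all mutations, setting ``region``/``effect`` in place."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.start)
    calls = []
    for m in mutations:
        call = classify_effect(m, by_chrom.get(m.chrom, ()), reference, code)
        m.region = call.region
        if m.mclass == "substitution":
            m.effect = call.effect
        else:
            m.effect = "NA" if call.region == "coding" else "noncoding"
        calls.append(call)
    return calls


def expected_ns_ratio(
    codon_usage: CodonUsageTable,
    ts_tv: float,
    code: Mapping[str, str] | None = None,
) -> float:
    """Neutral expectation for the nonsynonymous/synonymous ratio.

    Every sense codon (weighted by usage) admits 9 single-base changes; each
    transition carries weight ``kappa = 2 * ts_tv`` and each transversion
    weight 1, so the implied pooled Ts/Tv over a codon equals the input ratio
    (1 transition vs 2 transversions per site).  Changes creating a stop count
    as nonsynonymous; stop codons themselves contribute no opportunities.
    """
    if ts_tv <= 0:
        raise ValueError("ts_tv must be positive")
    code = dict(code) if code is not None else standard_code()
    kappa = 2.0 * ts_tv
    w_n = w_s = 0.0
    for codon, freq in codon_usage.frequencies.items():
        if freq == 0 or code.get(codon, "*") == "*":
            continue
        aa = code[codon]
        for i, ref in enumerate(codon):
            for alt in _BASES:
                if alt == ref:
                    continue
                w = kappa if _is_transition(ref, alt) else 1.0
                mutant = codon[:i] + alt + codon[i + 1 :]
                if code.get(mutant, "X") == aa:
                    w_s += freq * w
                else:
                    w_n += freq * w
    if w_s == 0:
        raise ValueError("no synonymous opportunities (degenerate code/usage)")
    return w_n / w_s


def ns_observed_test(
    n_nonsyn: int, n_syn: int, expected_ratio: float
) -> tuple[float, float, float]:
    """Observed NS/S ratio and a 1-df chi-square test against the neutral one.

    The expected cell proportions are ``R/(1+R)`` and ``1/(1+R)`` for
    ``R = expected_ratio``.  Returns (observed_ratio, chi_square, p).
    """
    total = n_nonsyn + n_syn
    if total < 1:
        raise ValueError("need at least one classified substitution")
    if expected_ratio <= 0:
        raise ValueError("expected_ratio must be positive")
    observed_ratio = math.inf if n_syn == 0 else n_nonsyn / n_syn
    p_n = expected_ratio / (1.0 + expected_ratio)
    expected = np.array([total * p_n, total * (1.0 - p_n)])
    observed = np.array([n_nonsyn, n_syn], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, 1))
    return observed_ratio, chi2, p


def ssr_enrichment_test(
    k_in_ssr: int, n_total: int, ssr_fraction: float
) -> float:
    """One-sided exact binomial p-value for SSR enrichment, P(X >= k)."""
    if not (0 <= k_in_ssr <= n_total):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < ssr_fraction < 1.0):
        raise ValueError("ssr_fraction must be in (0, 1)")
    return float(
        stats.binomtest(k_in_ssr, n_total, ssr_fraction, alternative="greater").pvalue
    )


@dataclass
class IndelSummary:
    """Totals and ratios of the insertion/deletion size accounting."""

    n_insertions: int
    n_deletions: int
    inserted_bp: int
    deleted_bp: int
    net_change_bp: int  # inserted - deleted (negative = net loss)
    per_line_net_mean: float
    per_line_net_se: float
    del_ins_count_ratio: float
    del_ins_bp_ratio: float
    frac_3n: float
    frac_3n_in_ssr: float
    frac_3n_out_ssr: float
    n_coding: int
    n_noncoding: int


def indel_balance(
    deleted_bp: float, inserted_bp: float, n_lines: int
) -> tuple[float, float]:
    """Net sequence loss across lines and the mean loss per line."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    net_loss = deleted_bp - inserted_bp
    return net_loss, net_loss / n_lines


def indel_accounting(
    mutations: Iterable[Mutation], lines: Sequence[MALine]
) -> IndelSummary:
    """Account indel sizes: totals, deletion bias, per-line net change, 3n."""
    per_line_net = {l.line_id: 0 for l in lines}
    ins_bp = del_bp = n_ins = n_del = 0
    n3 = n3_in = n3_out = n_in = n_out = 0
    n_coding = n_noncoding = 0
    for m in mutations:
        if m.mclass == "insertion":
            n_ins += 1
            ins_bp += m.indel_length
            per_line_net[m.line_id] = per_line_net.get(m.line_id, 0) + m.indel_length
        elif m.mclass == "deletion":
            n_del += 1
            del_bp += m.indel_length
            per_line_net[m.line_id] = per_line_net.get(m.line_id, 0) - m.indel_length
        else:
            continue
        if m.indel_length % 3 == 0:
            n3 += 1
            if m.in_ssr:
                n3_in += 1
            else:
                n3_out += 1
        if m.in_ssr:
            n_in += 1
        else:
            n_out += 1
        if m.region == "coding":
            n_coding += 1
        elif m.region == "noncoding":
            n_noncoding += 1
    nets = np.asarray([per_line_net[l.line_id] for l in lines], dtype=float)
    mean = float(nets.mean()) if nets.size else 0.0
    se = (
        float(nets.std(ddof=1) / math.sqrt(nets.size)) if nets.size >= 2 else math.nan
    )
    total = n_ins + n_del
    return IndelSummary(
        n_insertions=n_ins,
        n_deletions=n_del,
        inserted_bp=ins_bp,
        deleted_bp=del_bp,
        net_change_bp=ins_bp - del_bp,
        per_line_net_mean=mean,
        per_line_net_se=se,
        del_ins_count_ratio=(n_del / n_ins) if n_ins else math.inf,
        del_ins_bp_ratio=(del_bp / ins_bp) if ins_bp else math.inf,
        frac_3n=(n3 / total) if total else math.nan,
        frac_3n_in_ssr=(n3_in / n_in) if n_in else math.nan,
        frac_3n_out_ssr=(n3_out / n_out) if n_out else math.nan,
        n_coding=n_coding,
        n_noncoding=n_noncoding,
    )


@dataclass
class EffectSummary:
    """Per-group counts in the style of the experiment summary table."""

    n_substitutions: int = 0
    n_indels: int = 0
    n_synonymous: int = 0
    n_nonsynonymous: int = 0
    n_noncoding_subs: int = 0
    n_subs_in_ssr: int = 0
    n_indels_in_ssr: int = 0
    n_indels_coding: int = 0
    n_indels_noncoding: int = 0


def effect_summary(mutations: Iterable[Mutation]) -> EffectSummary:
    s = EffectSummary()
    for m in mutations:
        if m.mclass == "substitution":
            s.n_substitutions += 1
            if m.effect == "synonymous":
                s.n_synonymous += 1
            elif m.effect == "nonsynonymous":
                s.n_nonsynonymous += 1
            else:
                s.n_noncoding_subs += 1
            if m.in_ssr:
                s.n_subs_in_ssr += 1
        else:
            s.n_indels += 1
            if m.in_ssr:
                s.n_indels_in_ssr += 1
            if m.region == "coding":
                s.n_indels_coding += 1
            else:
                s.n_indels_noncoding += 1
    return s
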