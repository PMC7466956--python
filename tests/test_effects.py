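"""Tests for effect classification, NS/S expectation and indel accounting."""

from __future__ import annotations

import math

import pytest
from Bio.Seq import Seq
from scipy import stats as sps

from mamut.effects import (
    CodonUsageTable,
    annotate_effects,
    classify_effect,
    expected_ns_ratio,
    indel_accounting,
    indel_balance,
    ns_observed_test,
    ssr_enrichment_test,
    standard_code,
)
from mamut.model import GeneModel, MALine, Mutation

_BASES = "ACGT"


def _gene(seq_len, strand="+", start=0):
    return GeneModel("g1", "c", strand, ((start, start + seq_len),))


class TestClassifyEffect:
    def test_met_to_ile_is_nonsynonymous(self):
        ref = {"c": "ATGAAATAA"}
        m = Mutation("l", "c", 3, "G", "A", "substitution")
        call = classify_effect(m, [_gene(9)], ref)
        assert call.effect == "nonsynonymous"
        assert (call.aa_ref, call.aa_alt) == ("M", "I")

    def test_leu_codon_third_position_is_synonymous(self):
        ref = {"c": "CTTAAATAA"}
        m = Mutation("l", "c", 3, "T", "C", "substitution")
        call = classify_effect(m, [_gene(9)], ref)
        assert call.effect == "synonymous"
        assert call.aa_ref == "L"

    def test_minus_strand_codons_read_on_reverse_complement(self):
        # reverse complement of "CATTTTTGA"[::-1]... gene on '-': CDS is
        # revcomp of the genomic slice; genomic TCAAAAATG -> CDS ATG AAA TGA... wait
        # build explicitly: CDS = ATGAAATAA, genomic = revcomp = TTATTTCAT
        ref = {"c": "TTATTTCAT"}
        gene = _gene(9, strand="-")
        # genomic pos 8 (0-based) is the CDS first base (A of ATG)
        m = Mutation("l", "c", 7, "A", "G", "substitution")  # CDS offset 1: T->C
        call = classify_effect(m, [gene], ref)
        assert call.aa_ref == "M"
        assert call.effect == "nonsynonymous"

    def test_outside_cds_is_noncoding(self):
        ref = {"c": "ATGAAATAACCCC"}
        m = Mutation("l", "c", 11, "C", "T", "substitution")
        call = classify_effect(m, [_gene(9)], ref)
        assert call.region == "noncoding"
        assert call.effect == "noncoding"

    def test_coding_indel_frameshift_flag(self):
        ref = {"c": "ATGAAAGGGTAA"}
        fs = Mutation("l", "c", 4, "AA", "A", "deletion", 1)
        inframe = Mutation("l", "c", 4, "AAAG", "A", "deletion", 3)
        call_fs = classify_effect(fs, [_gene(12)], ref)
        call_if = classify_effect(inframe, [_gene(12)], ref)
        assert call_fs.frameshift is True
        assert call_if.frameshift is False

    def test_deletion_spanning_cds_boundary_flagged_ambiguous(self):
        ref = {"c": "ATGAAATAACCCC"}
        m = Mutation("l", "c", 8, "AACC", "A", "deletion", 3)
        call = classify_effect(m, [_gene(9)], ref)
        assert call.region == "coding"
        assert call.ambiguous

    def test_reference_consistency_on_simulated_truth(
        self, small_experiment, small_genome
    ):
        """Re-classifying simulated mutations from scratch reproduces the
        simulator's truth effects, and the predicted amino-acid change agrees
        with an independent re-translation of the mutated CDS."""
        ref = small_genome.sequences()
        genes = small_genome.gene_models
        muts = [
            Mutation(
                m.line_id, m.chrom, m.pos, m.ref_allele, m.alt_allele,
                m.mclass, m.indel_length,
            )
            for m in small_experiment.truth.mutations
        ]
        calls = annotate_effects(muts, genes, ref)
        truth = small_experiment.truth.mutations
        subs = [
            (m, t, c)
            for m, t, c in zip(muts, truth, calls)
            if m.mclass == "substitution"
        ]
        assert subs
        for m, t, call in subs:
            assert m.region == t.region
            assert m.effect == t.effect
            if call.region == "coding":
                gene = next(g for g in genes if g.gene_id == call.gene_id)
                s, e = gene.segments[0]
                cds = ref[gene.chrom][s:e]
                mutated = (
                    cds[: m.pos - 1 - s] + m.alt_allele + cds[m.pos - s :]
                )
                if gene.strand == "-":
                    cds = str(Seq(cds).reverse_complement())
                    mutated = str(Seq(mutated).reverse_complement())
                aa_before = str(Seq(cds).translate())
                aa_after = str(Seq(mutated).translate())
                assert (aa_before == aa_after) == (m.effect == "synonymous")


class TestExpectedNsRatio:
    def brute_force(self, ts_tv):
        """Independent enumeration over all sense codons x 9 changes using
        Biopython translation."""
        code = standard_code()
        kappa = 2 * ts_tv
        w_n = w_s = 0.0
        purines = {"A", "G"}
        for codon, aa in code.items():
            if aa == "*":
                continue
            for i in range(3):
                for alt in _BASES:
                    if alt == codon[i]:
                        continue
                    w = kappa if (codon[i] in purines) == (alt in purines) else 1
                    mut = codon[:i] + alt + codon[i + 1 :]
                    aa_mut = str(Seq(mut).translate())
                    if aa_mut == str(Seq(codon).translate()):
                        w_s += w
                    else:
                        w_n += w
        return w_n / w_s

    def test_uniform_usage_unbiased_matches_enumeration(self):
        got = expected_ns_ratio(CodonUsageTable.uniform(), ts_tv=0.5)
        assert got == pytest.approx(self.brute_force(0.5), rel=1e-12)

    def test_transition_dominated_limit(self):
        got = expected_ns_ratio(CodonUsageTable.uniform(), ts_tv=1e9)
        # transitions-only enumeration
        code = standard_code()
        w_n = w_s = 0
        ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for codon, aa in code.items():
            if aa == "*":
                continue
            for i in range(3):
                mut = codon[:i] + ts_partner[codon[i]] + codon[i + 1 :]
                if code[mut] == aa:
                    w_s += 1
                else:
                    w_n += 1
        assert got == pytest.approx(w_n / w_s, rel=1e-6)

    def test_usage_rescaling_invariance(self):
        freqs = {c: f for c, f in CodonUsageTable.uniform().frequencies.items()}
        scaled = CodonUsageTable({c: 100 * f for c, f in freqs.items()})
        assert expected_ns_ratio(scaled, 2.0) == pytest.approx(
            expected_ns_ratio(CodonUsageTable.uniform(), 2.0)
        )

    def test_toy_code_with_neutral_third_position(self):
        """Custom code where the amino acid is the first two bases: every
        third-position change is synonymous, every other change is not, so
        the ratio is exactly 2 for any ts_tv."""
        toy = {
            a + b + c: a + b for a in "ACG" for b in "ACG" for c in _BASES
        }
        usage = CodonUsageTable(
            {a + b + "A": 1.0 for a in "ACG" for b in "ACG"},
            allow_stops=True,
        )
        for ts_tv in (0.42, 0.5, 3.0):
            assert expected_ns_ratio(usage, ts_tv, code=toy) == pytest.approx(2.0)

    def test_monotone_in_ts_tv_for_standard_code(self):
        usage = CodonUsageTable.uniform()
        vals = [expected_ns_ratio(usage, t) for t in (0.1, 0.5, 1.0, 5.0, 50.0)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_invalid_ts_tv_raises(self):
        with pytest.raises(ValueError):
            expected_ns_ratio(CodonUsageTable.uniform(), 0.0)


class TestNsObservedTest:
    def test_observed_ratio_21_over_4(self):
        ratio, chi2, p = ns_observed_test(21, 4, 3.32)
        assert ratio == 5.25
        # hand-computed 1-df goodness-of-fit sum
        total = 25
        e_n = total * 3.32 / 4.32
        e_s = total - e_n
        hand = (21 - e_n) ** 2 / e_n + (4 - e_s) ** 2 / e_s
        assert chi2 == pytest.approx(hand)
        assert p == pytest.approx(sps.chi2.sf(hand, 1))

    def test_perfect_fit_gives_zero_chi_square(self):
        ratio, chi2, p = ns_observed_test(30, 10, 3.0)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_synonymous_gives_infinite_ratio(self):
        ratio, chi2, p = ns_observed_test(5, 0, 3.0)
        assert math.isinf(ratio)
        assert math.isfinite(chi2)


class TestSsrEnrichment:
    def test_zero_hits_give_p_one(self):
        assert ssr_enrichment_test(0, 10, 0.143) == 1.0

    def test_all_hits_at_half_probability(self):
        assert ssr_enrichment_test(10, 10, 0.5) == pytest.approx(2**-10)

    def test_matches_pmf_summation_oracle(self):
        for k, n, f in [(12, 37, 0.143), (24, 74, 0.143), (3, 20, 0.3)]:
            oracle = sum(
                math.comb(n, j) * f**j * (1 - f) ** (n - j)
                for j in range(k, n + 1)
            )
            assert ssr_enrichment_test(k, n, f) == pytest.approx(
                oracle, abs=1e-12
            )

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            ssr_enrichment_test(1, 10, 0.0)


class TestIndelAccounting:
    def _lines(self, n):
        return [MALine(f"l{i}", "L", 100, 1000, 600, 400) for i in range(n)]

    def test_net_loss_and_per_line_mean(self):
        net, per_line = indel_balance(545, 59, 37)
        assert net == 486
        assert round(per_line) == 13

    def test_single_line_requirement(self):
        with pytest.raises(ValueError):
            indel_balance(1, 1, 0)

    def test_no_indels_all_zero(self):
        acct = indel_accounting([], self._lines(3))
        assert acct.inserted_bp == acct.deleted_bp == 0
        assert acct.net_change_bp == 0
        assert math.isnan(acct.frac_3n)

    def test_totals_and_3n_fraction(self):
        lines = self._lines(2)
        muts = [
            Mutation("l0", "c", 5, "ATTT", "A", "deletion", 3, in_ssr=False),
            Mutation("l0", "c", 9, "AT", "A", "deletion", 1, in_ssr=True),
            Mutation("l1", "c", 5, "A", "ATTTTTT", "insertion", 6, in_ssr=False),
        ]
        acct = indel_accounting(muts, lines)
        assert acct.deleted_bp == 4
        assert acct.inserted_bp == 6
        assert acct.net_change_bp == 2
        assert acct.n_deletions == 2 and acct.n_insertions == 1
        assert acct.frac_3n == pytest.approx(2 / 3)
        assert acct.frac_3n_in_ssr == 0.0
        assert acct.frac_3n_out_ssr == 1.0
        assert acct.per_line_net_mean == pytest.approx((6 - 4) / 2)
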