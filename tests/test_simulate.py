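"""Tests for the synthetic MA-experiment generator."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest
from scipy import stats as sps

from mamut.model import SpectrumCounts
from mamut.simulate import (
    MAExperiment,
    SimulationConfig,
    SimulationError,
    generate_genome,
    simulate_ma_lines,
    write_experiment,
)
from mamut.ssr import find_ssrs


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = SimulationConfig()
        assert sum(cfg.spectrum_weights) == pytest.approx(1.0)
        assert sum(cfg.indel_length_distribution) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gc_content": 1.5},
            {"callable_fraction": 0.0},
            {"genome_length": 5000},
            {"mu_bs": -1e-9},
            {"ssr_slippage_multiplier": 0.5},
            {"spectrum_weights": (1, 2, 3)},
            {"generations_per_line": 0},
            {"deletion_fraction": 1.2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_per_line_generations_list(self):
        cfg = SimulationConfig(
            genome_length=20_000, n_lines=3, generations_per_line=[10, 20, 30]
        )
        assert cfg.generations_list() == [10.0, 20.0, 30.0]
        with pytest.raises(ValueError):
            SimulationConfig(
                genome_length=20_000, n_lines=2, generations_per_line=[10]
            )


class TestGenerateGenome:
    def test_realized_gc_close_to_target(self):
        cfg = SimulationConfig(
            genome_length=1_000_000, n_chromosomes=2, gc_content=0.225, seed=9
        )
        genome = generate_genome(cfg)
        assert 0.205 <= genome.gc_fraction() <= 0.245

    def test_no_ssrs_requested_none_planted(self):
        cfg = SimulationConfig(
            genome_length=50_000, n_chromosomes=1, ssr_target_fraction=0.0,
            gene_fraction=0.0, gc_content=0.5, seed=2,
        )
        genome = generate_genome(cfg)
        assert genome.ssr_loci == []
        # chance tracts in a random 50/50 sequence are rare and short: the
        # detector should find at most a handful of bp beyond expectation
        found = find_ssrs(genome.sequences())
        chance_bp = sum(l.length for l in found)
        assert chance_bp < 0.005 * cfg.genome_length

    def test_planted_ssr_fraction_recovered_from_truth(self):
        cfg = SimulationConfig(
            genome_length=1_000_000, n_chromosomes=1,
            ssr_target_fraction=0.143, seed=4,
        )
        genome = generate_genome(cfg)
        covered = sum(l.length for l in genome.ssr_loci)
        frac = covered / cfg.genome_length
        assert 0.114 <= frac <= 0.172

    def test_truth_loci_are_nonoverlapping_and_well_formed(self, small_genome):
        by_chrom = {}
        for l in small_genome.ssr_loci:
            by_chrom.setdefault(l.chrom, []).append(l)
        for loci in by_chrom.values():
            loci.sort(key=lambda l: l.start)
            for a, b in zip(loci, loci[1:]):
                assert a.end <= b.start
        for l in small_genome.ssr_loci:
            assert 1 <= l.unit_length <= 10
            assert l.copies >= 3

    def test_gene_models_valid(self, small_genome):
        genes = sorted(small_genome.gene_models, key=lambda g: (g.chrom, g.start))
        seen_end = {}
        for g in genes:
            assert g.cds_length % 3 == 0
            assert g.start >= seen_end.get(g.chrom, 0)
            seen_end[g.chrom] = g.end
            codes = small_genome.chromosomes[g.chrom]
            if g.strand == "+":
                trio = codes[g.start : g.start + 3]
                assert "".join("ACGT"[c] for c in trio) == "ATG"
            else:
                trio = codes[g.end - 3 : g.end]
                assert "".join("ACGT"[c] for c in trio) == "CAT"

    def test_unit_lengths_biased_toward_3_and_6(self):
        cfg = SimulationConfig(genome_length=500_000, n_chromosomes=1, seed=6)
        genome = generate_genome(cfg)
        units = np.array([l.unit_length for l in genome.ssr_loci])
        counts = np.bincount(units, minlength=11)
        assert counts[3] > counts[2] and counts[6] > counts[5]


class TestSimulateLines:
    def test_zero_rates_give_empty_truth(self):
        cfg = SimulationConfig(
            genome_length=20_000, n_chromosomes=1, n_lines=3,
            generations_per_line=10, mu_bs=0.0, mu_indel=0.0, seed=1,
        )
        exp = simulate_ma_lines(generate_genome(cfg), cfg)
        assert exp.truth.mutations == []
        assert all(v == 0 for v in exp.truth.per_line_event_counts.values())

    def test_saturating_rates_refused(self):
        cfg = SimulationConfig(
            genome_length=20_000, n_chromosomes=1, n_lines=1,
            generations_per_line=100, mu_bs=2e-3, mu_indel=0.0, seed=1,
        )
        with pytest.raises(SimulationError, match="saturat"):
            simulate_ma_lines(generate_genome(cfg), cfg)

    def test_mean_substitutions_match_poisson_expectation(self):
        """mu 1e-6 over ~1e6 callable sites and T=10 in 50 lines: the mean
        count per line should sit within 3 SEM of the expectation."""
        cfg = SimulationConfig(
            genome_length=1_000_000, n_chromosomes=1, n_lines=50,
            generations_per_line=10, callable_fraction=1.0,
            mu_bs=1e-6, mu_indel=0.0, mnm_fraction=0.0, seed=8,
        )
        genome = generate_genome(cfg)
        exp = simulate_ma_lines(genome, cfg)
        counts = {l.line_id: 0 for l in exp.lines}
        for m in exp.truth.mutations:
            counts[m.line_id] += 1
        per_line_expected = [
            cfg.mu_bs * l.callable_sites * l.generations for l in exp.lines
        ]
        mean_expected = np.mean(per_line_expected)
        sem = np.sqrt(mean_expected / cfg.n_lines)
        assert abs(np.mean(list(counts.values())) - mean_expected) <= 3 * sem

    def test_mutations_lie_inside_callable_masks(self, small_experiment):
        masks = {l.line_id: l.mask for l in small_experiment.lines}
        for m in small_experiment.truth.mutations:
            assert bool(masks[m.line_id].contains(m.chrom, m.pos - 1)[0])

    def test_ref_alleles_match_genome(self, small_experiment, small_genome):
        seqs = small_genome.sequences()
        for m in small_experiment.truth.mutations:
            ref = seqs[m.chrom][m.pos - 1 : m.pos - 1 + len(m.ref_allele)]
            assert ref == m.ref_allele

    def test_event_counts_treat_mnm_pairs_as_one(self, small_experiment):
        by_line_events = {}
        for m in small_experiment.truth.mutations:
            by_line_events.setdefault(m.line_id, set()).add(m.event_id)
        for line_id, events in by_line_events.items():
            assert (
                len(events)
                == small_experiment.truth.per_line_event_counts[line_id]
            )

    def test_mnm_fraction_recovered(self):
        """~10% of substitution events should be 50 bp pairs."""
        cfg = SimulationConfig(
            genome_length=500_000, n_chromosomes=1, n_lines=10,
            generations_per_line=20, mu_bs=1.2e-5, mu_indel=0.0,
            mnm_fraction=0.1, seed=21,
        )
        exp = simulate_ma_lines(generate_genome(cfg), cfg)
        sizes = {}
        for m in exp.truth.mutations:
            sizes[(m.line_id, m.event_id)] = sizes.get((m.line_id, m.event_id), 0) + 1
        n_events = len(sizes)
        n_pairs = sum(1 for v in sizes.values() if v >= 2)
        assert n_events > 800
        lo, hi = sps.binomtest(n_pairs, n_events, 0.1).proportion_ci(0.95)
        assert lo <= 0.1 <= hi
        # partners really are within the window, on one line and chromosome
        by_event = {}
        for m in exp.truth.mutations:
            by_event.setdefault((m.line_id, m.event_id), []).append(m)
        for members in by_event.values():
            if len(members) == 2:
                a, b = members
                assert a.chrom == b.chrom
                assert 1 <= abs(a.pos - b.pos) <= 50

    def test_spectrum_recovery_within_multinomial_ci(self):
        cfg = SimulationConfig(
            genome_length=500_000, n_chromosomes=1, n_lines=10,
            generations_per_line=20, mu_bs=1e-5, mu_indel=0.0,
            mnm_fraction=0.0, seed=33,
        )
        exp = simulate_ma_lines(generate_genome(cfg), cfg)
        subs = [m for m in exp.truth.mutations if m.mclass == "substitution"]
        assert len(subs) >= 500
        spec = SpectrumCounts.from_mutations(subs)
        for cls_name, weight in zip(spec.as_dict(), cfg.spectrum_weights):
            k = spec.as_dict()[cls_name]
            lo, hi = sps.binomtest(k, spec.total, weight).proportion_ci(0.95)
            assert lo <= weight <= hi, cls_name

    def test_slippage_indels_enriched_in_ssrs(self):
        cfg = SimulationConfig(
            genome_length=500_000, n_chromosomes=1, n_lines=10,
            generations_per_line=20, mu_bs=0.0, mu_indel=5e-6,
            ssr_slippage_multiplier=2.9, seed=12,
        )
        exp = simulate_ma_lines(generate_genome(cfg), cfg)
        indels = exp.truth.mutations
        assert len(indels) > 200
        in_frac = np.mean([m.in_ssr for m in indels])
        # expected fraction: 2.9 f / (2.9 f + (1-f)) at f ~ 0.143
        f = 0.143
        expected = 2.9 * f / (2.9 * f + (1 - f))
        assert in_frac == pytest.approx(expected, abs=0.06)
        # slippage indels change copy number by one unit of the tract motif
        for m in indels:
            assert 1 <= m.indel_length <= 30

    def test_deletion_bias_recovered(self):
        cfg = SimulationConfig(
            genome_length=300_000, n_chromosomes=1, n_lines=10,
            generations_per_line=20, mu_bs=0.0, mu_indel=5e-6,
            deletion_fraction=0.818, seed=13,
        )
        exp = simulate_ma_lines(generate_genome(cfg), cfg)
        n_del = sum(m.mclass == "deletion" for m in exp.truth.mutations)
        n = len(exp.truth.mutations)
        lo, hi = sps.binomtest(n_del, n, 0.818).proportion_ci(0.95)
        assert lo <= 0.818 <= hi


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(
            genome_length=50_000, n_chromosomes=2, n_lines=3,
            generations_per_line=20, mu_bs=1e-6, mu_indel=5e-7, seed=99,
        )
        outs = []
        for name in ("a", "b"):
            genome = generate_genome(cfg)
            exp = simulate_ma_lines(genome, cfg)
            out = tmp_path / name
            write_experiment(exp, out)
            outs.append(out)
        a, b = outs
        for rel in [
            "reference.fasta",
            "genes.gff3",
            "ssr_truth.bed",
            "metadata.tsv",
            "truth_mutations.tsv",
            "config.yaml",
        ]:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel
        for vcf in sorted((a / "lines").iterdir()):
            assert filecmp.cmp(vcf, b / "lines" / vcf.name, shallow=False)
        for bed in sorted((a / "masks").iterdir()):
            assert filecmp.cmp(bed, b / "masks" / bed.name, shallow=False)

    def test_different_line_seed_changes_mutations_not_genome(self):
        cfg = SimulationConfig(
            genome_length=30_000, n_chromosomes=1, n_lines=2,
            generations_per_line=20, mu_bs=5e-6, seed=7,
        )
        genome = generate_genome(cfg)
        e1 = simulate_ma_lines(genome, cfg, seed=1)
        e2 = simulate_ma_lines(genome, cfg, seed=2)
        k1 = {(m.line_id, m.chrom, m.pos) for m in e1.truth.mutations}
        k2 = {(m.line_id, m.chrom, m.pos) for m in e2.truth.mutations}
        assert k1 != k2
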