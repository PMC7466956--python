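"""Synthetic mutation-accumulation experiment generator.

Builds an AT-rich haploid genome with planted simple-sequence-repeat tracts
and protein-coding genes, then accumulates mutations independently in each MA
line under known parameters: Poisson substitution counts drawn from a
six-class spectrum, 1-30 bp indels with a deletion bias and an elevated
slippage rate inside SSR tracts, and a configurable fraction of substitution
events that spawn a paired substitution within 50 bp (multinucleotide
mutations).  Because every event is recorded in a truth set, each downstream
estimator can be tested by parameter recovery.

The default configuration mirrors the study conditions this generator
emulates: a ~77.5% AT genome with ~14.3% of sites in SSR tracts biased toward
3- and 6-bp units, 37 lines (19 "L" + 18 "QS"), ~81.3% of sites callable per
line, a substitution rate of 2.47e-11 and an indel rate of 4.93e-11 per site
per generation with an ~4.5:1 deletion bias.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as mio
from .effects import standard_code
from .intervals import GenomeMask
from .model import GeneModel, MALine, Mutation, SSRLocus, SUB_CLASSES
from .ssr import canonical_rotation

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "TruthMutation",
    "TruthSet",
    "MAExperiment",
    "generate_genome",
    "simulate_ma_lines",
    "write_experiment",
]


class SimulationError(RuntimeError):
    """Raised when a configuration is infeasible or saturating."""


_BASES = "ACGT"

# unit-length weights 1..10, biased toward 3- and 6-bp units as in the
# emulated genome
DEFAULT_UNIT_WEIGHTS = (2.0, 1.0, 4.0, 0.5, 0.5, 4.0, 0.25, 0.25, 0.25, 0.25)

# Six-class weights (order: SUB_CLASSES).  The A/T->G/C and G/C->A/T cells
# reproduce the observed 4+1 and 7+9 counts; the two GC-conservative
# transversion classes are split 13:3, roughly by target-site availability in
# a 77.5% AT genome.  Totals: 11 transitions vs 26 transversions.
DEFAULT_SPECTRUM_WEIGHTS = (4.0, 1.0, 13.0, 7.0, 9.0, 3.0)


def _default_indel_lengths() -> tuple[float, ...]:
    # truncated geometric over 1..30 bp, mean ~6.5 bp
    w = [(1 - 1 / 7) ** (k - 1) for k in range(1, 31)]
    total = sum(w)
    return tuple(x / total for x in w)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic MA experiment; defaults are study-scale."""

    genome_length: int = 34_000_000
    gc_content: float = 0.225
    n_chromosomes: int = 6
    ssr_target_fraction: float = 0.143
    ssr_unit_weights: Sequence[float] = DEFAULT_UNIT_WEIGHTS
    gene_fraction: float = 0.62
    n_lines: int = 37
    generations_per_line: float | Sequence[float] = 1500
    callable_fraction: float = 0.813
    mu_bs: float = 2.47e-11
    spectrum_weights: Sequence[float] = DEFAULT_SPECTRUM_WEIGHTS
    mu_indel: float = 4.93e-11
    deletion_fraction: float = 0.818
    indel_length_distribution: Sequence[float] = field(
        default_factory=_default_indel_lengths
    )
    ssr_slippage_multiplier: float = 2.9
    mnm_fraction: float = 0.12
    mnm_window: int = 50
    mask_window_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "ssr_target_fraction", "gene_fraction",
                     "deletion_fraction", "mnm_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.callable_fraction <= 1.0):
            raise ValueError("callable_fraction must be in (0, 1]")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000 bp")
        if self.n_chromosomes < 1 or self.n_lines < 1:
            raise ValueError("n_chromosomes and n_lines must be >= 1")
        if self.mu_bs < 0 or self.mu_indel < 0:
            raise ValueError("rates must be >= 0")
        if self.ssr_slippage_multiplier < 1:
            raise ValueError("ssr_slippage_multiplier must be >= 1")
        w = np.asarray(self.ssr_unit_weights, dtype=float)
        if w.size != 10 or np.any(w < 0) or w.sum() == 0:
            raise ValueError("ssr_unit_weights must be 10 non-negative weights")
        self.ssr_unit_weights = tuple(float(x) for x in w / w.sum())
        s = np.asarray(self.spectrum_weights, dtype=float)
        if s.size != 6 or np.any(s < 0) or s.sum() == 0:
            raise ValueError("spectrum_weights must be 6 non-negative weights")
        self.spectrum_weights = tuple(float(x) for x in s / s.sum())
        d = np.asarray(self.indel_length_distribution, dtype=float)
        if d.size != 30 or np.any(d < 0) or d.sum() == 0:
            raise ValueError(
                "indel_length_distribution must be 30 non-negative weights"
            )
        self.indel_length_distribution = tuple(float(x) for x in d / d.sum())
        for T in self.generations_list():
            if T < 1:
                raise ValueError("generations_per_line must all be >= 1")

    def generations_list(self) -> list[float]:
        g = self.generations_per_line
        if isinstance(g, (int, float)):
            return [float(g)] * self.n_lines
        g = [float(x) for x in g]
        if len(g) != self.n_lines:
            raise ValueError("generations_per_line list must have n_lines entries")
        return g

    def line_labels(self) -> list[tuple[str, str]]:
        """(line_id, lab) pairs; first ceil(n/2) lines belong to lab L."""
        n_l = (self.n_lines + 1) // 2
        out = []
        for i in range(self.n_lines):
            lab = "L" if i < n_l else "QS"
            idx = i + 1 if i < n_l else i - n_l + 1
            out.append((f"{lab}{idx:02d}", lab))
        return out

    def to_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "gc_content": self.gc_content,
            "n_chromosomes": self.n_chromosomes,
            "ssr_target_fraction": self.ssr_target_fraction,
            "ssr_unit_weights": list(self.ssr_unit_weights),
            "gene_fraction": self.gene_fraction,
            "n_lines": self.n_lines,
            "generations_per_line": (
                self.generations_per_line
                if isinstance(self.generations_per_line, (int, float))
                else list(self.generations_per_line)
            ),
            "callable_fraction": self.callable_fraction,
            "mu_bs": self.mu_bs,
            "spectrum_weights": list(self.spectrum_weights),
            "mu_indel": self.mu_indel,
            "deletion_fraction": self.deletion_fraction,
            "indel_length_distribution": list(self.indel_length_distribution),
            "ssr_slippage_multiplier": self.ssr_slippage_multiplier,
            "mnm_fraction": self.mnm_fraction,
            "mnm_window": self.mnm_window,
            "mask_window_bp": self.mask_window_bp,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SyntheticGenome:
    """Generated reference with its planted SSR and gene truth."""

    chromosomes: dict[str, np.ndarray]  # uint8 codes 0..3 (ACGT)
    ssr_loci: list[SSRLocus]
    gene_models: list[GeneModel]
    config: SimulationConfig

    def sequence(self, chrom: str) -> str:
        return "".join(_BASES[c] for c in self.chromosomes[chrom])

    def sequences(self) -> dict[str, str]:
        return {c: self.sequence(c) for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(a) for a in self.chromosomes.values())

    def gc_fraction(self) -> float:
        gc = sum(
            int(np.sum((a == 1) | (a == 2))) for a in self.chromosomes.values()
        )
        return gc / self.total_length


@dataclass
class TruthMutation(Mutation):
    """A simulated mutation carrying its event identity.

    Mutations sharing an ``event_id`` arose as one mutational event (an MNM
    pair counts as a single event).
    """

    event_id: int = -1


@dataclass
class TruthSet:
    """Everything the simulator knows to be true about one experiment."""

    mutations: list[TruthMutation]
    ssr_loci: list[SSRLocus]
    gene_models: list[GeneModel]
    per_line_event_counts: dict[str, int]


@dataclass
class MAExperiment:
    lines: list[MALine]
    truth: TruthSet
    genome: SyntheticGenome


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Generate the reference with planted SSR tracts and gene models."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    k = config.n_chromosomes
    base_len = config.genome_length // k
    lengths = [base_len + (config.genome_length % k if i == 0 else 0) for i in range(k)]

    chroms: dict[str, np.ndarray] = {}
    ssr_loci: list[SSRLocus] = []
    gene_models: list[GeneModel] = []
    gene_idx = 0
    for ci, clen in enumerate(lengths):
        name = f"chr{ci + 1}"
        seq = rng.choice(4, size=clen, p=probs).astype(np.uint8)
        occupied = np.zeros(clen, dtype=bool)
        ssr_loci.extend(
            _plant_ssrs(name, seq, occupied, config, rng)
        )
        genes, gene_idx = _plant_genes(name, seq, occupied, config, rng, gene_idx)
        gene_models.extend(genes)
        chroms[name] = seq
    return SyntheticGenome(chroms, ssr_loci, gene_models, config)


def _random_motif(u: int, probs, rng) -> np.ndarray:
    """A u-mer with minimal period u (so the tract's unit is unambiguous)."""
    for _ in range(50):
        motif = rng.choice(4, size=u, p=probs).astype(np.uint8)
        if u == 1:
            return motif
        if all(
            not np.array_equal(np.tile(motif[:p], u // p + 1)[:u], motif)
            for p in range(1, u)
        ):
            return motif
    # force aperiodicity by flipping the last base
    motif[-1] = (motif[-1] + 1) % 4
    return motif


def _plant_ssrs(chrom, seq, occupied, config, rng) -> list[SSRLocus]:
    clen = seq.size
    target_bp = config.ssr_target_fraction * clen
    if target_bp == 0:
        return []
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    loci: list[SSRLocus] = []
    planted = 0
    attempts = 0
    max_attempts = int(50 * target_bp / 20) + 1000
    units = np.arange(1, 11)
    while planted < target_bp:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"{chrom}: could not reach ssr_target_fraction="
                f"{config.ssr_target_fraction} after {attempts} placement "
                "attempts (constraint: non-overlapping tracts)"
            )
        u = int(rng.choice(units, p=config.ssr_unit_weights))
        copies = 2 + int(rng.geometric(0.25))  # mean 6, minimum 3
        tract = u * copies
        if tract + 2 >= clen:
            continue
        start = int(rng.integers(1, clen - tract - 1))
        if occupied[start - 1 : start + tract + 1].any():
            continue
        motif = _random_motif(u, probs, rng)
        seq[start : start + tract] = np.tile(motif, copies)
        # keep the tract maximal: break period-u continuation at both flanks
        if seq[start - 1] == seq[start - 1 + u]:
            seq[start - 1] = (seq[start - 1 + u] + 1 + rng.integers(3)) % 4
        end = start + tract
        if end < clen and seq[end] == seq[end - u]:
            seq[end] = (seq[end - u] + 1 + rng.integers(3)) % 4
        occupied[start:end] = True
        motif_str = "".join(_BASES[c] for c in motif)
        loci.append(
            SSRLocus(
                chrom=chrom,
                start=start,
                end=end,
                motif=canonical_rotation(motif_str),
                unit_length=u,
                copies=copies,
            )
        )
        planted += tract
    return loci


_ATG = np.array([0, 3, 2], dtype=np.uint8)  # ATG
_CAT = np.array([1, 0, 3], dtype=np.uint8)  # revcomp start codon


def _plant_genes(chrom, seq, ssr_occupied, config, rng, gene_idx):
    clen = seq.size
    genes: list[GeneModel] = []
    if config.gene_fraction == 0:
        return genes, gene_idx
    mean_codons = 450.0
    mean_gene = 3 * mean_codons
    f = config.gene_fraction
    mean_gap = max(mean_gene * (1 - f) / f, 1.0)
    pos = int(rng.geometric(1.0 / mean_gap))
    while True:
        n_codons = 50 + int(rng.geometric(1.0 / (mean_codons - 50)))
        glen = 3 * n_codons
        if pos + glen >= clen:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        trio = slice(pos, pos + 3) if strand == "+" else slice(
            pos + glen - 3, pos + glen
        )
        if ssr_occupied[trio].any():
            pos += 3  # slide past the repeat tract
            continue
        seq[trio] = _ATG if strand == "+" else _CAT
        gene_idx += 1
        genes.append(
            GeneModel(
                gene_id=f"g{gene_idx:05d}",
                chrom=chrom,
                strand=strand,
                segments=((pos, pos + glen),),
            )
        )
        pos += glen + 1 + int(rng.geometric(1.0 / mean_gap))
    return genes, gene_idx


# ---------------------------------------------------------------------------
# line simulation
# ---------------------------------------------------------------------------

# alt code for each (ref code, class index) pair; -1 = impossible
_ALT_FOR_CLASS = {
    0: {0: 2, 1: 1, 2: 3},  # A -> G, C, T for the three A:T classes
    3: {0: 1, 1: 2, 2: 0},  # T -> C, G, A
    2: {3: 0, 4: 3, 5: 1},  # G -> A, T, C for the three G:C classes
    1: {3: 3, 4: 0, 5: 2},  # C -> T, A, G
}


def simulate_ma_lines(
    genome: SyntheticGenome,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> MAExperiment:
    """Accumulate mutations independently in each MA line.

    ``seed`` (default: derived from ``config.seed``) controls the line
    simulation only, so several replicate experiments can share one genome.
    """
    config = config or genome.config
    root = np.random.SeedSequence(
        [config.seed if seed is None else int(seed), 1]
    )
    line_seeds = root.spawn(config.n_lines)

    chrom_names = list(genome.chromosomes)
    chrom_lens = {c: genome.chromosomes[c].size for c in chrom_names}
    offsets = {}
    off = 0
    for c in chrom_names:
        offsets[c] = off
        off += chrom_lens[c]
    total_len = off
    genome_codes = np.concatenate([genome.chromosomes[c] for c in chrom_names])
    starts_arr = np.array([offsets[c] for c in chrom_names])

    # global SSR occupancy for slippage stratification
    ssr_global = np.zeros(total_len, dtype=bool)
    loci_by_chrom: dict[str, list[SSRLocus]] = {}
    for locus in genome.ssr_loci:
        o = offsets[locus.chrom]
        ssr_global[o + locus.start : o + locus.end] = True
        loci_by_chrom.setdefault(locus.chrom, []).append(locus)
    loci_sorted = {
        c: sorted(ls, key=lambda l: l.start) for c, ls in loci_by_chrom.items()
    }
    loci_starts = {
        c: np.array([l.start for l in ls]) for c, ls in loci_sorted.items()
    }
    gene_sorted = sorted(genome.gene_models, key=lambda g: (g.chrom, g.start))

    def to_chrom(gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(starts_arr, gpos, side="right")) - 1
        c = chrom_names[ci]
        return c, gpos - offsets[c]

    spectrum = np.asarray(config.spectrum_weights)
    at_w = spectrum[:3]
    gc_w = spectrum[3:]
    gens = config.generations_list()
    labels = config.line_labels()

    lines: list[MALine] = []
    truth_muts: list[TruthMutation] = []
    event_counts: dict[str, int] = {}
    event_id = 0

    for li, ((line_id, lab), T) in enumerate(zip(labels, gens)):
        rng = np.random.default_rng(line_seeds[li])
        mask, callable_bool = _line_mask(genome, config, rng, chrom_names, offsets)
        callable_pos = np.flatnonzero(callable_bool)
        n = callable_pos.size
        if n == 0:
            raise SimulationError(f"{line_id}: zero callable sites")
        codes_at_callable = genome_codes[callable_pos]
        is_at = (codes_at_callable == 0) | (codes_at_callable == 3)
        at_pos = callable_pos[is_at]
        gc_pos = callable_pos[~is_at]
        n_at, n_gc = at_pos.size, gc_pos.size

        in_ssr_callable = ssr_global[callable_pos]
        n_in = int(in_ssr_callable.sum())
        n_out = n - n_in
        exp_sub = config.mu_bs * n * T
        exp_indel = config.mu_indel * T * (
            n_out + config.ssr_slippage_multiplier * n_in
        )
        if exp_sub + exp_indel > 0.1 * n:
            raise SimulationError(
                f"{line_id}: expected mutation count {exp_sub + exp_indel:.3g} "
                f"exceeds 10% of callable sites ({n}); rates are saturating"
            )

        lines.append(
            MALine(
                line_id=line_id,
                lab=lab,
                generations=T,
                callable_sites=n,
                callable_AT_sites=int(n_at),
                callable_GC_sites=int(n_gc),
                mask=mask,
            )
        )

        used: dict[int, int] = {}  # global position -> index into line_muts
        line_muts: list[TruthMutation] = []
        n_events = 0

        def place_substitution(gpos: int, cls: int, ev: int) -> None:
            chrom, cpos = to_chrom(gpos)
            ref_code = int(genome_codes[gpos])
            alt_code = _ALT_FOR_CLASS[ref_code][cls]
            line_muts.append(
                TruthMutation(
                    line_id=line_id,
                    chrom=chrom,
                    pos=cpos + 1,
                    ref_allele=_BASES[ref_code],
                    alt_allele=_BASES[alt_code],
                    mclass="substitution",
                    in_ssr=bool(ssr_global[gpos]),
                    event_id=ev,
                )
            )
            used[gpos] = len(line_muts) - 1

        # substitutions -------------------------------------------------
        n_primary = (
            rng.poisson(exp_sub / (1.0 + config.mnm_fraction))
            if exp_sub > 0
            else 0
        )
        classes = (
            rng.choice(6, size=n_primary, p=spectrum) if n_primary else []
        )
        for cls in classes:
            pool = at_pos if cls < 3 else gc_pos
            if pool.size == 0:
                continue
            for _ in range(100):
                gpos = int(pool[rng.integers(pool.size)])
                if gpos not in used:
                    break
            else:  # pragma: no cover - saturation is refused above
                continue
            event_id += 1
            n_events += 1
            place_substitution(gpos, int(cls), event_id)
            if rng.random() < config.mnm_fraction:
                w = config.mnm_window
                for _ in range(50):
                    offset = int(rng.integers(-w, w + 1))
                    p2 = gpos + offset
                    if offset == 0 or p2 < 0 or p2 >= total_len or p2 in used:
                        continue
                    c1, _ = to_chrom(gpos)
                    c2, _ = to_chrom(p2)
                    if c1 != c2 or not callable_bool[p2]:
                        continue
                    ref2 = int(genome_codes[p2])
                    wts = at_w if ref2 in (0, 3) else gc_w
                    if wts.sum() == 0:
                        continue
                    cls2 = int(rng.choice(3, p=wts / wts.sum()))
                    if ref2 not in (0, 3):
                        cls2 += 3
                    place_substitution(p2, cls2, event_id)
                    break

        # indels --------------------------------------------------------
        n_indel = rng.poisson(exp_indel) if exp_indel > 0 else 0
        p_in = (
            config.ssr_slippage_multiplier * n_in / (
                n_out + config.ssr_slippage_multiplier * n_in
            )
            if n > 0 and (n_out + n_in) > 0
            else 0.0
        )
        ssr_pool = callable_pos[in_ssr_callable]
        out_pool = callable_pos[~in_ssr_callable]
        for _ in range(n_indel):
            inside = rng.random() < p_in and ssr_pool.size > 0
            mut = None
            for _try in range(50):
                if inside:
                    gpos = int(ssr_pool[rng.integers(ssr_pool.size)])
                    mut = _slippage_indel(
                        gpos, genome, config, rng, offsets, to_chrom,
                        loci_sorted, loci_starts, line_id, callable_bool,
                    )
                else:
                    if out_pool.size == 0:
                        break
                    gpos = int(out_pool[rng.integers(out_pool.size)])
                    mut = _free_indel(
                        gpos, genome_codes, total_len, config, rng, to_chrom,
                        line_id,
                    )
                if mut is not None:
                    break
            if mut is None:
                continue
            # overlap resolution: a later event replaces any earlier event
            # it touches at the same site(s)
            o = offsets[mut.chrom]
            a, b = mut.affected_interval()
            span = range(o + a, o + b)
            clobbered = {used[p] for p in span if p in used}
            if clobbered:
                logger.warning(
                    "%s: event at %s:%d overwrites %d earlier event(s)",
                    line_id,
                    mut.chrom,
                    mut.pos,
                    len(clobbered),
                )
                for idx in clobbered:
                    line_muts[idx] = None  # type: ignore[call-overload]
            event_id += 1
            n_events += 1
            mut.event_id = event_id
            line_muts.append(mut)
            for p in span:
                used[p] = len(line_muts) - 1

        kept = [m for m in line_muts if m is not None]
        # recount events over surviving mutations (clobbered ones vanish)
        event_counts[line_id] = len({m.event_id for m in kept})
        # truth in_ssr for indels via overlap with planted tracts
        for m in kept:
            if m.mclass != "substitution":
                a, b = m.affected_interval()
                o = offsets[m.chrom]
                m.in_ssr = bool(ssr_global[o + a : o + b].any())
            _truth_region_effect(m, gene_sorted, genome)
        truth_muts.extend(kept)

    truth = TruthSet(
        mutations=truth_muts,
        ssr_loci=genome.ssr_loci,
        gene_models=genome.gene_models,
        per_line_event_counts=event_counts,
    )
    return MAExperiment(lines=lines, truth=truth, genome=genome)


def _line_mask(genome, config, rng, chrom_names, offsets):
    """Blocky callable mask: keep an exact fraction of fixed-size windows."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    total = sum(genome.chromosomes[c].size for c in chrom_names)
    callable_bool = np.zeros(total, dtype=bool)
    w = config.mask_window_bp
    for c in chrom_names:
        clen = genome.chromosomes[c].size
        n_win = (clen + w - 1) // w
        n_keep = int(round(config.callable_fraction * n_win))
        keep = rng.permutation(n_win)[:n_keep]
        keep.sort()
        intervals = [(int(k) * w, min((int(k) + 1) * w, clen)) for k in keep]
        if intervals:
            ivs[c] = intervals
            o = offsets[c]
            for s, e in intervals:
                callable_bool[o + s : o + e] = True
    return GenomeMask(ivs), callable_bool


def _slippage_indel(
    gpos, genome, config, rng, offsets, to_chrom, loci_sorted, loci_starts,
    line_id, callable_bool,
):
    """+-1 repeat-unit slippage at the SSR tract containing gpos."""
    chrom, cpos = to_chrom(gpos)
    ls = loci_sorted.get(chrom)
    if not ls:
        return None
    idx = int(np.searchsorted(loci_starts[chrom], cpos, side="right")) - 1
    if idx < 0:
        return None
    locus = ls[idx]
    if not (locus.start <= cpos < locus.end):
        return None
    u = locus.unit_length
    if locus.start < 1:
        return None  # no anchor base available
    if not callable_bool[offsets[chrom] + locus.start - 1]:
        return None  # anchor base must itself be callable
    seq = genome.chromosomes[chrom]
    anchor = locus.start - 1
    anchor_base = _BASES[seq[anchor]]
    unit = "".join(_BASES[c] for c in seq[locus.start : locus.start + u])
    if rng.random() < config.deletion_fraction:
        ref = anchor_base + unit
        alt = anchor_base
        mclass = "deletion"
    else:
        ref = anchor_base
        alt = anchor_base + unit
        mclass = "insertion"
    return TruthMutation(
        line_id=line_id,
        chrom=chrom,
        pos=anchor + 1,
        ref_allele=ref,
        alt_allele=alt,
        mclass=mclass,
        indel_length=u,
        in_ssr=True,
    )


def _free_indel(gpos, genome_codes, total_len, config, rng, to_chrom, line_id):
    """A 1-30 bp indel anchored at a callable non-SSR site."""
    chrom, cpos = to_chrom(gpos)
    length = 1 + int(rng.choice(30, p=config.indel_length_distribution))
    anchor_base = _BASES[genome_codes[gpos]]
    if rng.random() < config.deletion_fraction:
        # need `length` reference bases after the anchor on the same chromosome
        c_end, _ = to_chrom(min(gpos + length, total_len - 1))
        if gpos + length >= total_len or c_end != chrom:
            return None
        span = genome_codes[gpos + 1 : gpos + 1 + length]
        ref = anchor_base + "".join(_BASES[c] for c in span)
        return TruthMutation(
            line_id=line_id,
            chrom=chrom,
            pos=cpos + 1,
            ref_allele=ref,
            alt_allele=anchor_base,
            mclass="deletion",
            indel_length=length,
        )
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ins = "".join(_BASES[c] for c in rng.choice(4, size=length, p=probs))
    return TruthMutation(
        line_id=line_id,
        chrom=chrom,
        pos=cpos + 1,
        ref_allele=anchor_base,
        alt_allele=anchor_base + ins,
        mclass="insertion",
        indel_length=length,
    )


_CODE_TABLE = standard_code()
_COMP_STR = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _truth_region_effect(mut: TruthMutation, genes_sorted, genome) -> None:
    """Record the true coding context of a simulated mutation."""
    pos0 = mut.pos - 1
    gene = None
    for g in genes_sorted:
        if g.chrom == mut.chrom and g.start <= pos0 < g.end:
            gene = g
            break
    if gene is None:
        mut.region = "noncoding"
        mut.effect = "noncoding" if mut.mclass == "substitution" else "noncoding"
        return
    mut.region = "coding"
    if mut.mclass != "substitution":
        mut.effect = "NA"
        return
    seq = genome.chromosomes[gene.chrom]
    off = pos0 - gene.start
    if gene.strand == "-":
        off = (gene.end - gene.start) - 1 - off
    codon_idx, within = divmod(off, 3)
    if gene.strand == "+":
        cstart = gene.start + 3 * codon_idx
        codon = "".join(_BASES[c] for c in seq[cstart : cstart + 3])
        alt = mut.alt_allele
    else:
        cend = gene.end - 3 * codon_idx
        codon = "".join(
            _COMP_STR[_BASES[c]] for c in seq[cend - 3 : cend][::-1]
        )
        alt = _COMP_STR[mut.alt_allele]
    mutant = codon[:within] + alt + codon[within + 1 :]
    mut.effect = (
        "synonymous"
        if _CODE_TABLE.get(codon, "X") == _CODE_TABLE.get(mutant, "Y")
        else "nonsynonymous"
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_experiment(exp: MAExperiment, out_dir) -> dict[str, str]:
    """Write the complete synthetic experiment to disk.

    Emits reference FASTA, per-line VCF + callable-mask BED, SSR-truth BED,
    gene-model GFF3, metadata and truth TSVs and a YAML config echo.  Output
    is deterministic byte-for-byte for a fixed config and seed.
    """
    out = Path(out_dir)
    (out / "lines").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    ref = exp.genome.sequences()
    paths = {"reference": str(out / "reference.fasta")}
    mio.write_fasta(ref, paths["reference"])
    mio.write_gff3(exp.truth.gene_models, out / "genes.gff3")
    paths["genes"] = str(out / "genes.gff3")
    from .ssr import write_ssr_bed

    write_ssr_bed(exp.truth.ssr_loci, out / "ssr_truth.bed")
    paths["ssr_truth"] = str(out / "ssr_truth.bed")

    by_line: dict[str, list[TruthMutation]] = {l.line_id: [] for l in exp.lines}
    for m in exp.truth.mutations:
        by_line[m.line_id].append(m)
    rows = []
    for line in exp.lines:
        vcf_path = out / "lines" / f"{line.line_id}.vcf"
        mask_path = out / "masks" / f"{line.line_id}.bed"
        mio.write_vcf(by_line[line.line_id], ref, vcf_path, sample=line.line_id)
        line.mask.to_bed(mask_path)
        rows.append(
            f"{line.line_id}\t{line.lab}\t{line.generations:g}\t"
            f"lines/{line.line_id}.vcf\tmasks/{line.line_id}.bed"
        )
    with open(out / "metadata.tsv", "w") as fh:
        fh.write("line_id\tlab\tgenerations\tvcf_path\tmask_path\n")
        fh.write("\n".join(rows) + "\n")
    paths["metadata"] = str(out / "metadata.tsv")

    with open(out / "truth_mutations.tsv", "w") as fh:
        fh.write(
            "line_id\tchrom\tpos\tref\talt\tmclass\tindel_length\tin_ssr\t"
            "region\teffect\tevent_id\n"
        )
        for m in sorted(
            exp.truth.mutations, key=lambda m: (m.line_id, m.chrom, m.pos)
        ):
            fh.write(
                f"{m.line_id}\t{m.chrom}\t{m.pos}\t{m.ref_allele}\t"
                f"{m.alt_allele}\t{m.mclass}\t{m.indel_length}\t"
                f"{int(m.in_ssr)}\t{m.region}\t{m.effect}\t{m.event_id}\n"
            )
    paths["truth"] = str(out / "truth_mutations.tsv")

    cfg = exp.genome.config.to_dict()
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        fh.write(cfg_text)
    paths["config"] = str(out / "config.yaml")
    paths["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
    return paths
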