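"""Simple-sequence-repeat (microsatellite) detection and variant context.

SSRs are tandem repeats of a 1-10 bp motif.  They are replication-slippage
hotspots, and in AT-rich genomes such as the one studied here they can cover a
double-digit percentage of all sites, so every variant is flagged by SSR
context before rates are split by compartment.

The scan reports every *maximal perfect* tandem tract whose unit length is at
most ``max_unit``, with at least ``min_copies`` complete copies and a total
tract length of at least ``min_tract_bp``.  A tract is attributed to its
smallest repeating unit ("AAAA" is a homopolymer, not a 2-mer repeat), and
overlapping candidate tracts are resolved greedily left-to-right (longer
tract first at equal start; smaller unit breaks remaining ties).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomeMask, merge_intervals
from .model import Mutation, SSRLocus

__all__ = [
    "find_ssrs",
    "annotate_variants_ssr",
    "ssr_genome_fraction",
    "canonical_rotation",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGTN"


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if np.any(out == 255):
        bad = chr(arr[np.argmax(out == 255)])
        raise ValueError(f"illegal character {bad!r} in sequence")
    return out


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _minimal_period(codes: np.ndarray, max_check: int) -> int:
    """Smallest period p <= max_check of the array, or max_check+1 if none."""
    n = codes.size
    for p in range(1, max_check + 1):
        if n > p and np.array_equal(codes[p:], codes[:-p]):
            return p
    return max_check + 1


def find_ssrs(
    reference: Mapping[str, str],
    min_copies: int = 3,
    min_tract_bp: int = 8,
    max_unit: int = 10,
) -> list[SSRLocus]:
    """Scan reference sequences for perfect tandem repeats.

    Parameters mirror the conventional thresholds: motifs of 1-10 bp, at
    least 3 complete copies, tract at least 8 bp.  N bases never match.
    """
    if max_unit > 10:
        raise ValueError("max_unit must be <= 10")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    loci: list[SSRLocus] = []
    for chrom in reference:
        codes = (
            reference[chrom]
            if isinstance(reference[chrom], np.ndarray)
            else _encode(reference[chrom])
        )
        loci.extend(_scan_chrom(chrom, codes, min_copies, min_tract_bp, max_unit))
    return loci


def _scan_chrom(
    chrom: str,
    codes: np.ndarray,
    min_copies: int,
    min_tract_bp: int,
    max_unit: int,
) -> list[SSRLocus]:
    n = codes.size
    candidates: list[tuple[int, int, int]] = []  # (start, end, unit)
    for u in range(1, max_unit + 1):
        if n <= u:
            break
        eq = codes[u:] == codes[:-u]
        eq &= (codes[u:] != _CODE["N"]) & (codes[:-u] != _CODE["N"])
        padded = np.concatenate(([0], eq.view(np.int8), [0]))
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for a, b in zip(run_starts, run_ends):
            # eq true on [a, b) means codes[a : b + u) has period u
            length = b - a + u
            if length // u < min_copies or length < min_tract_bp:
                continue
            # attribute to the smallest period only
            if _minimal_period(codes[a : a + length], u - 1) <= u - 1:
                continue
            candidates.append((a, a + length, u))

    # greedy left-to-right resolution: earliest start wins; at equal start the
    # longer tract, then the smaller unit
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    kept: list[SSRLocus] = []
    cur_end = -1
    base_str = "ACGTN"
    for s, e, u in candidates:
        if s < cur_end:
            continue
        motif = "".join(base_str[c] for c in codes[s : s + u])
        kept.append(
            SSRLocus(
                chrom=chrom,
                start=int(s),
                end=int(e),
                motif=canonical_rotation(motif),
                unit_length=u,
                copies=int((e - s) // u),
            )
        )
        cur_end = e
    return kept


def annotate_variants_ssr(
    mutations: Iterable[Mutation],
    ssr_loci: Sequence[SSRLocus],
    flank_bp: int = 0,
) -> list[Mutation]:
    """Set ``in_ssr`` on each mutation by interval overlap with SSR loci.

    A substitution is in an SSR iff its position lies inside a locus; an
    indel iff its affected interval (anchor plus inserted/deleted span)
    overlaps a locus.  ``flank_bp`` widens the affected interval.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {l.chrom for l in ssr_loci}:
        ivs = merge_intervals(
            [(l.start, l.end) for l in ssr_loci if l.chrom == chrom]
        )
        by_chrom[chrom] = (ivs[:, 0], ivs[:, 1])
    muts = list(mutations)
    for m in muts:
        if m.chrom not in by_chrom:
            m.in_ssr = False
            continue
        starts, ends = by_chrom[m.chrom]
        a, b = m.affected_interval()
        a -= flank_bp
        b += flank_bp
        idx = int(np.searchsorted(starts, b, side="left"))
        m.in_ssr = idx > 0 and ends[idx - 1] > a
    return muts


def ssr_genome_fraction(
    ssr_loci: Sequence[SSRLocus], mask: GenomeMask
) -> float:
    """Fraction of callable sites lying inside SSR loci."""
    total = mask.total_bases()
    if total == 0:
        raise ValueError("empty callable mask")
    if not ssr_loci:
        return 0.0
    locus_mask = GenomeMask(
        {
            chrom: [(l.start, l.end) for l in ssr_loci if l.chrom == chrom]
            for chrom in {l.chrom for l in ssr_loci}
        }
    )
    return locus_mask.intersect(mask).total_bases() / total


def write_ssr_bed(ssr_loci: Sequence[SSRLocus], path) -> None:
    """Write loci as BED with name ``motif x copies`` and homopolymer flag."""
    loci = sorted(ssr_loci, key=lambda l: (l.chrom, l.start))
    with open(path, "w") as fh:
        for l in loci:
            flag = "homopolymer" if l.homopolymer else "multimer"
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.motif}x{l.copies}\t0\t+\t{flag}\n"
            )
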