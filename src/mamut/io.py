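"""Readers and writers for the experiment's on-disk formats.

Reads FASTA references (Biopython), single-sample VCFs (cyvcf2), BED callable
masks, GFF3 gene models (gffutils) and a metadata TSV listing the MA lines.
Internally everything is 0-based half-open; VCF stays 1-based and GFF3
1-based inclusive at the file boundary, per each format's convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .intervals import GenomeMask
from .model import GeneModel, MALine, Mutation

logger = logging.getLogger(__name__)

__all__ = [
    "read_reference",
    "base_counts",
    "read_callable_mask",
    "read_line_variants",
    "read_gene_models",
    "read_metadata",
    "load_experiment",
    "write_fasta",
    "write_vcf",
    "write_gff3",
]

_ALLOWED = set("ACGTN")


def read_reference(path) -> dict[str, str]:
    """Read a FASTA reference; sequences uppercased and validated."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {rec.id!r}: illegal characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def base_counts(reference: Mapping[str, str]) -> dict[str, dict[str, int]]:
    """Per-chromosome length and A+T / G+C / N counts."""
    out = {}
    for chrom, seq in reference.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        at = int(np.sum((arr == ord("A")) | (arr == ord("T"))))
        gc = int(np.sum((arr == ord("G")) | (arr == ord("C"))))
        out[chrom] = {
            "length": len(seq),
            "AT": at,
            "GC": gc,
            "N": len(seq) - at - gc,
        }
    return out


def _gc_cumsums(reference: Mapping[str, str]):
    """Cumulative AT/GC indicator sums for fast masked base counting."""
    cums = {}
    for chrom, seq in reference.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_at = (arr == ord("A")) | (arr == ord("T"))
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        cums[chrom] = (
            np.concatenate(([0], np.cumsum(is_at))),
            np.concatenate(([0], np.cumsum(is_gc))),
        )
    return cums


def read_callable_mask(
    path, reference: Mapping[str, str]
) -> tuple[GenomeMask, int, int, int]:
    """Read a BED callable mask; returns (mask, n, n_AT, n_GC).

    Overlapping intervals are merged; ``n`` counts covered non-N positions.
    """
    lengths = {c: len(s) for c, s in reference.items()}
    mask = GenomeMask.from_bed(path, lengths)
    return (mask,) + mask_site_counts(mask, reference)


def mask_site_counts(
    mask: GenomeMask, reference: Mapping[str, str]
) -> tuple[int, int, int]:
    """(n, n_AT, n_GC) of a mask over the reference (N excluded from n)."""
    cums = _gc_cumsums(reference)
    n_at = n_gc = 0
    for chrom in mask.chromosomes:
        if chrom not in cums:
            raise ValueError(f"mask chromosome {chrom!r} absent from reference")
        cat, cgc = cums[chrom]
        iv = mask.intervals(chrom)
        n_at += int((cat[iv[:, 1]] - cat[iv[:, 0]]).sum())
        n_gc += int((cgc[iv[:, 1]] - cgc[iv[:, 0]]).sum())
    return n_at + n_gc, n_at, n_gc


@dataclass
class VariantReadStats:
    """Counts of records dropped while reading one line's VCF."""

    n_kept: int = 0
    n_long_indels: int = 0
    n_outside_mask: int = 0
    n_split_multiallelic: int = 0


def read_line_variants(
    vcf_path,
    line: MALine,
    reference: Mapping[str, str],
    split_multiallelic: bool = False,
    max_indel: int = 30,
) -> tuple[list[Mutation], VariantReadStats]:
    """Read and classify one MA line's variant calls.

    Indels longer than ``max_indel`` bp and calls outside the line's callable
    mask are dropped (counted in the returned stats).  Multi-allelic records
    raise unless ``split_multiallelic`` (MA lines are haploid single-colony
    isolates; multi-allelic calls indicate upstream problems).  A REF allele
    that disagrees with the reference sequence is a hard error.
    """
    stats = VariantReadStats()
    mutations: list[Mutation] = []
    for rec in VCF(str(vcf_path)):
        alts = rec.ALT
        if len(alts) > 1:
            if not split_multiallelic:
                raise ValueError(
                    f"{vcf_path}: multi-allelic record at {rec.CHROM}:{rec.POS}"
                )
            stats.n_split_multiallelic += 1
        if rec.CHROM not in reference:
            raise ValueError(f"{vcf_path}: unknown chromosome {rec.CHROM}")
        chrom_seq = reference[rec.CHROM]
        pos = rec.POS  # 1-based
        ref = rec.REF.upper()
        if pos < 1 or pos - 1 + len(ref) > len(chrom_seq):
            raise ValueError(
                f"{vcf_path}: coordinates out of range at {rec.CHROM}:{pos}"
            )
        if chrom_seq[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ValueError(
                f"{vcf_path}: REF mismatch at {rec.CHROM}:{pos} "
                f"(file {ref}, reference "
                f"{chrom_seq[pos - 1:pos - 1 + len(ref)]})"
            )
        for alt in alts:
            alt = alt.upper()
            if len(ref) == len(alt) == 1:
                mclass, net = "substitution", 0
            else:
                net = len(alt) - len(ref)
                if net == 0:
                    logger.warning(
                        "length-preserving complex record at %s:%s skipped",
                        rec.CHROM,
                        pos,
                    )
                    continue
                mclass = "insertion" if net > 0 else "deletion"
                if abs(net) > max_indel:
                    stats.n_long_indels += 1
                    continue
            if line.mask is not None and not bool(
                line.mask.contains(rec.CHROM, pos - 1)[0]
            ):
                stats.n_outside_mask += 1
                continue
            mutations.append(
                Mutation(
                    line_id=line.line_id,
                    chrom=rec.CHROM,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    mclass=mclass,
                    indel_length=abs(net),
                    complex_flag=len(ref) > 1 and len(alt) > 1,
                )
            )
            stats.n_kept += 1
    return mutations, stats


def read_gene_models(path) -> tuple[list[GeneModel], int]:
    """Read CDS features from a GFF3 file, grouped per gene.

    Genes whose total CDS length is not a multiple of 3 are excluded with a
    warning; the count of exclusions is returned alongside the models.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID") or [
            f"cds_{cds.seqid}_{cds.start}"
        ]
        key = parents[0]
        info = grouped.setdefault(
            key, {"chrom": cds.seqid, "strand": cds.strand, "segments": []}
        )
        # GFF3 is 1-based inclusive
        info["segments"].append((cds.start - 1, cds.end))
    models: list[GeneModel] = []
    n_excluded = 0
    for gene_id in sorted(grouped):
        info = grouped[gene_id]
        segments = tuple(sorted(info["segments"]))
        total = sum(e - s for s, e in segments)
        if total % 3 != 0:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3; excluded",
                gene_id,
                total,
            )
            n_excluded += 1
            continue
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=info["chrom"],
                strand=info["strand"] if info["strand"] in "+-" else "+",
                segments=segments,
            )
        )
    return models, n_excluded


def read_metadata(path) -> pd.DataFrame:
    """Read the experiment metadata TSV.

    Columns: line_id, lab, generations, vcf_path, mask_path (paths relative
    to the TSV's directory unless absolute).
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "lab": str})
    required = {"line_id", "lab", "generations", "vcf_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    base = Path(path).parent
    for col in ("vcf_path", "mask_path"):
        df[col] = [
            str(p) if Path(p).is_absolute() else str(base / p) for p in df[col]
        ]
    return df


def load_experiment(
    metadata_path, reference: Mapping[str, str], split_multiallelic: bool = False
) -> tuple[list[MALine], list[Mutation], dict[str, VariantReadStats]]:
    """Load all lines named in a metadata TSV: masks, then variants."""
    meta = read_metadata(metadata_path)
    lines: list[MALine] = []
    mutations: list[Mutation] = []
    stats: dict[str, VariantReadStats] = {}
    for row in meta.itertuples(index=False):
        mask, n, n_at, n_gc = read_callable_mask(row.mask_path, reference)
        line = MALine(
            line_id=row.line_id,
            lab=row.lab,
            generations=float(row.generations),
            callable_sites=n,
            callable_AT_sites=n_at,
            callable_GC_sites=n_gc,
            mask=mask,
        )
        muts, st = read_line_variants(
            row.vcf_path, line, reference, split_multiallelic=split_multiallelic
        )
        lines.append(line)
        mutations.extend(muts)
        stats[line.line_id] = st
    return lines, mutations, stats


# ---------------------------------------------------------------------------
# writers (plain-text; deterministic byte-for-byte for fixed inputs)
# ---------------------------------------------------------------------------


def write_fasta(reference: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in reference:
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(
    mutations: Sequence[Mutation],
    reference: Mapping[str, str],
    path,
    sample: str = "sample",
) -> None:
    """Write mutations of one line as a minimal single-sample VCF v4.2."""
    muts = sorted(mutations, key=lambda m: (m.chrom, m.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for m in muts:
            fh.write(
                f"{m.chrom}\t{m.pos}\t.\t{m.ref_allele}\t{m.alt_allele}"
                "\t.\tPASS\t.\tGT\t1\n"
            )


def write_gff3(gene_models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(gene_models, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tmamut\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            phase = 0
            segs = g.segments if g.strand == "+" else tuple(reversed(g.segments))
            for s, e in sorted(segs):
                fh.write(
                    f"{g.chrom}\tmamut\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )
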