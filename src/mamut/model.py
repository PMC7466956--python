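"""Core data model for mutation-accumulation (MA) experiment analysis.

An MA experiment propagates many lines of a haploid organism through repeated
single-cell bottlenecks, so that spontaneous mutations fix essentially
neutrally.  The objects here carry what the downstream estimators need: one
record per line (generations ``T`` and callable-site counts ``n``), one record
per called mutation, the six strand-symmetric substitution classes, and rate
estimates with their bootstrap intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "SUB_CLASSES",
    "MALine",
    "Mutation",
    "SpectrumCounts",
    "RateEstimate",
    "SSRLocus",
    "GeneModel",
    "MNMCluster",
    "NeEstimate",
    "classify_substitution",
]

#: The six strand-symmetric substitution classes.  A base substitution on a
#: double-stranded genome is identified with its complement, so e.g. A->G and
#: T->C are both "A:T -> G:C transition".
SUB_CLASSES = (
    "AT_to_GC_ts",
    "AT_to_CG_tv",
    "AT_to_TA_tv",
    "GC_to_AT_ts",
    "GC_to_TA_tv",
    "GC_to_CG_tv",
)

_PAIR_TO_CLASS = {
    ("A", "G"): "AT_to_GC_ts",
    ("T", "C"): "AT_to_GC_ts",
    ("A", "C"): "AT_to_CG_tv",
    ("T", "G"): "AT_to_CG_tv",
    ("A", "T"): "AT_to_TA_tv",
    ("T", "A"): "AT_to_TA_tv",
    ("G", "A"): "GC_to_AT_ts",
    ("C", "T"): "GC_to_AT_ts",
    ("G", "T"): "GC_to_TA_tv",
    ("C", "A"): "GC_to_TA_tv",
    ("G", "C"): "GC_to_CG_tv",
    ("C", "G"): "GC_to_CG_tv",
}


def classify_substitution(ref: str, alt: str) -> str:
    """Return the strand-symmetric class of a single-base substitution."""
    try:
        return _PAIR_TO_CLASS[(ref.upper(), alt.upper())]
    except KeyError:
        raise ValueError(f"not a substitution: {ref!r} -> {alt!r}") from None


@dataclass
class MALine:
    """One mutation-accumulation lineage.

    Parameters
    ----------
    line_id : str
        Laboratory label of the line (e.g. ``"L03"``).
    lab : str
        Originating lab/experiment group (``"L"``, ``"QS"`` or other).
    generations : float
        Number of cell divisions accumulated by the line (``T``).
    callable_sites : int
        Number of reference positions with sufficient coverage to have
        detected a mutation (``n``); the rate denominator together with ``T``.
    callable_AT_sites, callable_GC_sites : int
        Callable positions whose reference base is A/T resp. G/C.  They may
        sum to less than ``callable_sites`` when the mask covers N bases.
    mask : GenomeMask, optional
        The callable intervals themselves (0-based half-open per chromosome).
    """

    line_id: str
    lab: str
    generations: float
    callable_sites: int
    callable_AT_sites: int = 0
    callable_GC_sites: int = 0
    mask: object | None = None

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError(f"{self.line_id}: generations must be > 0")
        if self.callable_sites <= 0:
            raise ValueError(f"{self.line_id}: callable_sites must be > 0")
        if self.callable_AT_sites + self.callable_GC_sites > self.callable_sites:
            raise ValueError(
                f"{self.line_id}: AT + GC callable sites exceed callable_sites"
            )


@dataclass
class Mutation:
    """One called mutational change in one MA line.

    ``pos`` is the 1-based reference coordinate of the changed base for
    substitutions, or of the anchor base for indels (VCF left-anchoring:
    the indel's REF/ALT share their first base).
    """

    line_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    mclass: str  # substitution | insertion | deletion
    indel_length: int = 0
    in_ssr: bool = False
    region: str = "NA"  # coding | noncoding | NA
    effect: str = "NA"  # synonymous | nonsynonymous | noncoding | NA
    complex_flag: bool = False  # len(ref) and len(alt) both > 1

    def __post_init__(self) -> None:
        ref, alt = self.ref_allele.upper(), self.alt_allele.upper()
        self.ref_allele, self.alt_allele = ref, alt
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.mclass == "substitution":
            if not (len(ref) == len(alt) == 1 and ref != alt):
                raise ValueError(f"invalid substitution {ref}->{alt}")
            if self.indel_length != 0:
                raise ValueError("substitutions have indel_length 0")
        elif self.mclass in ("insertion", "deletion"):
            net = abs(len(alt) - len(ref))
            if net != self.indel_length or not (1 <= net <= 30):
                raise ValueError(
                    f"indel_length {self.indel_length} inconsistent with "
                    f"alleles {ref}->{alt} (net {net}, allowed 1-30)"
                )
        else:
            raise ValueError(f"unknown mutation class {self.mclass!r}")

    @property
    def substitution_class(self) -> str:
        return classify_substitution(self.ref_allele, self.alt_allele)

    def affected_interval(self) -> tuple[int, int]:
        """0-based half-open interval of reference bases touched by the event.

        Substitution: the single changed base.  Deletion: anchor plus deleted
        span.  Insertion: anchor plus the following base (the junction the
        inserted sequence lands in).
        """
        a = self.pos - 1
        if self.mclass == "substitution":
            return a, a + 1
        if self.mclass == "deletion":
            return a, a + 1 + self.indel_length
        return a, a + 2


@dataclass
class SpectrumCounts:
    """Counts of base substitutions in the six strand-symmetric classes."""

    AT_to_GC_ts: int = 0
    AT_to_CG_tv: int = 0
    AT_to_TA_tv: int = 0
    GC_to_AT_ts: int = 0
    GC_to_TA_tv: int = 0
    GC_to_CG_tv: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative count for {f.name}")

    @classmethod
    def from_mutations(cls, mutations) -> "SpectrumCounts":
        s = cls()
        for m in mutations:
            if m.mclass == "substitution":
                name = m.substitution_class
                setattr(s, name, getattr(s, name) + 1)
        return s

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in SUB_CLASSES}

    @property
    def transitions(self) -> int:
        return self.AT_to_GC_ts + self.GC_to_AT_ts

    @property
    def transversions(self) -> int:
        return (
            self.AT_to_CG_tv + self.AT_to_TA_tv + self.GC_to_TA_tv + self.GC_to_CG_tv
        )

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    def __add__(self, other: "SpectrumCounts") -> "SpectrumCounts":
        return SpectrumCounts(
            **{k: getattr(self, k) + getattr(other, k) for k in SUB_CLASSES}
        )


@dataclass
class RateEstimate:
    """A per-site per-generation rate with its uncertainty.

    ``se`` is the standard error of the per-line mean; ``ci_low``/``ci_high``
    a 95% interval (BCa bootstrap over lines unless stated otherwise in
    ``method``).  ``nan`` marks quantities undefined at the given n_lines.
    """

    point: float
    se: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_lines: int = 0
    method: str = "per_line_mean"

    def __post_init__(self) -> None:
        if (
            self.n_lines >= 2
            and not math.isnan(self.ci_low)
            and not math.isnan(self.ci_high)
        ):
            if not (self.ci_low <= self.ci_high):
                raise ValueError("ci_low must be <= ci_high")


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem-repeat tract on the reference.

    ``motif`` is the canonical repeat unit: the lexicographically smallest
    rotation of the unit as read on the reference strand (reverse complements
    are not folded — SSR context is strand-local).  ``copies`` counts complete
    tandem copies; the tract ``[start, end)`` may include a partial trailing
    copy.
    """

    chrom: str
    start: int
    end: int
    motif: str
    unit_length: int
    copies: int

    def __post_init__(self) -> None:
        if not (1 <= self.unit_length <= 10):
            raise ValueError("unit_length must be in 1..10")
        if len(self.motif) != self.unit_length:
            raise ValueError("motif length must equal unit_length")
        if self.end - self.start < self.unit_length * self.copies:
            raise ValueError("interval shorter than copies x unit_length")

    @property
    def homopolymer(self) -> bool:
        return self.unit_length == 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered tuple of CDS segments.

    Segments are 0-based half-open intervals in genomic order; for minus-strand
    genes the coding sequence is the reverse complement read from the last
    segment backwards.
    """

    gene_id: str
    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev = -1
        for s, e in self.segments:
            if e <= s or s < 0:
                raise ValueError(f"{self.gene_id}: bad CDS segment ({s},{e})")
            if s < prev:
                raise ValueError(f"{self.gene_id}: segments not sorted")
            prev = e

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class MNMCluster:
    """A multinucleotide-mutation cluster: >=2 mutations of one line on one
    chromosome chained by inter-mutation gaps no larger than the window."""

    line_id: str
    chrom: str
    members: tuple[Mutation, ...]
    span_bp: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")
        pos = [m.pos for m in self.members]
        self.span_bp = max(pos) - min(pos)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class NeEstimate:
    """Effective population size from nucleotide diversity.

    For haploids the expected per-site diversity is ``theta = 2 Ne mu``, so
    ``ne = theta / (2 mu)``; CI bounds are the same monotone transform of the
    mutation-rate CI (order-reversed).
    """

    theta: float
    mu: float
    ne: float
    ci_low: float = math.nan
    ci_high: float = math.nan

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not math.isclose(self.ne * 2.0 * self.mu, self.theta, rel_tol=1e-12):
            raise ValueError("ne, mu and theta are inconsistent")
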