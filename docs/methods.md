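# Methods

This note documents the statistical procedures, the synthetic-data model and
the numerical choices behind `mamut`, in the spirit of a package methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Rate estimation

The per-line rate is μ̂ᵢ = mᵢ/(nᵢTᵢ): mᵢ observed mutations of the class of
interest, nᵢ callable sites (non-N reference positions under the line's BED
mask), Tᵢ generations.  The experiment-level point estimate is the
*unweighted mean* of per-line rates and its SE the across-line standard
deviation over √(number of lines).  This mirrors the per-line-then-average
convention of MA studies and makes the SE reflect true between-line spread;
the pooled alternative Σmᵢ/Σ(nᵢTᵢ) is also emitted for comparison
(`bs_rate_pooled`).

**Bootstrap.** 95% intervals are bias-corrected and accelerated (BCa)
bootstrap intervals over B = 1000 resamples.  The resampling unit is the MA
line, so each resample redraws (m, n, T) triples jointly.  z₀ is the normal
quantile of the fraction of bootstrap statistics below the point estimate; the
acceleration a = Σdᵢ³ / (6(Σdᵢ²)^{3/2}) with dᵢ the jackknife deviations.
Degenerate cases fall back with a warning: an all-identical bootstrap
distribution collapses to the point estimate, and a point estimate outside
the bootstrap range falls back to the percentile interval.  The
implementation is cross-checked in the tests against
`scipy.stats.bootstrap(method="BCa")` and against a percentile oracle on
symmetric data; a 200-replicate simulation verifies 90–99% coverage at
study-like per-line counts (λ ≈ 1).

**Conditional rates and equilibrium GC.**  μ_{A/T→G/C} pools the A:T→G:C
transition and A:T→C:G transversion counts over Σᵢ n_AT,ᵢTᵢ; μ_{G/C→A/T}
analogously over G/C sites.  The two GC-conservative classes (A:T→T:A,
G:C→C:G) enter neither.  Equilibrium GC = μ_{A/T→G/C}/(μ_{G/C→A/T} +
μ_{A/T→G/C}); GC-direction bias = μ_{A/T→G/C}/μ_{G/C→A/T}.  Denominators pool
site-generations across lines (the per-line-mean alternative would weight
small lines more; pooling is the default because the conditional counts are
sparse).

## MNM clustering and the Poisson dispersion test

Mutations of one line on one chromosome are sorted by position and chained
single-linkage whenever the gap to the previous mutation is ≤ window
(default 50 bp); chains of length ≥ 2 are clusters, so a cluster's *span* may
exceed the window.  A strict mode caps the span instead.  Indels participate
through their anchor position.  Collapsing replaces each cluster by one
event, reducing the per-line count by Σ(cluster size − 1).

The chance probability that ≥ 2 of m uniformly placed mutations land within
w bp on n sites uses the birthday-type product P = 1 − Π_{k=1}^{m−1}
(1 − 2wk/n), clipped to [0, 1]; it is validated against a Monte-Carlo
placement oracle to within 5% relative on grids with P ≥ 10⁻³.  The
approximation ignores edge effects and site exclusion, both O(mw/n)
corrections.

The Poisson goodness-of-fit test bins per-line counts by accumulating
adjacent count values (plus an open right tail) until each bin's expectation
under Poisson(λ̂), λ̂ = mean count, is ≥ 1; χ² = Σ(O−E)²/E with df = bins − 2
(normalization + estimated λ).  A 1000-replicate simulation at 37 lines and
λ = 1 shows a type-I error between 0.02 and 0.09 at α = 0.05 — binned χ²
tests with estimated parameters are approximate by nature, which is why
printed χ² values from any particular study are treated as qualitative
targets only.  An optional heterogeneous-exposure variant (λᵢ ∝ nᵢTᵢ) was
considered and deliberately left out: with the masks and generation counts
the package consumes, λ̂ differences across lines are second-order relative
to the MNM effect the test is meant to expose.

## SSR detection

A tract is reported when a unit of length u ≤ 10 repeats perfectly for ≥ 3
complete copies and ≥ 8 bp total (all configurable); maximal tracts may end
in a partial copy.  Each tract is attributed to its smallest period, the
motif is canonicalized to the lexicographically smallest rotation (reverse
complements are not folded — SSR context is strand-local), and overlapping
candidates are resolved greedily left-to-right (earliest start; longer tract,
then smaller unit, break ties).  N never matches.  The scanner is proven
equivalent to an exhaustive per-(start, unit) oracle on random sequences in
the test suite.  Enrichment of variants in SSRs is a one-sided exact binomial
test of k hits in n events against the callable-masked SSR fraction; an
indel's "in SSR" status is decided by overlap of its anchor-plus-span
interval with a locus.

## Coding effects and the neutral NS/S expectation

Substitutions inside an annotated CDS are translated in place (standard
code; stops compare as `*`); indels are flagged frameshift when length mod
3 ≠ 0.  Events whose anchored base is coding but whose span crosses a CDS
boundary are classified by the anchor and flagged ambiguous.

The neutral expectation weights each sense codon by usage and each of its
nine single-base changes by κ = 2·(Ts/Tv) for transitions and 1 per
transversion, so the implied pooled Ts/Tv equals the observed input (one
transition vs two transversions per site).  Changes *to* stops count as
nonsynonymous; stop codons contribute no opportunities.  The ratio is
W_N/W_S.  With usage unavailable, usage is counted from the reference CDSs
themselves.  The 1-df χ² compares observed (N, S) to proportions
(R/(1+R), 1/(1+R)); note that published χ² values for this comparison can
reflect variant test constructions and are not exactly reconstructible from
the two counts and R alone.

## Effective population size

For haploid neutral sites E[θ] = 2Neμ, so Ne = θ/(2μ) with θ an externally
supplied per-site diversity (default 0.00076).  CI bounds are the monotone
transform of the rate's BCa interval with order reversed; the method is
recorded in the report metadata since error-propagation conventions differ
between studies.

## The synthetic-data generator

The generator emulates the study conditions its defaults encode: a 34 Mb,
six-chromosome haploid genome at 22.5% GC; 14.3% of sites in planted SSR
tracts with unit lengths 1–10 weighted toward 3 and 6 and geometric copy
numbers (mean 6, minimum 3; motifs drawn at genome GC, forced aperiodic,
flanks broken so planted tracts stay maximal); ~62% of the genome in
non-overlapping single-segment genes (length 3×(50 + Geometric(1/400))
codons, start codon forced, random strand); 37 lines (19 "L" + 18 "QS"),
1500 generations each, 81.3% of windows (1 kb) callable per line with the
kept-window count fixed exactly; μ_bs = 2.47e-11 with six-class spectrum
weights (4, 1, 13, 7, 9, 3)/37 — the four printed class counts plus a
13:3 split of the unprinted GC-conservative transversions, chosen roughly by
target-site availability in a 77.5% AT genome; μ_indel = 4.93e-11 with
deletion fraction 0.818 (the 4.5:1 deletion bias), a truncated-geometric
1–30 bp length distribution (mean ≈ 6.5 bp), slippage multiplier 2.9 inside
SSRs (back-solved from 32.4% of indels in SSRs at a 14.3% SSR fraction) where
indels change copy number by ±1 unit; and an MNM fraction of 0.12 (pairing
probability per substitution event, matching 4 clusters among 33 substitution
events).

Placement is class-first: each event draws its class from the six-weight
multinomial and then a site uniformly among callable sites of the matching
base type, which makes realized class frequencies match the weights while
per-A/T-site and per-G/C-site rates differ as they should.  Primary event
counts are Poisson(μ_bs·n·T/(1 + mnm_fraction)) so that the *expected
substitution count* stays μ_bs·n·T once MNM partners (uniform offset within
±50 bp, same line and chromosome, callable) are added — the property the
rate-recovery calibration relies on.  Overlapping events resolve
deterministically: a later event replaces any earlier event it touches, with
a warning (negligible at realistic rates).  Saturating configurations
(expected events > 10% of callable sites) and zero-callable lines are
refused.

What the generator does *not* model: read-level error or coverage (no
FASTQ), site-specific rate heterogeneity beyond the SSR multiplier, indel
length correlation with local composition, selection during propagation, and
mechanistic generation counting (generations are taken as given per line).
Passing parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated placement model, not robustness to calling
artifacts in real data.

## Scaled test conditions

Calibration tests run at scaled rates so that simulated experiments carry
hundreds of events on megabase genomes (e.g. μ_bs = 2.5e-6, 1 Mb, T = 20,
37 lines; 20 replicate seeds sharing one genome), and the MNM/Poisson
calibration uses 100 line-simulation seeds on a 200 kb genome with ~2
events per line.  Rate estimators are scale-free (μ̂ = m/(nT)), so these
sizes test the same arithmetic as study-scale runs.  The indel-recovery
truth accounts for the slippage multiplier: the effective per-callable-site
rate is μ_indel·(n_out + s·n_in)/n per line.

## Numerical and format conventions

Internal coordinates are 0-based half-open; VCF stays 1-based with indels
left-anchored (REF and ALT share their first base), BED 0-based half-open,
GFF3 1-based inclusive.  Multi-allelic VCF records are rejected by default
(haploid single-colony isolates; a split option exists).  Complex records
with both alleles longer than 1 bp are classified by net length change and
flagged.  Indels longer than 30 bp are dropped with a count, matching the
size window of the analysis.  Reports render with sorted JSON keys and fixed
float formatting, and the simulator's outputs are byte-identical for a fixed
config and seed (per-line RNG streams are spawned from a root seed).

## Known limitations

- The SSR scanner models perfect repeats only; imperfect or compound
  microsatellites fragment into multiple loci or go undetected.
- The equilibrium-GC formula assumes a two-state site model driven only by
  the two conditional rates; context effects are ignored.
- The binned Poisson χ² has approximate size (see above); with few lines or
  very low λ the test degenerates and is reported as NA.
- `expected_ns_ratio` uses a single pooled Ts/Tv weight rather than the full
  six-class spectrum; the full-spectrum weighting could be added on top of
  the same enumeration.
- Ne inherits all systematic error in the external θ and in the assumption
  that the surveyed sites are neutral.
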