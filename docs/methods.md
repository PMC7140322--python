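# Methods

## Sequence model and conventions

All analyses operate on element coding sequences reported on the
positive strand (the strand encoding the ORFs), carried as
`CodingSequence` records with clade/host/ORF metadata parsed from
`key=value` FASTA header tokens. ORF validation requires length ≡ 0
(mod 3) and no internal TAA/TAG/TGA; a trailing stop codon is trimmed
before any codon statistic. Whether composition statistics should
include a terminal stop is an interpretation; we trim so that every
downstream statistic sees the same sense-codon payload. Codons
containing N are excluded from codon statistics, N positions are
excluded from mononucleotide fractions, and any dinucleotide window
touching an N is skipped. Internal coordinates are 0-based half-open;
reports are 1-based.

## Composition statistics

Dinucleotides are counted in an overlapping sliding window without
wrap-around. The expected frequency of XpY is the product of the
mononucleotide fractions (zero-order model); the χ² statistic compares
observed window counts with expected counts over the 16 cells, 15
degrees of freedom, no continuity correction — the convention matches
reporting observed/expected ratios per dinucleotide.

Polyadenylation signals are the hexamers AATAAA (canonical) and ATTAAA
(non-canonical), counted with overlap on the positive strand only:
premature termination of element transcription requires the signal on
the transcribed strand, and overlap counting is deterministic and
oracle-checkable. Counts are anywhere in the sequence, not restricted
to any reading-frame phase.

## Codon-usage bias estimators

The standard genetic code partitions the 20 amino acids into 2
single-codon families (Met, Trp), 9 two-fold, 1 three-fold (Ile), 5
four-fold and 3 six-fold (Leu, Ser, Arg); Wright's Nc treats each
degeneracy class separately:

    Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6,   F = Σ_c p_c²

with p_c the within-family codon frequencies. The default is the
frequency-based F (no small-sample correction) so the definitional
extremes Nc = 20 and Nc = 61 hold exactly; the corrected estimator
F = (nΣp² − 1)/(n − 1) is available by flag. A degeneracy class with no
countable family borrows the mean F of the observed degenerate
families. Results are clipped to [20, 61].

CAI is the geometric mean over query codon occurrences of
w_c = f_ref(c)/max over synonyms, excluding Met, Trp and stops. RCDI is
the mean over query codon occurrences of the query/reference ratio of
per-amino-acid conditional frequencies; this orientation makes
deoptimized queries give RCDI > 1 and RCDI = 1 exactly when the usages
coincide. Reference codons with zero counts in a family the query uses
receive a pseudo-count of 0.5 before normalization, keeping w and the
RCDI ratios finite; the choice only matters for sparse references and
is visible in `CodonUsageTable.cond_freq`.

The reference table pools codon counts over the host CDS set (rather
than averaging per-gene frequencies); pooling weighs genes by length,
which is what a whole-transcriptome codon count does.

eCAI draws, per replicate, the query's codon count of sense codons with
probability proportional to the product of the query's mononucleotide
frequencies (stops excluded, renormalized) and scores each replicate's
CAI; both the mean (default) and the 95th percentile summaries are
exposed since randomization servers differ on this point. eRCDI keeps
the query's amino-acid sequence and redraws each codon among its
synonyms with the same composition-driven weights, returning the mean
replicate RCDI. Defaults: 500 replicates, seeded; runs are
bit-reproducible for a fixed seed. Per-clade summaries are computed per
family consensus and then averaged (unweighted mean ± sd per
(clade, host) group).

## Mutation-spectrum procedure

The consensus is treated as the ancestral state — the procedure is
restricted to young families (mean copy divergence < 5%, at least 8
copies by default), where ancestral/derived polarity is unambiguous.
Substitutions are called per copy against the consensus in consensus
coordinates; alignment columns with a gap or N in either sequence are
skipped (indels are never tabulated). A variant is *shared* when the
identical (position, from, to) triple occurs in ≥ 2 copies; two
different substitutions at one position remain singletons. Only
singletons enter the spectrum, removing mutations inherited from a
common progenitor.

C→* variants are CpG-context iff the consensus carries G at the next
position; G→* iff C at the previous position; sequence edges are
decided by the single available neighbor. Rates are normalized by
mutational opportunity, rate(X→Y) = count/count of X in the consensus,
and rescaled to percentages summing to 100; the raw counts are reported
alongside. The GC→AT excess is the pooled GC→AT rate sum over the
pooled AT→GC rate sum.

**Recurrence correction.** The singleton filter removes not only
inherited mutations but also independent recurrences, which are common
at hypermutable CpG sites. For a per-copy, per-site mutation
probability q and n copies, the probability a mutation survives as a
singleton is r = q(1 − q)^(n−1); `branch_mutation_probability` inverts
this curve, and `corrected_context_rates` applies it per substitution
and context with context-specific opportunities (CpG vs non-CpG counts
of the source base). The CpG multiplier estimate is the mean
CpG/non-CpG corrected-rate ratio of the two deamination channels C→T
and G→A. Even corrected, the estimate is attenuated relative to the
per-site multiplier because CpG contexts decay: mutations on the
ancestral branch destroy (and create) CpG dinucleotides that the
consensus-based classification cannot see, so a fraction of
consensus-CpG sites actually mutate at the background rate. At the
default settings (divergence 3%, shared fraction 0.2, multiplier 10)
this predicts an observed ratio near 8–9; recovery tests therefore
require the estimate to be far above 1 and within a factor of two of
the configured value, while the substitution-matrix and GC→AT-excess
recoveries, which are unaffected by context decay, are held to 95%
binomial confidence intervals (Bonferroni-adjusted across the 12
matrix entries) and ±10% respectively.

An optional divergence-matched subsampling stage
(`divergence_matched_subsets`) greedily pairs families of two groups by
nearest mean divergence, for comparing spectra of clades at matched
ages.

## Synthetic-data generator

The generator emulates the three real inputs with known ground truth.

*Host CDS sets*: genes start ATG, end with a stop, contain no internal
stop; internal amino acids are drawn uniformly and codons per a
per-amino-acid conditional profile (uniform or GC3-preferring with
adjustable strength; the GC-preferring default mimics a vertebrate
exome's codon preference). Lengths are Poisson around the mean (default
50 genes × 400 codons — enough for stable conditional frequencies in
every family).

*Element consensi*: codons drawn base-by-base from the target
mononucleotide frequencies with stop codons rejection-resampled.
Default target is lizard-L1-like (A 0.43, C 0.17, G 0.16, T 0.24 —
67% AT with a strong A bias); realized composition lands within ~2
percentage points of target at ≥ 1,000 codons.

*Families*: star tree with an ancestral branch carrying a fraction
s = 0.2 of the expected divergence (mutations shared by all copies)
and independent copy branches carrying the rest. Mutations are
independent per-site Bernoulli events — appropriate below 5%
divergence, where back-mutation is negligible — with per-site rates
proportional to 1, or to the CpG multiplier (default 10, the lower end
of the 10–50× hypermutability of methylated CpG) for C/G in CpG
context evaluated on the branch's ancestral sequence at injection
time. Substitution targets follow a row-stochastic 4×4 weight matrix;
the default is transition-biased with GC rows leaning toward AT,
giving an analytic GC→AT excess of 1.7. Expected divergence defaults
to 3% and copy number to 10. Every injected mutation is logged
(branch, position, from, to); everything is bit-reproducible under a
fixed seed. Stop codons may arise in copies (pseudogenized copies are
realistic) but never in consensi.

What the generator does *not* emulate: dinucleotide selection (so
synthetic consensi have CpG/GpT/TpA ratios near 1, unlike real
elements), indels, rate heterogeneity beyond CpG, gene conversion,
APOBEC editing, insertion-site composition effects, and
retrotransposition bursts. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
that real element families satisfy the model.

## Statistical comparisons

Group comparisons use one-way ANOVA or two-sample t-tests; normality is
checked with a Kolmogorov–Smirnov test against a fitted normal;
composition–statistic relationships use ordinary least squares with r²
and the slope's p-value. Observed-vs-expected RCDI is tested with a
paired z on per-family (RCDI − eRCDI) differences — the paired
construction is an interpretation, as the original comparison is
underspecified. No multiple-testing correction is applied anywhere, by
design. On null synthetic data (no codon adaptation built in) the
paired z has no reason to be negative; the analysis driver only claims
host adaptation when z < 0.

## Numerical choices and problem sizes

Analysis drivers use 20 families × 10 copies × 800 codons and 60 host
genes (seed 2024); recovery tests use 20 families × 10 copies × 1,000
codons. These sizes put binomial sampling error on matrix entries near
±0.02 and keep the full suite and drivers fast. Tolerances: exact
identities at 1e-12..1e-9; Monte-Carlo comparisons at 2–5 standard
errors; KL divergence of the recovered matrix < 0.05.

## Known limitations

- The consensus-as-ancestor assumption degrades above ~5% divergence;
  no phylogeny-aware reconstruction is attempted.
- The CpG multiplier estimate is a context-ratio, systematically below
  the per-site multiplier (see above); treat it as a lower bound.
- eCAI/eRCDI model codon sampling from mononucleotide products, not
  dinucleotide-aware composition.
- Reverse-strand polyA signals are not scanned.
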