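# Methods

## Expression stability

Counts are normalized by the median-of-ratios estimator: with reference
transcripts R = {g : count(g, s) > 0 for every sample s}, the factor for
sample s is

    f_s = median_{g in R} [ count(g, s) / geomean_t(count(g, t)) ].

The raw estimator is defined only up to a common scalar (rescaling all
samples together changes nothing downstream of a CV), so the factor
vector is reported rescaled to geometric mean 1.  This makes
normalization idempotent: re-estimating factors on normalized counts
returns exactly 1.0 per sample.  Estimation fails, with an explicit
error, when no transcript is positive in every sample.

Stability is the sample coefficient of variation of normalized counts,
sd (n−1 denominator) divided by the arithmetic mean, computed per
transcript across all samples; each sample (sequencing run) is one
observation and replicates are not averaged per tissue.  A transcript
with zero mean has no defined CV and is excluded from ranking.  The
percentile rank of a value v is #{values ≤ v}/n, lying in (0, 1]; ties
are handled by the ≤ counting itself.  The geometric mean of normalized
counts is the n-th root of the product and is exactly 0 whenever any
sample is 0 — no pseudocount is added, so weakly expressed
zero-containing genes rank at the bottom of the expression scale rather
than at an arbitrary pseudocount-dependent position.

The low-expression filter removes transcripts whose mean **raw** count
is below 1 read ("less than" strict, so a mean of exactly 1.0 is kept).
Filtered transcripts stay in the stability table with
`passes_filter = False` and NaN percentiles, so the CV distribution of
removed transcripts can still be compared with the kept set; percentile
ranks are computed over the kept set only.

## Promoter extraction

The TSS is the annotated transcript 5′ end (no refinement from CAGE or
EST evidence).  TSS-relative coordinates use the biologist's convention:
−1 is the base immediately upstream, +1 the first transcribed base, and
there is no position 0.  The upstream "intergenic" sequence runs from
the nearest annotated gene boundary on the 5′ side — on either strand,
the simplest reading of "until the next gene" — capped at 2,000 bp
(configurable; the scans only need 100 bp, the cap documents the
extraction contract), and is truncated at the chromosome edge.  The
5′UTR is the concatenation of annotated five_prime_UTR intervals in
transcript order, reverse-complemented on the minus strand; when a
transcript has no five_prime_UTR features the UTR is empty rather than
inferred from CDS.  GFF3 coordinates are 1-based closed; transcripts are
mRNA features with Parent gene attributes.

Windows that overlap the TSS draw negative positions from the upstream
sequence and positive positions from the 5′UTR; positions beyond the
available sequence are clipped (the realized positions are reported), so
a window can be shorter than requested but never padded.

## Core promoter scanning

The motif scan slides a PWM across its element's window on the forward
strand only (promoters are orientation-defined relative to their TSS;
reverse-complement scanning is available behind a flag).  The raw score
at an offset is the sum of per-position weights; the relative score is
min–max normalized, (raw − min)/(max − min), where min/max are the sums
of per-position minima/maxima — the standard "relative score"
convention, bracketing [0, 1].  An element is called present when the
best relative score is strictly above the threshold (default 0.85).
Offsets whose window contains a non-ACGT base are skipped; if no offset
is valid the flag is false.  PWM files are JASPAR-like plain text; all-
non-negative matrices are treated as frequencies and converted to
log2-odds against a configurable background (default uniform), matrices
with negative entries are used as additive scores directly.

The octamer scan reports every listed 8-mer whose full extent lies
inside the element's window, with TSS-relative start positions.  CA and
GA are octamer-only elements; the motif scan covers TATA, Y patch and
Inr.  An element is combined-present if either method is positive.
Promoters with under 100 bp of intergenic sequence are Unscannable —
the rule keys on intergenic length only, since the UTR may legitimately
be short.  Scannable promoters are classified by precedence
TATA > YPatch > Coreless; both combined flags are preserved so any
other precedence can be re-applied downstream.

## Ortholog switch cascade

Per target gene, only the highest-expressing transcript is kept,
quantified as the geometric mean of normalized counts (a deliberate
choice; mean, max or total would serve similarly) with exact ties broken
toward the lexicographically smaller id.  Any (query, species) pair that
retrieved more than one target gene is removed entirely.  A member
switches expression pattern when its CV percentile and the query's lie
strictly on opposite sides of the 50th percentile; a member exactly at
the boundary does not switch ("crossing" read as strict).  Groups need
switches in at least 2 target species.  Species with more than one
member in an externally supplied gene-tree member count are removed, and
the group is dropped when that pushes switched species below the
minimum.  Species with missing expression data are excluded from both
present and switched sets rather than treated as unswitched.

Clade consistency replaces a manual tree-inspection step with a score:
|switched| / |leaves under MRCA(switched) ∩ present|, computed on a
rooted species tree; a singleton switched set scores 1, an empty set is
undefined.  A group is retained when the score reaches the threshold
(default 0.5, i.e. switches "mostly" within one clade).  The per-group
JSON reports label the score as a reconstruction.

## Reports

CV-percentile histograms per promoter class use bins on [0, 1] with
density normalization, restricted to filtered-in, scannable promoters;
by construction the class histograms weighted by class size sum to the
overall histogram.  Ortholog recovery is the fraction of a query set
with at least one ortholog row per species; the one-way ANOVA treats
each species as one observation per gene set (OLS ANOVA, with Tukey HSD
for the pairs).  Tertiles follow the verbatim edges 0.33 and 0.66 (not
1/3 and 2/3), closed on the right, with boundary values assigned to the
lower bin.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not the data-collection process: no reads, adapters or alignment — the
pipeline starts at count matrices.

**Genomes.**  Genes are laid out left to right with intergenic gaps
drawn uniformly from [300, 1500] bp (every promoter therefore has at
least 300 bp of clean upstream sequence), one transcript per gene
(5′UTR of 50–200 bp plus a 300 bp body), strands drawn with a
configurable minus fraction, over i.i.d. background at GC 0.36 —
typical of plant intergenic DNA and the simplest model under which
false-positive motif rates are measurable.  Elements are planted at
TSS-relative windows (defaults: TATA −33..−24, Y patch −30..−21,
Inr −4..+4, CA −20..−13, GA +5..+12), reverse-complemented for
minus-strand genes, and recorded in a truth table.  The shipped PWMs and
octamer lists are synthetic, idealized constructions whose consensus
chains equal the planted sequences (so consensus plants score exactly
1.0); real analyses should supply curated motif files.  The planted TATA
is the 10-mer GTATAAATAG: with equal minor weights the relative score
reduces to matches/length, and the two G flanks keep the background
false-positive rate of the 0.85 threshold near 1% on AT-rich background
(an 8-mer of pure A/T would false-positive an order of magnitude more
often).

**Atlases.**  One sample per tissue (default 12 tissues, stages assigned
round-robin, satisfying the ≥10 tissue / ≥2 stage atlas definition).
Uniform genes have mean `base_mean` (default 100) everywhere;
conditional genes have that mean in k randomly chosen tissues (default
3) and a 0.1 "leak" mean elsewhere — not exactly 0, so geometric means
are exercised both with and without zeros.  Counts are
negative-binomial with var = μ + αμ² (default α = 0.05); α = 0 is the
documented noise-free limit in which counts equal rounded means.
Per-sample library distortions are log-normal (σ = 0.25) unless given
explicitly.

**Families.**  A balanced default tree over 8 species; 40 groups of
which 10 carry switches in the full leaf set of a clade not containing
the query (consistency exactly 1), 10 carry scattered switches spanning
the root (consistency ≤ 3/8), and 20 none.  Switched species receive the
opposite designed class from the query.  Each species' atlas adds
background genes so the totals are 40% uniform, 20% intermediate
(expressing in ~2/3 of tissues) and 40% conditional: the intermediate
band strictly separates the CV of uniform and conditional genes, so
every designed-uniform gene ranks below the 0.5 CV percentile and every
designed-conditional gene above it, and switch detection against the
planted truth is exact rather than approximate.  Optional plants:
1:many ortholog duplications (two table rows for one query/species
pair) and multi-member gene-tree counts, for exercising the two 1:1
filters.  Ortholog rows can be thinned per query class
(`ortholog_presence`) to emulate the empirically lower retrieval rate of
conditionally expressed genes; the pipeline default is 0.9 for uniform
and 0.5 for conditional queries.

**What passing tests do not show.**  The atlases have no batch effects,
replicate structure, isoform ambiguity or mappability artifacts; the
genomes have no repeats, nested genes or alternative TSSs; element
plants are consensus-strength, so recovery rates here upper-bound what
degraded real motifs would give.  Results on synthetic data validate the
machinery, not biological conclusions about real promoters.

## Problem sizes and numerics

Default validation scales: 500-gene genomes × 3 seeds for planted-motif
recovery; 1,000 genes × 12 tissues × 5 seeds for CV-class separation;
8 species × 240 genes × 3 seeds for the switch cascade; 1,000 random
cases per scanner oracle.  These sizes give stable estimates (binomial
standard errors under 1 percentage point) while keeping a full run in
seconds.  Randomness is always drawn from `numpy` generators seeded via
`SeedSequence` spawning, so every artifact is reproducible from one
integer seed; ties in ranking, set iteration and file ordering are
broken deterministically (lexicographic ids, sorted keys), making
`run-all` byte-identical across repeated runs.  Degenerate inputs —
empty windows, all-N sequences, empty octamer sets, zero-mean
transcripts, empty switched sets — return defined empty/NaN/false
results rather than raising, except where the contract names an error
(no reference transcripts, malformed octamers, unknown strands,
oversized layouts).
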