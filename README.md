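# promstab

Core promoter architecture versus expression stability in plant
transcriptomes, at desk scale.

Plant core promoters fall into a handful of architectural classes —
TATA-box, pyrimidine patch (Y patch), initiator (Inr), the rarer CA and
GA octamer elements, and "Coreless" promoters that carry none of them.
A long-standing observation is that TATA-box promoters tend to drive
conditional (tissue- or condition-specific) expression while Coreless
promoters skew toward uniform, constitutive-like expression.  `promstab`
implements the full analysis chain needed to test such claims across
species:

1. **Expression stability.** Raw transcript counts from a tissue atlas
   (≥10 tissues, ≥2 developmental stages) are normalized with the
   median-of-ratios size-factor estimator.  Stability of gene *g* is the
   coefficient of variation of its normalized counts across samples,
   CV(g) = s_g / x̄_g (sample standard deviation over mean), converted
   to a percentile rank P(g) = #{CV ≤ CV(g)} / n so species are
   comparable.  Transcripts with a mean raw count below 1 read are
   flagged out before ranking.
2. **Promoter extraction.** From FASTA + GFF3, each transcript is
   anchored at its annotated TSS; the upstream intergenic region (to the
   nearest annotated gene boundary, capped at 2 kb) and the 5′UTR are
   extracted strand-correctly into a TSS-relative coordinate system
   (−1 abuts the TSS, +1 is the first transcribed base, no position 0).
3. **Core promoter scan.** A PWM *motif scan* in fixed windows (TATA
   −100..−1, Y patch −100..+100, Inr −10..+10) calls an element when the
   min–max-normalized score (raw − min)/(max − min) exceeds 0.85, and an
   *octamer scan* calls an element when a listed 8-mer lies inside a
   narrower window (TATA −45..−18, Y patch −50..+50, CA −35..−1,
   GA −35..+75).  Either method positive ⇒ element present; promoters
   with <100 bp of intergenic sequence are Unscannable; scannable
   promoters are classified TATA > YPatch > Coreless.
4. **Ortholog switches.** Given per-species stability tables, an
   ortholog table and a species phylogeny, a filtering cascade keeps the
   highest-expressing transcript per target gene, discards 1:many
   orthology, flags members whose CV percentile crosses the 50th
   percentile relative to the query ("expression-pattern switch"),
   requires ≥2 switched species and 1:1 membership, and scores clade
   consistency as |switched| / |present leaves under their MRCA|.
5. **Reports.** CV-percentile distributions by promoter class, ortholog
   recovery rates per gene set with one-way ANOVA + Tukey HSD, and
   low/mid/high tertile summaries.

Real inputs (RNA-seq atlases, reference genomes, ortholog databases) are
expensive; the `promstab.synth` module generates genomes with planted
elements, negative-binomial tissue atlases with designed uniform and
conditional genes, and multi-species ortholog families with planted
expression switches — all with ground-truth tables — so every stage is
testable end to end on a laptop.

## Worked example

Run the whole pipeline from the built-in configuration:

```bash
promstab run-all --outdir out --seed 3
```

This simulates a 300-gene genome whose conditional genes receive a
TATA-box 70% of the time (uniform genes 20%), a 12-tissue atlas, and an
8-species ortholog family, then prints a summary like:

```json
{
  "anova_F": 37.698609,
  "anova_p": 3.66815e-07,
  "class_counts": {"Coreless": 45, "TATA": 44, "YPatch": 31},
  "mean_cv_percentile_by_class": {
    "Coreless": 0.365185, "TATA": 0.599318, "YPatch": 0.374839
  },
  "n_genes": 300,
  "n_groups": 40,
  "n_promoters_scanned": 120,
  "n_retained_groups": 9,
  "recovery_rate_by_set": {
    "conditional": 0.47205, "random": 0.635714, "uniform": 0.87395
  },
  "seed": 3
}
```

Reading it: of the 120 scanned promoters (40% subsample), TATA-labeled
promoters sit at a mean CV percentile of 0.60 versus 0.37 for Coreless —
the planted TATA-conditional association is recovered.  Uniformly
expressed query genes retrieve orthologs far more often (87%) than
conditionally expressed ones (47%), with the random set in between and
the three sets cleanly separated by ANOVA (F = 37.7).  Of 40 ortholog
groups, the cascade retains 9 whose expression switches are concentrated
in one clade (one planted group is lost to a randomly missing ortholog
under the default 0.9/0.5 retrieval rates).  Per-stage tables land in
`out/` (`stability/`, `promoters/`, `scan/`, `orthologs/`, `report/`).

Individual stages are available as `promstab simulate | stability |
extract | scan | orthologs | report`, and as plain library calls
(`promstab.stability.stability_table`, `promstab.scan.scan_promoters`,
`promstab.orthologs.switch_cascade`, ...).

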