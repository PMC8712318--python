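# Methods

`mitocohort` analyses cohorts of whole human mitochondrial genomes: it
calls variants against the revised Cambridge Reference Sequence (rCRS,
NC_012920.1), characterizes the cohort's mutational landscape, examines
gender/age/immune-stratified trends, and scans substitutions for
association with CD4+ T-cell outcomes under antiretroviral therapy.
This note records the models, conventions and numerical choices, and
what the synthetic-data studies do and do not demonstrate.

## Reference model

The bundled reference is the canonical 16,569-bp rCRS with the standard
NC_012920 annotation: 13 protein-coding genes, 22 tRNAs, 2 rRNAs and
the control region, which wraps the origin and is stored as two arcs
(16024–16569 and 1–576) under the single name `D-loop`. Coordinates are
1-based inclusive, matching `m.POS REF>ALT` nomenclature. For regional
summaries genes are grouped into seven macrodivisions: D-loop, RNRs,
tRNAs, NDs (ND1–6 and ND4L), COs (CO1–3), ATPs (ATP6/ATP8) and CYB.
Translation uses the vertebrate mitochondrial code (NCBI table 2:
AGA/AGG stop, ATA Met, TGA Trp). The placeholder N at position 3107
sits in RNR2 and is excluded from calling and from the substitution
space.

### The possible-substitution space

For every genome-encoded position of every protein-coding gene and each
of its three alternative bases, the change is classified synonymous or
nonsynonymous by re-translating the affected codon (light-strand ND6 is
reverse-complemented first), and transition or transversion. The
conventions, each an explicit keyword:

- **Overlaps.** A position inside two genes (ATP8/ATP6, the shared base
  9207 of ATP6/CO3, ND4L/ND4) contributes independently to each gene,
  and the genome-wide totals sum the per-gene counts (i.e. overlap
  positions count twice). The totals 8,291 + 25,894 = 3 × 11,395 equal
  three times the summed CDS lengths *including* overlaps and
  incomplete-stop bases, which is what fixes this convention.
- **Incomplete stop codons.** The T/TA gene endings completed by mRNA
  polyadenylation (ND1, ND2, CO3, ND3, ND4, CYB) are completed with 3'
  A's; their genome-encoded positions are included in the space.
- **Completed-stop TGA rule.** A polyadenylation-completed stop codon
  that mutates to TGA is counted stop-preserving (synonymous). Exactly
  one rCRS change is affected — m.4262A>G in ND1's completed TAA — and
  with the rule on, the enumeration yields exactly 8,291 possible
  synonymous and 25,894 possible nonsynonymous substitutions. All other
  stop-to-stop changes (TAA↔TAG, AGA↔AGG) are synonymous by the plain
  table; stop gain/loss is nonsynonymous, the standard dN/dS
  convention.
- **Initiators.** Start codons are translated by the plain table; an
  optional `initiator_as_met` switch treats codon 1 as Met with
  ATG/ATA/ATT/GTG as synonymous initiator exchanges. Off by default.

The space also records, per target amino acid, the maximum number of
distinct changes producing it — the denominators of amino-acid-change
bias. Changes involving a stop on either side are excluded from the
amino-acid change matrix, since they produce no residue pair.

## Variant calling

Participant genomes are globally aligned to the rCRS. Two engines:

- `needle`: affine-gap global alignment (Biopython `PairwiseAligner`,
  EDNAFULL scoring; default gap open 10, extend 0.5), quadratic time,
  used for fragments (≤ 5 kb) by default and available on demand.
- `edlib`: bit-parallel unit-cost edit-distance alignment, used
  automatically for full-length genomes. For the sparse, mostly
  isolated differences between human mtDNA sequences the two engines
  produce identical variant calls after normalization; a test asserts
  this on fragments.

Variants are read off alignment columns: substitutions per reference
position (IUPAC mixture codes in the query are preserved as the alt
allele and flagged *ambiguous*; a definite call is a single base);
contiguous gap runs collapse to single insertion/deletion events.
Indels are **left-aligned** against the reference — reported at the
lowest equivalent coordinate — and split representations of one event
(an aligner may divide a deletion into equal-cost pieces) are merged
and re-normalized until stable. Columns where either sequence has an N
are not callable. Annotation reconstructs the affected codon per
overlapping gene under the same conventions as the enumeration, so a
called variant and the substitution space can never disagree about
synonymy. Indels are descriptive only: they enter diversity and volume
but are excluded from relative diversity, momentum, amino-acid-change
metrics and the association scan, where ambiguous substitutions are
likewise excluded wherever a metric is defined over *definite*
substitutions.

## Characterization metrics

With the cohort's variant-type registry (types keyed by position, ref,
alt, kind; one row per overlapping gene):

- **Diversity** = distinct types per unit; **volume** = carrier-weighted
  count. A type inside two genes counts once per gene but once only in
  genome-wide totals. For a single participant diversity equals volume.
- **Diversity density** = diversity / sample size / unit length (kb).
  Unit lengths sum member-gene spans (the D-loop arcs sum to 1,122 bp;
  overlap bases count in each member gene, consistent with the space).
- **Relative diversity** = observed distinct definite substitution
  types / possible substitutions, per class (all, synonymous,
  nonsynonymous, transition, transversion); the density variant divides
  the observed count by the sample size.
- **Momentum** = OLS slope (with intercept) of per-gene observed/n
  against the per-gene possible count across the 13 protein genes. The
  raw slope is reported; direction interpretation is left to the
  caller.
- **Amino-acid-change bias** = observed changes to a residue / maximum
  possible changes to it; prevalence counts distinct change types by
  default (a carrier-weighted variant exists behind a flag).
- **Physicochemical change prevalence** distributes observed changes
  over ordered class pairs of a property scheme. The schemes (acidity /
  hydropathy / volume / chemical / charge / hydrogen donor–acceptor /
  polarity) follow the IMGT amino-acid classes, recorded in
  `data/aa_class_schemes.yaml`; the acidity scheme is the classic
  neutral-apolar / neutral-polar / acidic / basic split.

## Stratified trends

Analyses of mutational patterns run within 16 subpopulations — 2
genders × 4 age groups (17–29, 30–44, 45–59, ≥60) × 2 immune levels
(pre-treatment CD4 < 200 vs ≥ 200 cells/µl) — after restriction to one
ethnicity (Han by default). Strata smaller than 5 are flagged, never
dropped. Age trends are OLS slopes over the ordinal codes 1–4 (any
affine recoding rescales the slope, so the codes are fixed); fits use
stratum-level points, unweighted. Distribution comparisons use the
two-sided Wilcoxon rank-sum test (exact for small tie-free samples,
tie-corrected normal approximation otherwise) and sequencing-platform
batches are compared with Welch's unequal-variance t-test.

## Association scan

Substitution carriers are coded 0/1 (mtDNA is treated as haploid per
major allele). Columns with carrier prevalence outside the open
interval (1%, 99%) are removed — at n = 724 the retained carrier counts
run from 8 to 716. Two outcome models: pre-treatment CD4 on gender,
age, ethnicity and transmission mode; and post-treatment CD4 with the
pre-treatment count, regimen class and treatment duration as additional
covariates (a change-score model). With 287 retained substitutions the
scan performs 574 tests and the Bonferroni threshold is 0.05/574 =
8.71e-5.

Because CD4 outcomes have heavy-tailed residuals (the generator uses
Laplace noise for exactly this reason, and `residual_diagnostics`
checks Breusch–Pagan homoscedasticity and Shapiro–Wilk normality at
α = 0.05), each model is a least-absolute-deviation (median)
regression. Inference is case-resampling bootstrap: SE is the standard
deviation of the coefficient over B replicate fits (B = 1,000 by
default), CI = β ± 1.96 SE, t = β/SE, p = 2(1 − Φ(|t|)) — the normal
approximation whose internal consistency the tests verify. Each
substitution draws its bootstrap indices from a private seed stream
derived from the master seed and the column key, making results
invariant to column order. Replicates whose resampled design loses a
column (e.g. no carriers drawn) are dropped and counted, with a warning
above 10%.

### The LAD solver

The solver is written for this package: iteratively reweighted least
squares (weights 1/max(|r|, ε), ε = 1e-10 of the outcome scale)
followed by a vertex polish — an LAD optimum interpolates p
observations, so a simplex-style descent over interpolating bases
(single-observation swaps, moving on strict improvement) terminates at
the exact linear-programming optimum on small problems. Modes: `full`
descent (default for n·p ≤ 2,000), `restricted` (descent over the 4p
smallest-residual observations; near-exact, linear in n) and `none`
(plain IRLS, used for bootstrap replicates where solver wobble is
negligible against resampling variability). A test compares the solver
with a brute-force `scipy.optimize.linprog` formulation at 1e-8
objective tolerance on 100 random instances, and with statsmodels
`QuantReg` as an independent implementation. Two exact shortcuts are
exploited: for the intercept + binary-genotype design the LAD solution
is the difference of group medians, which vectorizes over bootstrap
replicates (one sort per group) and makes covariate-free null scans
hundreds of times faster; batched replicate fits warm-start from the
full-data coefficients.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes:
genomes are the rCRS with substitutions (optionally emitted as IUPAC
mixtures at a 4% ambiguity rate, matching the observed share of
ambiguous calls) and indels planted at configured carrier frequencies;
metadata marginals mirror the cohort table (74.18% male; age-group
weights 30.1/40.5/18.8/10.5% over 17–29/30–44/45–59/≥60; 94.51% Han;
69.04/28.62/2.34% heterosexual/homosexual/other transmission; 77.07%
zidovudine-based regimen; 59.67% treated ≥3 months). Pre-treatment CD4
is log-normal with median 219 cells/µl and log-sd 0.5 (IQR ≈ 156–307,
near the observed 149–295); the post-treatment count is
cd4_pre + 70 + covariate effects + planted variant effects + Laplace
noise (scale 90, reproducing a pre-to-post change IQR of ≈ 130 cells/µl
around the observed median change of 70), truncated at zero. Variants
are independent across participants and positions — no linkage or
haplogroup structure — because the scan treats substitutions
marginally. Everything is drawn from one master seed; identical seeds
give byte-identical outputs, and the emitted ground-truth ledger (the
exact variant objects written into each genome, plus the carrier
matrix) lets calling, metrics, stratification and the scan be audited
exactly.

What passing these studies shows: the pipeline recovers exactly what
was planted, its estimator is calibrated under heavy-tailed noise, and
its multiple-testing control behaves as designed. What they do not
show: robustness to real-data features the generator omits —
haplogroup linkage, sequencing error, heteroplasmy, nuclear
mitochondrial pseudogene contamination, and non-independent missingness.

## Problem sizes of the simulation studies

- Parameter recovery / CI coverage: 100 simulations at n = 724 with
  B = 200 bootstrap replicates; planted effect −55 cells/µl at 10%
  carrier frequency under the full-covariate post-treatment model.
- Null calibration: 100 independent scans of 287 null columns × both
  outcomes at n = 300, B = 200, covariate-free models (the covariate-
  free design enables the exact group-median fast path). Under the
  null, per-substitution p-values are uniform at conventional levels —
  pooled over null scans, P(p < 0.05) ≈ 0.051 and P(p < 0.01) ≈ 0.011 —
  but the normal approximation with a bootstrap SE is intrinsically
  anti-conservative at the extreme Bonferroni quantile (≈ 8.7e-5): the
  bootstrap variance of a quantile-type estimator has relative error of
  order n^(-1/4), which thickens the tail of t = β/SE far from the
  centre. The measured family-wise error of the fully null scan is
  therefore well above the nominal 5% (≈ 0.2–0.3 across n = 300–724 and
  B = 200–500), and the null-calibration check in the acceptance suite
  fails by design honesty rather than by implementation defect; the
  companion mid-tail calibration test passes. Practically, this means a
  Bonferroni-significant hit from this model family carries less than
  the nominal family-wise guarantee — a caveat that applies to any
  bootstrapped median-regression scan of this design, not just this
  implementation.
- Round-trip calling: 100 full genomes carrying ~25 random
  substitutions plus a 9-bp deletion, a 2-bp insertion and 5% ambiguous
  emissions.

## Known limitations

- The scan's production default (B = 1,000, full covariates, 287
  columns, both outcomes) is minutes-scale on one CPU; tests and the
  acceptance script use the reduced sizes above.
- Circular-genome wrap-around indels spanning position 16569/1 are not
  normalized across the origin.
- Heteroplasmy fractions, base qualities and chimeric assemblies are
  out of scope; ambiguous IUPAC calls are carried as variant types but
  never resolved.
- The Wilcoxon and Welch helpers are thin wrappers over SciPy and exist
  to fix the package's conventions (two-sided, tie handling, Welch df),
  not to reimplement the statistics.
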