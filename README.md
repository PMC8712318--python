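# mitocohort

Cohort-scale analysis of whole human mitochondrial genomes: variant
calling against the revised Cambridge Reference Sequence (rCRS),
mutational characterization, stratified trend statistics, and a
genome-wide association scan between mtDNA substitutions and CD4+
T-cell outcomes under antiretroviral therapy.

The package is aimed at studies of people living with HIV (and similar
cohorts) where whole-mtDNA sequences and clinical metadata are
available per participant, and where the question is twofold: *what
does the cohort's mitochondrial mutational landscape look like* —
overall, and across gender, age and immune strata — and *which
individual substitutions predict immune outcomes*.

## What it computes

**Reference model.** The bundled 16,569-bp rCRS (NC_012920.1) with the
standard gene annotation, the vertebrate mitochondrial genetic code,
and the enumeration of *every possible* coding substitution classified
as synonymous/nonsynonymous and transition/transversion. Under the
package's documented conventions the rCRS admits 8,291 possible
synonymous and 25,894 possible nonsynonymous substitutions — the
denominators of the relative-diversity metrics.

**Variant calling.** Global pairwise alignment of each participant
genome to the rCRS (bit-parallel edit-distance alignment for full
genomes, affine-gap EMBOSS-style alignment for fragments), extraction
of substitutions and left-normalized indels in `m.POSREF>ALT`
notation, and per-gene annotation (synonymy by codon reconstruction,
IUPAC-ambiguous calls flagged).

**Metrics.** Mutational diversity (distinct variant types) and volume
(carrier-weighted counts) per gene/macrodivision/genome; diversity
densities; relative diversity (observed/possible); *momentum* — the
slope β of per-gene observed-over-n against the per-gene maximum
possible count; amino-acid-change prevalence and bias; and
physicochemical-change profiles over seven property schemes.

**Stratified trends.** The 16 gender × age-group × immune-level
subpopulations, age-trend slopes over ordinal codes, Wilcoxon rank-sum
and Welch-t comparisons.

**Association scan.** For each substitution with carrier prevalence in
(1%, 99%), a least-absolute-deviation (median) regression of the CD4
outcome on carrier status plus covariates, with case-resampling
bootstrap inference: SE = sd of replicate coefficients,
CI = β ± 1.96 SE, t = β/SE, p = 2(1 − Φ(|t|)), Bonferroni-corrected
across all tests. With 287 substitutions and two outcomes that is 574
tests and a threshold of 0.05/574 = 8.71 × 10⁻⁵.

**Synthetic cohorts.** A generator that plants substitutions, indels
and ambiguous calls into the rCRS at chosen frequencies, draws
realistic metadata marginals and heavy-tailed CD4 outcomes with known
variant effects, and emits an exact ground-truth ledger — so the whole
pipeline is testable without any sequence download.

## Worked example

```python
import mitocohort as mc
from mitocohort import simulate as sim

ref = mc.load_reference()                      # bundled rCRS + annotation
space = mc.enumerate_substitution_space(ref)
print(int(space.totals["possible_synonymous"]),
      int(space.totals["possible_nonsynonymous"]))
# 8291 25894

# a synthetic cohort with one causal substitution (-55 cells/ul, 10%)
cfg = sim.planted_effect_config(ref, effect=-55.0, frequency=0.10, seed=7)
cohort = sim.simulate_cohort(cfg, ref, build_sequences=False)
G = mc.prevalence_filter(cohort.genotype_matrix()).matrix
res = mc.run_scan(G, cohort.metadata,
                  mc.ModelSpec(outcome="cd4_change", bootstrap=200, seed=1),
                  ref=ref)
print(res.results.head(1)[["substitution", "region", "beta", "se", "p"]])
#   substitution region       beta         se         p
# 0    m.5025C>T    ND2 -43.752947  11.950407  0.000251
```

The top hit is the planted substitution: its estimated effect on the
post-treatment CD4 count is −43.8 cells/µl (bootstrap SE 12.0,
p = 2.5 × 10⁻⁴), recovering the planted −55 within sampling error.
Annotation of the classic worked example:

```python
ann = mc.annotate_variant(mc.Variant(14308, "T", "C", "substitution"), ref)
print([(e.gene, e.synonymy) for e in ann.genes])
# [('ND6', 'synonymous')]
```

See `docs/methods.md` for the models, conventions and the design
decisions behind them.

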