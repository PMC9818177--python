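# Methods

## The statistical model

The pipeline treats a two-group methylation-array study (cases vs benign
controls) as a funnel of effect-size-gated hypothesis tests, followed by a
sign-consistency join with expression and two orthogonal screens
(enrichment, dependency correlation).

**Beta values.** For probe *i* with methylated intensity *M* and
unmethylated intensity *U*,

    β_i = max(M, 0) / (max(M, 0) + max(U, 0) + 100).

The clamping handles background-subtracted (possibly negative) channel
values; the +100 offset stabilizes low-intensity probes and makes β = 1
unreachable for finite intensities, so β ∈ [0, 1). The offset biases β
downward by a factor total/(total+100); at typical array totals (~5,000
units) this is < 2%, well inside the per-sample noise.

**Group tests.** All screens use the pooled-variance (Student) two-sample
*t*-test, not Welch: with 5-vs-6 sized groups there is little information
to estimate separate variances, and the pooled form is the stated
convention of this workflow family (a Welch escape hatch would be a
one-line change; `pooled_t_test` is the single code path all three screens
share). Degenerate rows — both groups constant, which truncated beta values
can produce — follow an explicit convention: *p* = 1 when the constants are
equal (no evidence), *p* = 0 when they differ (a deterministic separation).
Constancy is detected on the raw values, not on the computed variance,
because floating-point cancellation otherwise turns an exactly-constant
group into a tiny nonzero variance and a meaningless *t*.

**Probe vs region gates.** Probes are flagged at |Δβ| > 0.1 with raw
*p* < 0.05; regions — per-sample unweighted means of the probes sharing a
(gene, annotation-class) pair, under either the gene-annotation or the
CpG-island classification — at the stricter |Δβ| > 0.5. Both gates are
configurable. There is deliberately no multiple-testing correction in the
methylation screens: the effect-size gate is the primary false-positive
control (the null simulations below quantify this), and a
Benjamini–Hochberg column is available behind a flag for reporting.

**Fold change.** The DEG statistic is the ratio of arithmetic means of the
anti-logged signals, `mean(2^case)/mean(2^control)`, while the *t*-test
runs on the log2 scale. These intentionally disagree with each other's
conventions: the fold change weights high-signal samples more than a
geometric mean would (e.g. case log2 signals {0, 4} vs control {1, 1} give
FC = 4.25, not 2), and the test is variance-stabilized. Gates: FC > 2 or
FC < 0.5, *p* < 0.05.

**Gene-level reduction and integration.** Region screens yield several
records per gene; `resolve_gene_methylation` collapses them with the
PROMOTER_FIRST policy by default — among significant regions prefer the
promoter window (TSS1500, TSS200, 5'UTR, 1st exon), then the largest |Δβ|,
falling back to whatever the gene has. The default reflects the canonical
mechanism this pipeline is built to find: promoter methylation repressing
transcription, so promoter hypomethylation accompanying over-expression is
the HYPO_UP driver signature (and hypermethylation with silencing,
HYPER_DOWN). A MAX_ABS policy (largest |Δβ| anywhere) is exposed for
sensitivity analysis. Integration applies its own gates — |Δβ| > 0.1,
|log2FC| > 1, both raw *p* < 0.05 — to the *full* tables, not to the
0.5-gated region calls: the region gate is a reporting convention for
strong DMRs, while candidate selection is deliberately more inclusive.
Sign-discordant genes (hypo+down, hyper+up) are excluded and counted.

**Enrichment.** Over-representation uses the upper-tail hypergeometric
probability P(X ≥ m), evaluated through the distribution's survival
function (log-space internally), with Bonferroni over the number of terms
actually tested (terms with no member in the universe are not tested).
Bonferroni is the primary correction because it is the named procedure of
this workflow; BH is available. The universe defaults to all genes in the
study.

**Biomarker ROC.** AUC is computed as the Mann–Whitney U statistic over
n₁·n₂ — identical to the fraction of concordant case/control pairs with
ties counted ½ — under the convention that cases score high. The operating
threshold maximizes Youden's J (sensitivity + specificity − 1) over
observed values, predicting case at value ≥ threshold; ties resolve to the
lowest threshold.

**Dependency screen.** For each gene, Pearson correlation (two-sided *t*
*p*-value) between its expression across cell lines and the target gene's
effect score, run once per scoring algorithm; hits are r > 0 with
*p* < 0.05, and the two hit sets are intersected. Pearson is the default
because the relationship is modelled as linear (fitted-line screens);
Spearman is a flag. Genes with constant expression get r = 0, *p* = 1
rather than an error, with a logged count. Note the screen is one-sided in
effect (r > 0 of a two-sided test), so the per-screen null hit rate is
α/2.

## The synthetic cohort

`synthetic_data` emulates the study design this pipeline targets: 5 case
vs 6 control samples, ~2,000 genes, one probe group per gene per
annotation class (2 probes each by default).

- **Baseline methylation** is bimodal by CpG class — islands low
  (mean β 0.15), shores intermediate (0.45), shelves/open sea high
  (0.70–0.75), sd 0.05 between regions, 0.02 between probes of a region —
  with promoter-proximal classes island-biased in the class assignment.
  These constants are fixed design choices, not fitted to any dataset.
- **Planted drivers** shift the TSS1500/TSS200 regions by ∓0.3 β in cases
  only (HYPO_UP negative, HYPER_DOWN positive), on a mid-range baseline
  (0.4–0.6) so the shift never saturates; expression of the same genes
  shifts by ±2 log2 units with sd 0.5 noise.
- **Noise and intensities.** Per-sample Gaussian noise (sd 0.05) is added
  on the beta scale and truncated to (0.001, 0.999) — truncation counts
  are recorded; intensities are `M = total·β`, `U = total·(1−β)` with
  `total ~ N(5000, 750)` floored at 250.
- **Dependency panel.** 100 cell lines over 5 tissue lineages; a latent
  N(0,1) target-dependency vector, shifted −0.8 in thyroid-lineage lines
  (the planted most-dependent lineage); two observed effect vectors add
  independent algorithm noise (sd 1.1) that is made sample-orthogonal to
  the latent vector and to each other with exact sample scale. The
  orthogonalization removes small-panel seed luck so a finite panel's
  inter-algorithm agreement (r ≈ 0.5) matches the configured regime; at
  that agreement the two-screen intersection meaningfully removes
  coincident false positives while per-screen power for planted genes
  (population expression–latent correlation 0.6, observed ≈ 0.45 at
  n = 100) stays near 1.
- **Gene sets.** 50 random terms of 10–60 genes plus one planted term
  overlapping the planted gene set (drivers, or the dependency-correlated
  genes when no drivers are planted) at fraction 0.8.

Every generator is a pure function of the config (seed included); RNG
substreams are derived per stage so stages can be regenerated in
isolation.

**What the simulation does not emulate** — and therefore what passing
tests do not establish about real arrays: probe-level detection
*p*-values against background, dye bias, batch effects, realistic EPIC
probe geometry (type I/II chemistry, probe density per region),
correlated probes within regions beyond the shared baseline, copy-number
confounding of dependency scores, and non-Gaussian expression noise.
Recovery rates on planted truth are upper bounds on real-data
performance.

## Numerical and engineering choices

- All result tables are written as TSV with 6-significant-digit floats and
  documented sort keys (p-value then identifier), making repeated runs
  byte-identical; the run summary JSON is key-sorted with no timestamps,
  and carries a SHA-256 config hash.
- Problem sizes in the test and acceptance runs (1,000–2,000 genes, 1–2
  probes per region, 20-seed null sweeps) were chosen as the smallest
  cohorts at which the calibration and recovery properties are
  statistically unambiguous.
- The null-AUC check averages ~30 label permutations because a single
  permutation's AUC at n = 500 has sd ≈ 0.026, comparable to the tolerance
  being checked.
- `enrich` truncates to the top 10 significant terms by default, the usual
  reporting convention for pathway tables.
- Missing values in any input are hard errors; no imputation exists in v1.
- The CERES/Chronos-style gene-effect estimators themselves are out of
  scope: the screen consumes pre-exported effect vectors, as a user of a
  dependency portal would.

## Known limitations

- With 5-vs-6 groups the pooled *t* has 9 df; the region screen's 0.5 gate
  then dominates, and genuinely shifted regions with Δβ ≈ 0.3 are reported
  through the integration gates instead. This mirrors the intended
  division of labour but means `dmr_*.tsv` can be empty on realistic
  effect sizes.
- The zero-variance *p* ∈ {0, 1} convention is discontinuous: an
  infinitesimal jitter on a constant group yields a large finite *p*
  change. It only matters for saturated betas.
- Bonferroni over correlated, overlapping gene sets is conservative.
- The dependency screen's positive-correlation selection has no effect-size
  gate (`r_min` defaults to 0); at very large panels trivially small r
  would pass. Raise `r_min` for such panels.
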