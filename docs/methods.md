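# Methods

This note documents the models and procedures implemented in matrisopy, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic generators do and do not emulate.

## Domain-rule matrisome classification

A matrisome is constructed from domain annotations in three passes.

**Screen.** A protein is a candidate if at least one of its domain accessions
falls in the union of the rule set's inclusion lists. Screening is
deterministic and monotone: adding annotations can only add candidates.

**Curate.** Candidates are kept if they carry at least one *bona fide* ECM
domain — a configured high-confidence subset of the inclusion union that, in
the shipped default, excludes the ECM-affiliated lectin/galectin accessions
(proteins whose only evidence is an affiliated domain are too weakly tied to
the matrix to survive curation). Exact sequence duplicates collapse to the
lexicographically lowest identifier; every removal is recorded with a reason
in an exclusion report. Near-duplicate and artifact removal beyond exact
identity is out of scope: in real studies that step is manual.

**Assign.** Categories are evaluated in rule-set order — core categories
first, then associated, adhesome, other — and the first category whose
inclusion domains match, whose signal-peptide/membrane requirements hold, and
whose exclusion domains do *not* match, wins. Exclusion is evaluated before
inclusion, so a category is barred outright when any of its exclusion domains
is present (a cadherin-repeat protein can never be called an ECM
glycoprotein, whatever else it carries). A protein matching no category but
carrying a bona fide domain lands in `other/other_ecm`; otherwise it is
non-ECM. First-match precedence keeps assignment single-valued, and the
division counts therefore partition the curated set, with the matrisome size
always equal to core + associated.

The rule set ships as an editable YAML config. The default lists are a
working assembly of the standard category signatures (collagen triple helix
and NC1, LamG, TSP1, vWFA, EGF, FN3 for the core; astacin/peptidase, TIMP,
serpin, Kunitz for regulators; Wnt, TGF-β, IGFBP, Kazal for secreted factors;
cadherin, integrin, Ig-like for adhesion receptors), with a kinase-domain
exclusion throughout. They are matched against both InterPro and
member-database (Pfam/SMART) accessions, since annotation exports vary in
which space they report; the reader emits both when present and the rules
decide.

**Venom flagging** uses toxin-database BLAST results: a protein is a putative
venom when its best e-value is at or below 1e-3. The threshold direction is
"significant matches", i.e. small e-values flag; it is configurable.

## TMT stage comparison

The quantitative model assumes log2 reporter intensities are approximately
normal per protein with stage, replicate, and batch entering additively.

- **QC**: contaminant-flagged proteins and proteins quantified with fewer
  than 2 unique peptides are dropped (counts recorded).
- **log2**: zeros become missing values, never −∞; negative intensities are
  an error.
- **Technical replicates** are averaged to one column per biological sample
  before modelling, so residual degrees of freedom reflect biological
  replication only.
- **Batch cleanup**: per protein, OLS on condition (cell-means coding) plus
  treatment-coded batch indicators; only the estimated batch components are
  subtracted, so condition structure is untouched. Perfectly confounded
  batch/condition designs are rejected by a rank check.
- **Calibration**: `median_center` (default) subtracts each sample's median
  and rescales to a common median absolute deviation on the log2 scale;
  `affine_arsinh` fits h_s(x) = arsinh(a_s + b_s·x) per sample on the raw
  scale by iterative least-trimmed squares (middle 90% of proteins, ≤ 50
  iterations, convergence at 1e-6) against the across-sample mean profile.
  The first sample anchors the scale and log b_s is bounded within ±8 of the
  anchor's, because on data without shared protein structure the unbounded
  trimmed fit can legitimately flatten a sample (b→0), which destroys the
  strict monotonicity the calibration must preserve.

**Moderated t-test.** Per protein, OLS on the design (condition cell-means +
block factors); the contrast estimate is the log2 fold change, with unscaled
variance v_c = c'(X'X)⁻¹c. Residual variances are shrunk toward a prior
fitted by method of moments on log variances under the scaled-F model
s²_g ~ s₀²·F(df_g, d₀): matching the mean and variance of log s²_g to their
digamma/trigamma expressions gives a trigamma equation for d₀, solved by
Newton iteration (globally convergent since trigamma is monotone). When the
observed dispersion of log variances does not exceed the sampling
expectation, d₀ = ∞ and s₀² is the geometric mean of the observed variances
— so that identical variances pool exactly to their common value. The
moderated statistic t = fc/(s̃·√v_c) with s̃² = (d₀s₀² + df·s²)/(d₀+df) is
referred to t with d₀+df degrees of freedom (normal tails when d₀ = ∞;
d₀ = 0 reproduces the ordinary t and is available for comparison, never
fitted). Proteins with missing values are fitted on their observed samples;
those with fewer than 2 observations in a contrasted group are dropped from
that contrast with a count in the results.

**Hit rule**: BH false-discovery rate strictly below 0.05 *and* absolute
fold change of at least 2 (the fold-change boundary is inclusive — "at least
2-fold"). BH is applied within each contrast, not globally, because each
stage pair is reported as its own comparison. The fold-change filter is
applied to the contrast estimate, not to raw stage medians. Stage summaries
are per-stage medians of the normalized matrix.

## Single-cell expression

Counts live in an AnnData; the normalized layer is counts per cell scaled to
10,000 and log1p-transformed. Dot-plot summaries per gene × cluster report
percent of cells with a raw count > 0, the mean of expm1(normalized), and a
per-gene z-score of log1p(mean expression) across clusters clipped to ±2.5
(the conventional dot-plot "scaled average" semantics); genes with zero
across-cluster variance take scaled value 0 by convention.

**Detection predicate**: a gene is detectable in a transcriptomic state when
its percent detected is at least 5 (inclusive) *and* its scaled average is
above 0 ("above average"; the requirement is a toggle, since "above average"
admits other readings). Absence is the symmetric failure of the same
predicate rather than strictly zero counts, which makes the cascade robust to
ambient counts.

**Binning cascade** for cnidocyte-expressed genes: (1) not detectable in any
cnidocyte state → `not_expressed`; (2) detectable in more than 50% of
non-cnidocyte states → `ubiquitous`; (3) detectable in zero non-cnidocyte
states → exclusive, sub-binned by which cnidocyte class detects it
(specification/mature; genes detected in both default to
`exclusive_specification`, with the tie-break exposed because the published
phase-level and figure-level tallies of these bins do not reconcile — the
implementation reports whichever convention is configured and does not
attempt to resolve the discrepancy); (4) otherwise `shared`. Bins are
exhaustive and mutually exclusive, and raising the detection threshold can
only move genes toward `not_expressed`.

**Module scores**: genes are cut into 24 equal-frequency bins by
dataset-average expression; each gene-set member draws 100 control genes
uniformly without replacement from its bin (with replacement, with a warning,
when a bin is smaller); the score is the mean normalized expression of the
set minus that of the pooled controls. Scores are seed-deterministic.

**Markers**: two-sided Wilcoxon rank-sum of the target cluster against all
other cells, pre-filtered to ≥ 20% detection in target or rest and a log
fold-change of mean expm1 expression (+1) of at least 0.25. The return
threshold 0.001 applies to the unadjusted p (BH-adjusted values are still
reported) — the published description is ambiguous on this point, so it is
configurable. At ≤ 8 cells per side the p-value is computed by exact
enumeration over rank assignments with midranks; larger samples use the
tie-corrected normal approximation.

## Orthogroup complexity

For cross-species comparison, an in-silico matrisome is filtered to proteins
whose orthogroup contains at least one gene of at least one reference
(published) matrisome; genes without an orthogroup are excluded. The filter
is idempotent and monotone in the reference sets. The complexity record per
species is the filtered matrisome size and the number of distinct
orthogroups it occupies (necessarily no larger). Protein→gene mappings, when
supplied, are assumed 1:1 (isoform collapse is upstream) and add a distinct
gene count to the record.

## Synthetic generators

Every generator takes a seed, is bit-reproducible, and emits truth labels.

- **Proteomes**: template domain architectures per category (signal + triple
  helix + NC1 for collagens, signal + astacin for regulators, cadherin
  repeats + membrane for receptors, kinase-only for contaminants, ...), with
  jittered coordinates and composition-neutral random sequences — the
  classifier reads sequence only for duplicate collapse, so the class signal
  is carried entirely by the architecture. Planted architectures are
  unambiguous under the shipped rule set, which is what makes 100% recovery
  the correct expectation.
- **TMT**: log2 intensity = baseline N(20, 2) + signed stage effect (log2
  fold change uniform over the configured range) for a designated DE
  fraction + batch offset N(0, 0.5) + noise with per-protein variances from
  a scaled-inverse-χ²(d₀ = 4, s₀² = 0.05) — the heterogeneity that makes
  shrinkage matter. Defaults follow the three-stage, four-samples-per-stage
  biological-replicate design; on null data the pipeline's p-values are
  approximately uniform (checked by a KS test in the suite).
- **Atlases**: negative-binomial counts (gamma–Poisson, dispersion 0.5, a
  typical droplet-data value) with per-bin expression patterns at wide
  margins: expressed states at mean 3 counts/cell (detection ≫ 5%), silent
  states at 0.002 (detection ≪ 5%). Ubiquitous genes are expressed in all
  cnidocyte states and a strict majority — but not all — of the
  non-cnidocyte states: at least one silent state is required to anchor the
  across-cluster z-scores, otherwise a uniformly expressed gene's scaled
  averages hover at zero and the "above average" half of the detection
  predicate becomes a coin flip. Shared genes are expressed in exactly half
  of the non-cnidocyte states.
- **Orthogroups**: one orthogroup per target gene; a configured fraction
  also receives a reference-matrisome gene, plus decoy reference genes
  outside any matrisome set.

What the generators do **not** emulate: real domain-annotation noise
(spurious/missed domains, e-value spread), isoform structure, peptide-level
quantitation and its rollup, ambient RNA and doublets, cluster structure
beyond class labels, or realistic orthogroup size distributions. Passing
closed-loop tests therefore demonstrates that the *rules and statistics* are
implemented correctly, not that the pipeline is robust to every failure mode
of real annotation and measurement.

## Numerical choices and limitations

- Problem sizes in the test and acceptance runs (m = 1000 proteins × 12
  samples for error-control simulations, 2000 for prior recovery, ≤ 500×200
  cell fixtures) are chosen as the smallest sizes at which the asymptotic
  behaviour under test is stable.
- The moderated-test implementation is cross-checked against limma
  (lmFit/eBayes via Rscript) on a shared fixture at rtol 1e-5, and against a
  scripted-arithmetic oracle at 1e-10; the Rscript test skips cleanly when no
  R installation is present.
- Tie-breaks: duplicate collapse keeps the lowest id; category precedence is
  rule-set order; exclusive-bin ties default to specification.
- Degenerate inputs: empty files parse to empty collections; empty proteomes
  and empty reference sets give zero counts rather than errors; all-tied
  expression gives p = 1; zero-count cells, unknown labels, confounded
  designs, and out-of-domain p-values raise.
- p-values are floored at the smallest positive double so BH input stays in
  (0, 1].
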