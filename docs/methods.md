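# Methods

`mkptools` implements the computational workflow for discovering, gating,
and validating canonical vs noncanonical megakaryocyte progenitor
(cMkP / ncMkP) subtypes from multimodal single-cell data (RNA +
surface-protein ADT + lineage reporter label), together with the
downstream concordance scoring, flow-style quantification, and the
single-HSC clonal-restriction analysis.  This note records the models,
the numerical choices, and what the synthetic data does and does not
emulate.

## ADT normalization (CLR variant)

Raw ADT counts are compositional; each cell is normalized independently.
For a cell with counts `x_1..x_p` over `p` ADT features:

    s = Σ_{x_j > 0} ln(x_j + 1)
    g = exp(s / p)
    z_j = ln(1 + x_j / g)

Two deliberate dialect choices, both switchable per call:

- the nonzero log-sum is divided by the **total** feature count `p`, not
  the number of nonzero features (textbook CLR); `denominator="nonzero"`
  selects the textbook dialect;
- the final variance-stabilizing log is `log1p` of the normalized value,
  so zero counts map exactly to zero on the normalized scale;
  `final_log="log"` selects the plain-log dialect (zeros map to −inf).

## Mixture-model gating threshold

CD48 positivity on the CLR scale is decided by a two-component univariate
Gaussian mixture fitted by EM to the marker's normalized values among
RNA-annotated MkPs, with the threshold τ at the midpoint of the two
component means.  Numerical choices (the method itself does not dictate
them): means initialized at the 25th/75th percentiles, equal initial
weights, both standard deviations at half the sample SD; convergence when
the log-likelihood improves by less than 1e-6; at most 500 iterations;
standard deviations floored at 1e-6 to avoid component collapse;
components reported sorted by mean.  The EM log-likelihood path is stored
and asserted non-decreasing in tests.  Constant input or fewer than 10
finite values is an error.  On the default synthetic CD48 modes
(N(0.3, 0.1²) and N(1.9, 0.2²)), τ lands at ≈ 1.10.

## Manual protein gates and RNA gate

The hierarchical flow-style gate: MyPro = Sca1 < 0.71 AND CD117 > 1;
MkP = MyPro AND CD150 > 0.45 AND CD41 > 0.6; MkPs split into cMkP
(CD48 ≥ τ) vs ncMkP (CD48 < τ).  Boundary conventions: the MyPro/MkP
inequalities are strict as printed; CD48 positivity is inclusive at τ
(the boundary convention is not dictated by the gate definitions; we fix
it once).  The RNA-only gate calls positivity as expression > 0 counts
and classifies Cd48+F11r− as cMkP-like, Cd48−F11r+ as ncMkP-like,
excluding double-positive and double-negative cells with the exclusion
reason recorded.  Four per-barcode annotation schemes are produced:
reporter-based (RNA + GFP/Tom), RNA + protein (CD48 split of RNA MkPs),
protein-only (full gate tree), and RNA-only (transcript gate).
Cells carrying both reporter labels count as GFP (they have genetically
switched).

## Pseudobulk differential expression

Single-cell counts are summed into one pseudobulk sample per
biosample × condition.  The engine is a deliberately compact DESeq2-style
negative-binomial Wald test:

- **size factors**: median-of-ratios to the per-gene geometric mean over
  genes with no zero count (factors are defined up to a common scale);
- **dispersion**: per-gene method of moments on normalized counts with a
  degrees-of-freedom adjustment (`m − 2` residual df for the two fitted
  group means), Poisson component `mean(1/s)·μ` subtracted, floored at
  1e-8 and capped at 20;
- **GLM**: two-group NB regression with log link and size-factor offsets,
  fitted by iteratively reweighted least squares (weights μ/(1+αμ),
  initialized at group means, tolerance 1e-8, max 100 iterations);
- **inference**: Wald statistic on the condition coefficient referred to
  a t distribution with `m − 2` degrees of freedom.  The t reference is a
  small-sample calibration choice: with plug-in moment dispersions at
  4 vs 4 replicates, normal quantiles give an empirical size near 0.10 at
  nominal 0.05, while the t reference keeps it near 0.05 (verified by
  simulation in the acceptance script);
- **multiplicity**: Benjamini–Hochberg across genes with a defined
  p value; all-zero or degenerate-fit genes get missing p/padj.

No dispersion-trend or MAP shrinkage, no LFC shrinkage, no independent
filtering, no outlier refitting, two-condition designs only.  On matched
simulations the engine's log2FC agrees with pyDESeq2 to ≈ 0.003 mean
absolute difference (asserted in tests, where pyDESeq2 serves as the
independent reference, never as the implementation).

Two properties of median-of-ratios normalization worth noting: factors
are meaningful only as ratios, and a large one-directional fraction of
truly differential genes (≳ 10–25%) shifts the median ratio and deflates
fold-change estimates — identically so in DESeq2.

### baseMean and DEG filters

`baseMean` within a condition is the mean of size-factor-normalized
counts across that condition's samples.  Candidate-marker filters:
drop blocklisted genes (mitochondrial, ribosomal, Malat1), drop genes
with no adjusted p value, drop genes whose baseMean is at or below the
abundance floor in **both** conditions (50 for bulk RNAseq, 5 for
pseudobulk single-cell; the boundary is "at or below", applied
symmetrically to both kinds), then apply either

- strict: |log2FC| ≥ 2.5 AND padj < 0.01, or
- relaxed: |log2FC| ≥ 1.5 OR padj < 0.1.

The fold-change thresholds act on |log2FC|; the relaxed rule is a
genuine OR (it admits genes with small fold change but small padj),
which is permissive by construction.

### ADT scoring

Group differences per ADT are scored with a tie-corrected
normal-approximation Wilcoxon rank-sum z (positive when the first group
is higher; exact tests are unnecessary at single-cell group sizes) or
with the overestimated-variance t statistic, in which both group
variances are divided by the first group's size — deliberately
overestimating the second group's standard error, and therefore not
antisymmetric under group swap when sizes differ.  Candidates keep
|score| ≥ 10 (restrictive) or ≥ 5 (relaxed) after removing mature-lineage
markers (CD3, CD4, CD5, CD8a, CD11b, Gr1, B220, Ter119) and the markers
that define the MkP gate itself (CD117/cKit, Sca1, CD150, CD41).

## Triage and concordance

Candidate markers require membrane-bound and antibody-available curation
flags (input metadata, not predicted) plus at least one evidence flag
among bulk/sc strict/relaxed DEGs and restrictive/relaxed ADT scores;
the bulk∩sc relaxed intersection is reported separately.  Flow validation
uses the fold change of background-subtracted MFIs with a two-fold pass
criterion in either direction; a nonpositive background-subtracted value
makes the ratio undefined and is flagged rather than raised.

Cross-annotation concordance: for each reference class, the capture rate
is the fraction of its barcodes assigned to the mapped test class;
unmatched or unlabeled barcodes are excluded and counted.  DEG-list
overlaps are reported as exclusive Venn region counts plus pairwise
Jaccard.

## Clonal restriction

Wells with ≥ 1 MkP are evaluable; wells without MkPs count only toward
the MkP-generation frequency.  Under strict clonal restriction every
evaluable well is pure, so with exact subtype calls a single mixed well
gives p = 0 against the strict model; with an optional per-MkP
misclassification rate ε > 0 the p value is the Poisson-binomial tail of
the mixed-well count over wells of observed sizes.  Under independent
per-MkP commitment at noncanonical probability p, the expected mixed
fraction is the mean over wells of `1 − p^n − (1−p)^n`; p is estimated by
pooling MkPs across wells (MkP-weighted, matching the generative model),
and observed-minus-expected is reported with a seeded percentile
bootstrap over wells (default 1000 resamples).  The bootstrap interval
slightly under-covers (≈ 85–90% at nominal 95% in simulations); it is a
descriptive compatibility band, while the strict-model verdict rests on
the exact mixed-well argument.

## Flow quantification

Absolute counts use the bead ratio `events_pop × beads_added /
events_beads` (per-μl when a volume is given).  Chimerism is the
baseline-subtracted donor fraction floored at 0 (the floor is our
convention for negative differences).  MFI is median minus background,
negative values allowed.  Activation-kinetics AUC is the trapezoidal
integral on raw timestamps, no smoothing or interpolation.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not real biology:

- RNA counts are negative-binomial (default dispersion 0.1) with
  lognormal per-gene base abundances, lognormal per-cell library sizes
  (sd 0.3), planted multiplicative group effects, a fixed blocklist gene
  set (3 mitochondrial, 4 ribosomal, Malat1), and subtype-dependent
  Cd48 / F11r marker genes so the RNA gate is meaningful.
- ADT counts are generated by sampling per-cell targets on the CLR scale
  (per-ADT, per-subtype Gaussian modes) and numerically inverting the
  CLR map: the per-cell scale g solves the fixed point
  g = exp(mean_j log1p(g·(e^{z_j} − 1))), iterated to convergence (the
  map is a log-scale contraction when enough panel markers are dim) and
  rounded to integer counts.  This controls gating-marker modes directly
  on the scale the gates operate on.  The 13-marker default panel puts
  CD48 at (1.9, 0.2) in cMkPs vs (0.3, 0.1) in ncMkPs — so the fitted
  mixture midpoint lands near 1.1 — keeps MkP-defining markers inside
  the manual gates for both subtypes, gives MyPro cells low CD150/CD41,
  and includes dim lineage markers.  If nearly every target is bright no
  finite fixed point exists; g is capped at 1e6 and the profile is
  unrepresentable.
- The GFP/Tom reporter is assigned from the true subtype with
  concordance 0.95 by default — a free parameter chosen to emulate
  near-but-imperfect correspondence between lineage label and phenotype;
  no single empirical rate is available to calibrate it.
- Default subtype mix: young 80% cMkP / 10% ncMkP / 10% MyPro, old
  50% / 35% / 15% — ncMkPs rare in youth and expanding with age; the
  exact fractions are a realism choice, fixed once.
- Well outcomes: strict-restriction wells draw one subtype per well,
  independent wells draw each MkP i.i.d.; well sizes are user-supplied,
  live-cell counts add Poisson(30) background.
- Flow events: lognormal channel intensities around a given median;
  beads carry a bright tight signal under a reserved population label.

Not emulated: read-level data and UMI collapsing, ambient/doublet
artifacts, batch effects, dispersion–mean trends, cell-cycle structure,
and compensation/spillover.  Passing tests therefore demonstrate
correctness of the computations under the assumed generative structure,
not robustness to those real-data artifacts.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen once: 2000-cell
multimodal datasets (200 genes, 13 ADTs), 2000-gene 4 vs 4 pseudobulk
tables for engine calibration (20 null replicates, 100 planted genes at
|log2FC| = 3 over 5 replicates), 20 seeds for mixture-threshold
recovery, 100 seeded runs per clonal-restriction model, and 10000-well
checks of the analytic mixed-fraction formula.

## Known limitations

- The DE engine targets two-group designs with replicates; it is not a
  general-purpose DESeq2 replacement (no shrinkage, no multi-factor
  designs), and with 4 replicates per group the information bound on
  log2FC precision is about ±0.34 (1 SD) at dispersion 0.1 — effect
  estimates at that depth are honest but noisy.
- The relaxed DEG rule's OR admits low-fold-change genes by design.
- The clonal analysis models strict restriction vs full independence
  only; intermediate (overdispersed) commitment is reported descriptively
  via observed-vs-expected mixed fractions but not modeled.
- FCS binary parsing is out of scope; flow event tables are CSV.
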