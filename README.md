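# mkptools

Toolkit for discovering, gating, and validating **canonical vs
noncanonical megakaryocyte progenitor (cMkP / ncMkP) subtypes** from
multimodal single-cell data.

During aging, a distinct population of megakaryocyte progenitors (MkPs)
arises directly from hematopoietic stem cells (HSCs), bypassing the
canonical differentiation path.  In lineage-tracing mice these cells are
identifiable by a reporter (Tom+ vs GFP+), but a surface-marker scheme —
cMkP = CD48+CD321−, ncMkP = CD48−CD321+ — makes them accessible in
unmodified animals.  `mkptools` implements the computational workflow
behind that scheme for anyone working with CITE-seq (RNA + ADT) data,
flow cytometry tables, and single-progenitor culture outcomes:

- **ADT normalization**: a per-cell CLR variant,
  `z_j = ln(1 + x_j / g)` with `g = exp(Σ_{x>0} ln(x+1) / p)`, so zero
  counts stay zero on the normalized scale.
- **Gating**: a two-component Gaussian mixture on normalized CD48 with
  the positivity threshold at the component-mean midpoint; hierarchical
  manual protein gates (Sca1 < 0.71, CD117 > 1 → MyPro; CD150 > 0.45,
  CD41 > 0.6 → MkP; CD48 ≥ τ → cMkP); an RNA-only Cd48/F11r gate; and
  four parallel per-barcode annotation schemes.
- **Differential expression**: pseudobulk aggregation, median-of-ratios
  size factors, a negative-binomial Wald engine
  (log2FC, BH-adjusted p, per-condition baseMean), blocklist/abundance
  filters, and strict (|log2FC| ≥ 2.5 ∧ padj < 0.01) / relaxed
  (log2FC ≥ 1.5 ∨ padj < 0.1) candidate thresholds.
- **ADT scoring & triage**: Wilcoxon / overestimated-variance t scores
  with restrictive (|z| ≥ 10) and relaxed (|z| ≥ 5) cutoffs, lineage and
  MkP-defining markers excluded; evidence intersection with
  membrane/antibody curation flags; two-fold MFI validation.
- **Concordance**: per-barcode capture rates between annotation schemes,
  confusion tables, DEG-set Venn overlaps and Jaccard.
- **Clonal restriction**: per-well subtype fractions from single-HSC
  cultures, the analytic mixed-well expectation
  `1 − p^n − (1−p)^n` under independent commitment, and a test of the
  strict clonal-restriction model (any mixed well falsifies it).
- **Flow quantification**: bead-based absolute counts, donor chimerism,
  background-subtracted MFI, activation-kinetics AUC.
- **Synthetic data**: seeded generators for multimodal datasets (NB RNA
  with planted log2 fold changes, ADT counts inverted from CLR-scale
  targets), well tables, and flow event tables, so the full pipeline
  runs and is testable without any external data.

See `docs/methods.md` for models, numerical choices, and limitations.

## Worked example

```python
from mkptools.simulate import SimConfig, generate_multimodal, generate_wells
from mkptools.normalize import clr_normalize_matrix
from mkptools.gating import annotate_schemes
from mkptools.concordance import capture_rate
from mkptools.clonal import test_strict_restriction

# 2000 synthetic cells: CD48-bimodal ADTs, GFP/Tom reporter at 95% concordance
ds = generate_multimodal(SimConfig(seed=0))
clr = clr_normalize_matrix(ds.adt_frame())
ann = annotate_schemes(ds, adt_clr=clr)
print(round(ann.attrs["cd48_threshold"], 3))      # 1.109
print(ann["protein_only"].value_counts().to_dict())
# {'cMkP': 1288, 'ncMkP': 461, 'MyPro': 241, 'unlabeled': 10}

rep = capture_rate(ann["rna_reporter"], ann["protein_only"],
                   {"cMkP": "cMkP", "ncMkP": "ncMkP"})
print({k: round(v, 3) for k, v in rep.capture_rates.items()})
# {'cMkP': 0.979, 'ncMkP': 0.888}

wells = generate_wells("independent", 0.3, 4, 500, seed=0)
res = test_strict_restriction(wells, seed=0)
print(round(res.mixed_fraction, 3), round(res.expected_mixed_independent, 3),
      res.strict_rejected)                        # 0.74 0.745 True
```

Reading: the mixture fit on CD48 places the positivity threshold at
1.109 on the CLR scale; the protein-only gate then recovers 97.9% of
reporter-defined cMkPs and 88.8% of ncMkPs (the gap reflects the 5%
reporter/subtype label noise plus gate tails).  In the well experiment,
74.0% of wells contain both subtypes, matching the 74.5% expected under
independent per-MkP commitment at the pooled ncMkP frequency — so a
strict clonal-restriction model (which predicts 0% mixed wells) is
rejected.

A command-line interface mirrors the library:

```bash
mkptools simulate --seed 0 --out data/
mkptools normalize --adt adt.csv --out clr.csv
mkptools gate --clr clr.csv --out labels.csv
mkptools de --counts pseudobulk.csv --meta samples.csv --mode relaxed --out degs.csv
mkptools wells --wells wells.csv --out report.json
```

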