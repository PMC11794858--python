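# fcbiotype

Functional-connectivity biotyping: data-driven stratification of a
clinical cohort from resting-state brain connectivity.

Psychiatric risk populations — here, individuals at clinical high risk
(CHR) for psychosis — are biologically heterogeneous: patients with
similar symptoms can carry distinct network-level brain alterations.
`fcbiotype` implements the full stratification pipeline that turns
per-subject ROI x ROI Fisher-z connectivity matrices, a clinical table
(19 SIPS symptom items, 2 GAF scores, 8 MCCB cognitive tests) and a
246-region network-labeled atlas into validated connectivity *biotypes*:

1. **Edge selection** — Pearson-correlate all P(P−1)/2 edges with the 21
   clinical items over patients; keep edges with p < 0.005 on ≥ 3 items.
2. **Multikernel similarity clustering** (SIMLR-style) — learn a
   row-stochastic subject similarity S jointly with weights w over 55
   locally-scaled Gaussian kernels and a low-rank spectral factor L by
   block-coordinate descent on

       min −⟨K_w, S⟩ + β‖S‖²_F + γ tr(Lᵀ(I−S_sym)L) + ρ Σ w_m log w_m ,

   with S rows and w on the probability simplex and LᵀL = I; cluster the
   spectral embedding with k-means.
3. **Cluster-number estimation** — eigengap of the normalized Laplacian
   of the sparse row-stochastic similarity, k ∈ 2..8.
4. **Stability** — 500 × 90% patient subsampling with full re-selection
   and re-clustering; modal k; NMI of iteration labels vs the final
   partition against a label-shuffling null; repeated stratified 10-fold
   linear-SVM accuracy.
5. **Contrasts** — per-edge GLM (biotype vs controls, adjusted for sex,
   age, education), signed binarization at p < 0.005, and a
   network-pair cluster-mass permutation test with BH-FDR (q < 0.05)
   over the 36 network blocks.
6. **Neurochemistry** — per-ROI counts of abnormally increased /
   decreased edges, spatially correlated with 39 parcellated
   receptor/transporter density maps, BH-FDR over the whole table.

Because cohorts of this kind are rarely shareable, the package ships a
first-class synthetic-data module that draws cohorts with the same
statistical structure (three planted biotypes with network-specific
signed effects, symptom-coupled edges, receptor maps with planted
spatial correlation), so every stage is testable end to end without any
download. See `docs/methods.md` for the model details and what the
generator does and does not emulate.

## Worked example

```python
import numpy as np, fcbiotype as fb
from sklearn.metrics import adjusted_rand_score

design = fb.SimulationDesign(seed=1)           # 151 CHR + 88 HC, 246 ROIs
cohort, stack, truth = fb.simulate_cohort(design)

chr_idx = np.flatnonzero(cohort.group_mask("CHR"))
edges = stack.edges[chr_idx]
items = cohort.clinical_items(chr_idx).to_numpy(float)

sel = fb.screen_and_select(edges, items)       # symptom-correlated edges
solution, learned, k_hat = fb.simlr(edges[:, sel.selected_edges], seed=0)
print(sel.n_selected, k_hat, solution.sizes,
      adjusted_rand_score(truth.biotype_labels, solution.labels))
```

prints

```
689 3 [77 45 29] 1.0
```

i.e. 689 of 30,135 edges survive the clinical screen, the eigengap
estimates three clusters, their sizes are 77/45/29 (51.0 / 29.8 / 19.2%
of the patients), and the partition matches the planted biotypes
exactly (adjusted Rand index 1.0). The `examples/` directory has one
short script per capability — simulation, selection, clustering,
stability, group contrasts, neurochemistry, and summary-table
statistics — each printing its results with a note on what they mean.

A thin CLI covers the shell-level entry points:

```bash
fcbiotype simulate --out bundle/ --seed 1   # write a synthetic input bundle
fcbiotype validate --input bundle/          # consistency checks
fcbiotype run-all --input bundle/ --out results/ --seed 1
fcbiotype table-stats summary.tsv           # pooled t-tests from a summary table
```

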