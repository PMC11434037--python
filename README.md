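# hypoximm

Analysis toolkit for studying how tumor hypoxia remodels the immune
microenvironment. It is aimed at computational biologists working with
bulk, single-cell, and spatial transcriptomics of tumors who want a
tested, reproducible implementation of the following chain:

- **Hypoxia scoring** — single-sample enrichment of a 15-gene
  HIF1A-associated signature (ACOT7, ADM, ALDOA, CDKN3, ENO1, LDHA, MIF,
  MRPS17, NDRG1, P4HA1, PGAM1, SLC2A1, TPI1, TUBB6, VEGFA) via a weighted
  Kolmogorov–Smirnov rank walk (ssGSEA-style, exponent 0.25), plus a
  mean-scaled-z scorer for single cells.
- **Tumor-boundary delineation** on hexagonal spot lattices: QC
  filtering, malignant-core seeding from a malignancy signature,
  layer-wise extrapolation in principal-component space, and Mal / Bdy /
  nMal region labels with hypoxia-score summaries.
- **Spot deconvolution and co-localization** — non-negative least
  squares (min‖y − S·w‖², w ≥ 0) against cell-type references, ALCAM-high
  macrophage gating, Tex-spot gating, and first-outer-circle
  co-localization with a Wilcoxon exhaustion-score contrast.
- **Immunophenoscore (IPS)** — the sum over four immune categories
  (effector cells, suppressor cells, MHC, checkpoints) of averaged
  ±1-weighted sample z-scores.
- **Pseudotime TF screen** — first-PC cell ordering, natural-spline
  trend F-tests with BH correction, the three-stage differentiation
  filter (p < 0.05, q < 0.05, rising toward the trajectory end,
  consistent in ≥ half of all datasets), and Spearman classification
  against the hypoxia score.
- **Survival / ICB statistics** — Spearman + FDR screens, Wilcoxon
  contrasts of responders vs non-responders (PD vs CR/PR, or the IMvigor
  pooling PD vs CR/PR/SD), maximally selected log-rank cutpoints, and
  Kaplan–Meier / log-rank machinery.

A first-class synthetic-data module generates hex-lattice slides with a
malignant core / boundary ring / non-malignant exterior, staged bulk
cohorts whose hypoxia program drives survival and therapy response, and
single-cell T-cell datasets along a naive→exhausted pseudotime axis — all
with ground truth, so every analysis is validated by parameter recovery.
See `docs/methods.md` for models, assumptions, and design choices.

## Worked example

Simulate a 217-spot slide (8 rings, 3-ring malignant core), delineate the
tumor boundary, and summarize hypoxia by region:

```python
from hypoximm import simulate as sim, regions as reg
from hypoximm.scoring import hypoxia_signature, score_rank_enrichment

slide = sim.simulate_slide(sim.SlideSimParams(seed=0))
sq = reg.qc_filter(slide)
graph = reg.build_neighbor_graph(sq)
core = reg.identify_malignant_core(sq, sim.default_programs()["malignancy"], graph)
assign = reg.delineate_boundary(sq, graph, core)
hyp = score_rank_enrichment(sq.expr, hypoxia_signature())
summary = reg.summarize_region_scores(hyp, assign)
print(summary[["n_spots", "mean_score", "normalized_mean"]].round(3))
```

```
        n_spots  mean_score  normalized_mean
region
Mal          37       0.394            1.000
Bdy          24       0.277            0.587
nMal        156       0.111            0.000
```

The malignant region has the highest hypoxia score, the boundary ring is
intermediate, and the exterior lowest (Wilcoxon Mal vs Bdy p = 9.6e-11,
Bdy vs nMal p = 4.1e-10 on this slide) — and the recovered labels match
the generator's ground truth (37/24/156 spots).

The same pipeline is available from the shell; every subcommand writes a
JSON manifest with SHA-256 digests so runs are byte-for-byte
reproducible:

```
hypoximm simulate --kind slide --out-dir slide --seed 13
hypoximm score    --matrix slide --out scores.tsv
hypoximm regions  --slide-dir slide --out regions.tsv
hypoximm deconv   --slide-dir slide --ref-dir slide/ref --out props.tsv
hypoximm coloc    --slide-dir slide --props props.tsv --regions regions.tsv --out coloc.tsv
```

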