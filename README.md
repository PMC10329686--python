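# spotloc

Recover spatial locations and ordered tissue domains for dissociated single
cells from a spatial-transcriptomics (ST) reference.

A supervised feed-forward network is trained on spot-level expression with
known positions and then applied to scRNA-seq/snRNA-seq query cells. Four
interchangeable heads cover the tasks:

- **coord2d** — 2D tissue coordinates in the unit square (summed squared
  error loss, sigmoid outputs);
- **ellipse** — an axis-aligned elliptical prediction region per cell
  (center + strictly positive semi-axes) fit with an asymmetric
  quantile-style loss calibrated to a target coverage `alpha`, plus a
  certainty score (1 − normalized ellipse area);
- **domain** — unordered spatial domains via one-vs-rest logistic scores;
- **ordinal** — ordered layers (e.g. cortical L1…L6, WM) via a
  rank-consistent cumulative-logit loss with monotone cut points.

An optional augmentation stage fabricates replicate training "sections"
from limited ST data: per-gene 2D rasterization of the spot grid, K-means
clustering of genes by spatial pattern, and a cluster-conditioned
variational autoencoder (conv encoder 16/8/4 channels, mirrored decoder,
embedding dim 512, KL weight β = 1e-5, 2 replicates by default). Replicates
reuse the source spots' coordinates and labels and are concatenated with the
original rows for training.

Everything runs on NumPy: the models are built on a small internal
reverse-mode autodiff engine (`spotloc._nn`), so there is no deep-learning
framework dependency.

## Library quick start

```python
import spotloc as sl

# seeded synthetic tissue: gradient genes + nulls over a holed grid
genes = [(f"g{i}", sl.LinearGradient("row", 2.0)) for i in range(20)]
spec = sl.TissueSpec(grid=(30, 30), hole_fraction=0.1, genes=genes, seed=0)
ref = sl.normalize_expression(sl.make_reference(spec))     # log1p + z-score
query = sl.make_query(spec, 500, noise_sd=0.0, seed=1)     # normalized cells

ref, query = sl.harmonize_genes(ref, query)
cfg = sl.LocationModelConfig(task="coord2d", epochs=500, seed=0)
model = sl.train_location_model(ref, config=cfg)
preds = sl.predict(model, query)                           # coords in [0,1]^2

truth = sl.scale_coords(query.true_coords, model.scaler)
print(sl.pairwise_distance_correlation(preds.coords, truth))
```

Augmentation:

```python
stack = sl.rasterize_genes(ref)                  # per-gene 2D images
clusters = sl.cluster_genes(stack, K=20, seed=0)
vae = sl.train_augmenter(stack, clusters, sl.AugmenterConfig(seed=0))
reps = sl.generate_replicates(vae, stack, clusters, R=2, seed=1)
model = sl.train_location_model(ref, replicates=reps, config=cfg)
```

## CLI

```bash
spotloc simulate --preset layers --out run/ --grid 30,30 --seed 0
spotloc preprocess --input run/reference.csv --out run/ref_norm.csv
spotloc augment   --input run/ref_norm.csv --out run/aug --k-clusters 20 --seed 0
spotloc train     --input run/ref_norm.csv --task ordinal --epochs 500 \
                  --replicates run/aug --out run/model --seed 0
spotloc predict   --model run/model --query run/query.csv --out run/preds.csv
spotloc evaluate  --pred run/preds.csv --truth run/query.csv \
                  --task layers --out run/report.json
```

Artifacts carry `.meta.json` provenance sidecars (config hash, seed,
package version); progress is logged as JSON lines on stderr. Inputs may be
CSV, Matrix Market (+ `genes.tsv`/`barcodes.tsv`/`coords.tsv` sidecars) or
h5ad.

## Module map

| Module | Role |
| --- | --- |
| `spotloc.io_preprocess` | containers, CSV/MTX/h5ad I/O, log1p + z-score normalization, gene selection/harmonization, multi-section merging, condition-invariant gene filter |
| `spotloc.augmentation` | rasterization, gene clustering, cluster-conditioned VAE, replicate sampling |
| `spotloc.location_models` | the four losses, coordinate scaler, predictor training |
| `spotloc.inference` | prediction sets, certainty scores, label assignment |
| `spotloc.evaluation` | top-1/top-2 layer accuracy, pairwise-distance correlation, Euclidean errors, recovered expression maps, SSIM |
| `spotloc.synthetic_data` | seeded tissue simulators (layer bands, gradients, co-expressed families) |
| `spotloc.cli` | `spotloc` pipeline entry point |
| `spotloc._nn` | minimal autodiff engine, layers, Adam |
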