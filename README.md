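# stilmap

Spatial analysis of tumor-infiltrating lymphocytes (TILs) on whole-slide-image
patch lattices, and its downstream use for predicting lymph node metastasis
(LNM) in lung adenocarcinoma.

Digital pathology pipelines tile a whole slide image into fixed-size patches
(here 150×150 px at 20×) and classify each tissue patch as TIL-positive,
TIL-negative, or necrotic/other. `stilmap` consumes that patch-label contract
and provides, for researchers working on the tumor immune microenvironment:

1. **TIL scores** — per slide, the TIL-positive fraction among non-necrotic
   tissue patches, `score = n_pos / (n_pos + n_neg)`; per patient, the mean
   over slides.
2. **Hot spot maps** — local Getis-Ord Gi* statistics on the masked patch
   lattice (queen contiguity, self-included),

   ```
   z_i = (Σ_j w_ij x_j − x̄ W_i) / (S · sqrt[(n U_i − W_i²)/(n − 1)])
   ```

   with x the binarized TIL field, W_i = Σ_j w_ij and U_i = Σ_j w_ij²,
   rendered as diverging blue–white–red maps (red = local TIL enrichment).
3. **Spatial TIL clusters (sTILCs)** — hot spot maps are resized to
   1024×1024×3, encoded by a fixed random 4-stage convolutional encoder into
   16,384-dimensional vectors, reduced by PCA (95% cumulative variance), and
   partitioned by K-means; the cluster count is chosen by a consensus vote of
   the Silhouette score, Davies-Bouldin index and Calinski-Harabasz index
   over k ∈ {2..6}. The cluster with the lower mean hot fraction is named
   sTILC1 ("TIL-cold"), the other sTILC2 ("TIL-hot").
4. **LNM model comparison** — random-forest models M1 (age category, T stage,
   TIL score, sTILC) vs M2 (age category, T stage) with cross-validated
   hyperparameters, evaluated by ROC AUC, the DeLong test for correlated
   AUCs, the Brier score, exact interventional Shapley attributions (all 2⁴
   coalitions), and decision-curve net benefit
   `NB(t) = TP/N − FP/N · t/(1−t)`.
5. **Synthetic cohorts** — spatially autocorrelated TIL lattices from two
   archetypes (sparse/weakly clustered "cold" vs dense/strongly clustered
   "hot") and a logistic LNM outcome with protective TIL effects, so every
   stage can be exercised end to end with known ground truth.

## Worked example

```python
import numpy as np
from stilmap.simulate import CohortSpec, generate_cohort
from stilmap.hotspot import compute_hotspot_map, render_hotspot_map
from stilmap.encoder import EncoderConfig, encode_hotspot_map, preprocess_map_image
from stilmap.clustering import fit_pca, consensus_k_selection, assign_stilc_names
from stilmap.lattice import compute_til_score

cohort = generate_cohort(CohortSpec(n_patients=200, seed=101))
print(compute_til_score(cohort.grids[0]))

cfg = EncoderConfig()  # the package's fixed filter bank
maps, feats = [], []
for grid in cohort.grids:
    hmap = compute_hotspot_map(grid)
    maps.append(hmap)
    feats.append(encode_hotspot_map(preprocess_map_image(render_hotspot_map(hmap)), cfg))
pca, reduced = fit_pca(np.vstack(feats), variance_target=0.95)
vote = consensus_k_selection(reduced, seed=7)
print(vote.winners, "->", vote.selected_k)
stilc = assign_stilc_names(vote.selected_labels, maps)
```

prints (abridged):

```
TILScore(value=0.079006..., n_pos=105, n_tissue_nonnecrotic=1329)
{'silhouette': 6, 'davies_bouldin': 2, 'calinski_harabasz': 2} -> 2
```

i.e. the first simulated slide has 7.9% TIL-positive tissue (a cold slide),
and the Davies-Bouldin/Calinski-Harabasz majority selects two spatial TIL
clusters (the silhouette differences across k are a few thousandths here),
which are then named sTILC1/sTILC2 by their hot spot content. The numbered scripts
under `analysis/` walk the same path stage by stage on a persisted cohort
(simulation → TIL scores → hot spot maps → sTILCs → M1/M2 comparison) and
write their tables under `results/`; the `stilmap` CLI
(`stilmap simulate|score|hotspot|cluster|model|report --config run.yaml`)
runs the identical stages from a YAML config.

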