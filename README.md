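# seafusion

Multi-omics data fusion for detecting illicit fish conservation
treatments, with the companion 16S microbiome statistics chain.

"Cafodos" (a sodium-citrate / hydrogen-peroxide mixture) is fraudulently
applied to mask spoilage in fish such as sea bass. Its signature is
diffuse — it touches lipids, metabolites, proteins, and the surface
microbiome — so no single marker suffices. `seafusion` implements the
multivariate workflow used to find that signature in a paired study
design: on each experimental day one treated and one control fish are
processed together (6 day-pairs per exposure time, 3 h and 24 h; 24 fish
total), and each fish is sampled at up to four sites (muscle, skin,
gills, eye) by several omics platforms.

The package is for analysts who have per-sample feature tables
(lipidomics / metabolomics / proteomics intensities) and OTU count
tables, and want reproducible discrimination models plus the standard
microbiome statistics — or who want to study the behavior of this class
of workflow on synthetic data with known ground truth.

## Methods at a glance

* **Paired preprocessing.** Each feature is centered per day-pair
  (`x_i ← x_i − mean(pair)`), removing the additive day batch effect
  exactly, then autoscaled (mean 0, unit variance, `n−1` denominator).
* **Low-level fusion.** Blocks are concatenated column-wise with
  provenance bookkeeping: `X = [X_lip | X_metab | X_prot]`.
* **MFA** (Multiple Factor Analysis): global PCA after rescaling each
  block by `1/λ₁(block)`, so every block starts with equal inertia; an
  optional qualitative "classes" block (scaled indicator coding)
  participates like any other. Outputs scores, block contributions and
  variable contributions per dimension.
* **BE-PLS-DA**: two-class PLS-DA (NIPALS, y = +1 control / −1 treated)
  with VIP scores
  `VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)`,
  wrapped in backward elimination: remove the minimum-VIP feature, track
  the venetian-blind cross-validated error (one fold per day-pair,
  autoscaling re-estimated inside every fold), and keep the feature set
  with the best cross-validated prediction error (RMSECV).
* **Microbiome chain**: bias-corrected Chao1, Shannon, Gini–Simpson;
  Bray–Curtis + PCoA; Kruskal–Wallis and PERMANOVA; TMM normalization;
  per-taxon negative-binomial GLM with Wald test and Benjamini–Hochberg
  FDR, over the study's six contrast families.
* **Synthetic data**: paired designs with log-normal feature means,
  pair-shared day effects, sparse planted treatment effects, and
  negative-binomial OTU counts with planted fold changes — every stage
  has a parameter-recovery test surface.

## Worked example

Build the fused 3 h muscle model on synthetic data (blocks of 921
lipids, 464 metabolites, 66 proteins; 20 planted features per block at
standardized effect 3):

```python
from seafusion.design import generate_design, subset, class_vector
from seafusion.simulate import SyntheticSpec, generate_multiomics
from seafusion.preprocess import pair_center, fuse
from seafusion.selection import be_plsda, BEConfig, coefficient_report

design = subset(generate_design(6, sites=("muscle",)), time="t3h",
                site="muscle")
blocks, truth = generate_multiomics(design, SyntheticSpec(seed=1))
centered = {name: pair_center(b, design) for name, b in blocks.items()}
fused = fuse(centered, design)
model = be_plsda(fused, class_vector(design),
                 BEConfig(max_lv=5, drop_fraction=0.1, drop_floor=50))
print(f"selected {len(model.selected_features)} of "
      f"{fused.data.shape[1]} features")
print(f"per block: {model.selected_counts().to_dict()}")
print(f"n_lv={model.model.n_lv}  Acc%Cal={model.accuracy_cal:.0f}  "
      f"Acc%cv={model.accuracy_cv:.0f}")
print(coefficient_report(model).head(5).round(3).to_string())
```

prints

```
selected 20 of 1451 features
per block: {'lipidomics': 6, 'metabolomics': 8, 'proteomics': 6}
n_lv=1  Acc%Cal=100  Acc%cv=100
               block  coefficient    VIP direction
feature
lip_0421  lipidomics        0.054  1.007  decrease
lip_0758  lipidomics        0.054  1.006  decrease
lip_0248  lipidomics       -0.054  1.004  increase
lip_0688  lipidomics       -0.054  0.992  increase
lip_0149  lipidomics        0.053  0.982  decrease
```

The model keeps one latent variable and classifies every sample
correctly in calibration and in paired cross-validation; the selected
panel spans all three platforms. The `direction` column reads the signed
regression coefficient through the class coding: an "increase" feature
is more abundant after treatment. (Of the 20 selected features here, 19
are truly planted — with 12 samples some chance correlation is
unavoidable; see `docs/methods.md`.)

The same workflow runs from the shell:

```sh
seafusion simulate --out sim --seed 1
seafusion beplsda --design sim/design.tsv \
    --blocks sim/muscle_lipidomics.tsv sim/muscle_metabolomics.tsv \
             sim/muscle_proteomics.tsv \
    --time t3h --site muscle --out model
seafusion microbiome --otu sim/otu_table.tsv --design sim/design.tsv \
    --perms 999 --seed 1 --out micro
seafusion run-all --seed 1 --out full_run
```

## Layout

| module | contents |
| --- | --- |
| `seafusion.design` | paired design tables, day-pairs, class coding |
| `seafusion.simulate` | synthetic omics blocks and OTU tables with planted truth |
| `seafusion.preprocess` | pair centering, autoscaling, low-level fusion |
| `seafusion.mfa` | PCA, block weighting, qualitative coding, MFA |
| `seafusion.plsda` | NIPALS PLS-DA, VIP, venetian-blind paired CV |
| `seafusion.selection` | backward elimination, coefficient reports |
| `seafusion.microbiome` | diversity, ordination, PERMANOVA, TMM, NB-Wald DAA |
| `seafusion.pipeline` / `seafusion.cli` | one-config orchestration and subcommands |

See `docs/methods.md` for the statistical model, parameter defaults,
numerical conventions, and known limitations.
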