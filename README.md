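# cellsift

Cell-type-specific gene classification from in situ hybridization (ISH)
expression-pattern images, via dense SIFT bag-of-visual-words features,
regularized logistic classification and stability-selection feature ranking.

## The problem

Genes expressed preferentially in one brain cell type — neurons, astrocytes
or oligodendrocytes — leave characteristic spatial signatures in
cellular-resolution ISH images. Given per-gene expression images (with
binary expression masks marking foreground stain) and a table of
fold-enrichment values derived from cell-sorting experiments, `cellsift`
classifies genes by cell-type enrichment directly from image texture and
ranks the image features (and their locations) that drive the distinction.
It is aimed at computational neuroanatomists and bioimage analysts working
with atlas-style expression image collections.

## The method

1. **Dense SIFT on foreground.** Each image is expanded into a 4-level
   factor-2 Gaussian pyramid. At every level, 128-dimensional SIFT
   descriptors (4×4 spatial cells × 8 orientation bins of gradient
   magnitude) are computed on a dense grid of overlapping 16-px patches;
   only descriptors whose patch center lies in the expression mask are kept.
   Descriptors are ℓ2-normalized, clamped at 0.2 and renormalized;
   gradient-free patches are flagged as *zero descriptors*.
2. **Bag of visual words.** Non-zero descriptors from the two classes of a
   task are sampled into a class-balanced pool (target size 100,000) and one
   k-means codebook of m = 500 words is fit per resolution level (3
   restarts, best squared-Euclidean objective kept). An image becomes the
   histogram x counting descriptors nearest each word,

       x_k = Σ_i δ(k, argmin_j ‖v_i − c_j‖),

   plus one zero-descriptor bin per level, giving p = (500+1)×4 = 2004
   dimensions per section. Coronal and sagittal representations can be
   concatenated (with m = 250 per level).
3. **Classification.** Regularized logistic regression

       min_{w,b} Σ_i log(1 + exp(−y_i (wᵀx_i + b))) + λ Ω(w),

   with Ω = ‖w‖₂² for prediction and Ω = ‖w‖₁ for feature selection.
   Performance is the area under the ROC curve (AUC) over 30 random 2/3–1/3
   train/test partitions, with λ chosen by cross-validated AUC on each
   training side; paired methods are compared with a two-sided Wilcoxon
   signed-rank test.
4. **Feature ranking and traceback.** Stability selection: ⌊n/2⌋-size
   subsamples are drawn without replacement, ℓ1 paths are fit along a λ
   grid, and each feature is scored by its maximum selection frequency
   across λ. Top words are traced to the closest pool descriptor and back to
   the source image, gene and patch location, rendered as an overlay with
   the 4×4 cell grid and per-bin orientation arrows.

A synthetic-data generator renders ISH-like images (elliptical foreground
masks, isotropic base texture, class-specific oriented stripe textures
planted in known quadrants, enrichment tables with controllable folds) so
the whole pipeline is testable end to end without external downloads.

## Worked example

```
cellsift run-all --config examples/demo.toml
```

synthesizes the default study conditions (5 genes per enriched class, 10
negatives, two section types, 128-px noise-free images), runs two tasks with
coronal-only and combined coronal+sagittal features under the 30-repetition
protocol, then ranks the neuron-vs-oligodendrocyte features and traces the
top words. It prints:

```
N-vs-Neg@1.5 [coronal]: median AUC 1.0000
N-vs-Neg@1.5 [combined]: median AUC 1.0000
N-vs-O@1.5 [coronal]: median AUC 1.0000
N-vs-O@1.5 [combined]: median AUC 1.0000
report: demo_out/report.json
```

The planted stripe textures make the classes cleanly separable, so every
repetition reaches AUC 1.0. In `report.json` the ranking block lists the
positively-scored visual words; under this seed the two top-scoring words
(selection probabilities 1.00 and 0.95) trace to patches at (96, 48) in an
oligodendrocyte-gene image and (40, 84) in a neuron-gene image — inside the
bottom-left and top-right quadrants where those classes' discriminative
textures were planted.

Each stage is also available separately (`synth`, `extract`, `codebook`,
`featurize`, `train-eval`, `rank`, `traceback`); run `cellsift --help`.
The classifier accepts any numeric feature table with a `gene_id` column and
`f0..f{p-1}` columns, so external features (e.g. voxel expression energies)
can be evaluated under the identical protocol by swapping the input CSV of
`train-eval`.

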