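# Methods

## Problem and model

`adattn` implements a multi-label diagnostic model for Alzheimer's disease
(AD) that predicts, from routine tabular clinical data, three subtype
severities in [0, 1] — Logopenic Variant (lv), Posterior Cortical Atrophy
(pca) and Frontal Variant (fv) — rather than a single binary diagnosis.
Overall disease severity is the arithmetic mean of the three, binned into
four ordinal levels by upper-edge thresholds 0.25 / 0.5 / 0.75 / 1.0
(asymptomatic, mild, moderate, severe); a subtype is called present when its
severity is ≥ τ = 0.5 (boundary inclusive).

The 81-variable clinical panel is routed through four group modules — blood
chemistry/hematology (G1, 16 features), biochemical markers (G2, 34),
endocrine/immunological markers (G3, 17), lifestyle and demographics
(G4, 12) — while β2-microglobulin and MMSE bypass the groups and feed the
trunk directly (DIRECT). Each group module embeds its scalar features as
tokens (token_i = w_i·v_i + b_i, w_i, b_i ∈ ℝ^d learned per feature, d = 8
by default) and applies scaled dot-product self-attention

    Attention(X) = softmax(X Xᵀ / √d_k) X ,   d_k = d,

with a numerically stabilized row-softmax (row-max subtraction). The n
context rows are convex combinations of the tokens; mean-pooling them gives
one d-vector per group. The four pooled vectors concatenate with the DIRECT
values (trunk input 4d + 2 = 34) and pass through a fully connected trunk
(default widths 64, 32, ReLU) to three per-output logistic units.

Design choices where the design was genuinely open:

* **Tokenization.** A literal 1 × n input vector makes X Xᵀ a scalar and the
  softmax degenerate (identity attention). Treating each feature as a token
  through a learned scalar-to-d embedding lets attention operate *across* a
  group's features and up-weight the informative ones; d = 8 is the default
  and configurable.
* **Score scaling.** √d_k scaling is the default (the variance-stabilizing
  convention); a `score_scale="linear"` mode (divide by d_k) is kept as a
  switch since either reading of "scaling factor" is defensible.
* **Output activation.** A sum-to-one softmax head contradicts three
  *independent* severities whose average is the overall severity, so the
  default head is three independent logistic units; a `softmax` mode is
  retained for ablation.
* **Pooling.** Mean over context rows: size-independent and preserves
  convexity. Attention weights are exportable per patient/group for
  interpretability (`adattn predict --dump-attention`).

## Baseline

The comparison model is a plain fully connected network over the full
concatenated normalized feature vector, same depth class (input → hidden
layers → 3 outputs). Its hidden widths are solved by integer search (widths
scaled proportionally) so its trainable-parameter count lands within ±10% of
the proposed model's (default panel: 5683 proposed vs 5723 baseline).

## Preprocessing

Fixed, leakage-safe order: **impute → normalize → split-fit → SMOTE (train
only)**. Statistics are fit on the training split only and applied to
val/test; SMOTE is unreachable for val/test through the pipeline API.

* **Mean imputation.** Missing cells get the feature's training mean;
  justified by the missing-completely-at-random assumption. An all-missing
  feature is a fit-time error.
* **Min-max normalization.** x ↦ (x − low)/(high − low) clipped to [0, 1],
  using the feature's clinical reference range when the schema provides one
  (β2-microglobulin 1–3 mg/L: 1 ↦ 0, 3 ↦ 1), else the observed training
  min/max. Clipping keeps out-of-range values inside the model's stated
  input domain.
* **Split.** 70/15/15 train/val/test by seeded permutation;
  largest-remainder rounding with ties to the earlier split in (train, val,
  test) order, so 430 patients → (301, 65, 64).
* **SMOTE.** Stratum key = the triple of binarized subtype presences at 0.5
  (the natural multi-label analogue of a class). Each synthetic row is
  x + u·(z − x), u ~ U(0, 1), z one of x's k = 5 (capped at stratum size −
  1) nearest same-stratum neighbors; counts equalize to the majority
  stratum; originals are preserved verbatim; the *same* u interpolates the
  two parents' label vectors, keeping labels consistent with interpolated
  features. SMOTE is applied after normalization so neighbor distances are
  scale-free.

## Training

Binary cross-entropy against the continuous severity targets (Bernoulli-mean
regression; per-sample sum over the three outputs, mean over samples), Adam
(lr 1e-3, β₁ 0.9, β₂ 0.999), batch 32, early stopping on validation loss
with patience 20 and best-epoch weight restoration. Gradients are exact
reverse-mode derivations through the attention blocks (verified against
finite differences in the test suite). Everything is seeded: parameter
init, batch shuffling, SMOTE draws — the full pipeline is bit-reproducible
on fixed hardware.

## Synthetic cohorts

The clinical cohort the model was designed around (430 memory-clinic
patients) is private, so the generator produces cohorts with the structure
the model assumes, latent-first (severities cause features):

1. **Latents.** Each patient draws a true overall-severity level from a
   four-level mixture (uniform by default), then three subtype severities
   uniformly on [0, 1]³ by rejection until their mean lands in that level's
   bin.
2. **Group-structured features.** Within each group a seeded subset
   (`informative_fraction`, default 0.5) follows
   logistic(β·(a_g·s) + ε), ε ~ N(0, noise_sd), mapped linearly into the
   feature's clinical reference range (binary features become Bernoulli in
   that probability; ordinals round). The fixed loadings a_g concentrate
   each subtype's signal in a different group — lv → biochemical, pca →
   endocrine, fv → lifestyle — with a shared signal in the blood group, so
   the grouped-attention design is the matching inductive bias.
3. **DIRECT markers.** β2-microglobulin increases and MMSE decreases
   monotonically in overall severity, with slope scaled by β/5 so β = 0
   renders *every* feature independent of the latents (a clean null).
4. **Demographics.** Age ~ N(77.22, 8.87²), 50% female, 59.07% married,
   BMI ~ N(24.83, 7.16²), 21.16% smoking, 11.16% drinking, 59.98% diabetes,
   11.40% hypertension — the study cohort's descriptive marginals. Disease
   duration is log-normal targeting the reported 5.5-year median only (the
   printed quartiles are internally inconsistent with that median and are
   not imitated). These pinned features never carry subtype signal; the
   lifestyle-group signal lives in education, coronary heart disease and
   the activities-of-daily-living score.
5. **Missingness.** Cell-wise MCAR at `missing_rate` (default 0.02 —
   "minimal and random").

Defaults: n = 430, β = 5, informative_fraction = 0.5, noise_sd = 0.1,
uniform level mixture. What the generator does **not** emulate: real
inter-marker biochemistry correlations beyond the declared latent structure,
measurement batch effects, informative missingness, or longitudinal change —
so passing benchmarks here shows the method works *when its assumptions
hold*, not that it attains any particular accuracy on real patients.

## Evaluation conventions

Per-subtype metrics are standard 2×2 confusion-matrix quantities at τ = 0.5.
Per-level severity accuracy is class-conditional (among patients whose true
level is L, the fraction predicted L); every "overall" figure is the
unweighted mean of its per-class values — the convention under which the
published tables' overall cells follow from their row cells. Percentages
print to one decimal, rounding half away from zero. F1 at
precision = recall = 0 is reported as 0 with a warning.

## Benchmark experiments and problem sizes

* **Recovery.** n = 2000, β = 5, noise_sd = 0.1: the trained proposed model
  must reach mean per-subtype accuracy ≥ 0.90 and overall severity accuracy
  ≥ 0.80 on the held-out test split. (Typical run: ≈ 0.97 / ≈ 0.91.)
* **Comparison.** Ten seeded replicates at the study's cohort size
  (n = 430) with strong group-sparse signal (β = 5,
  informative_fraction = 0.25, noise_sd = 0.3): the proposed model's mean
  subtype accuracy must exceed the parameter-matched baseline's (paired
  one-sided t-test, α = 0.05). Typical means ≈ 0.89 vs ≈ 0.82.
* **Determinism.** The full generate → preprocess → train → evaluate
  pipeline, repeated under one seed, reproduces predictions bit-identically.

These sizes keep the whole suite and the acceptance script to a few minutes
on one CPU while leaving the statistical checks well-powered.

## Known limitations

* The per-feature scalar embedding is the simplest faithful tokenization; it
  cannot model interactions *between* groups before the trunk.
* Mean imputation understates uncertainty and is only defensible under MCAR.
* SMOTE on a continuous multi-label target needs a discretized stratum key;
  the presence-triple choice is a convention, not the only one.
* Real-data accuracies cannot be reproduced or audited here: the original
  cohort is private, and the synthetic benchmark is deliberately favorable
  to *any* well-specified learner of its structure.
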