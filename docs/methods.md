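# Methods

`pndeeg` implements an analysis chain for perioperative-neurocognitive-
disorder (PND) research in anesthetized mice: behavioral phenotyping of a
surgical cohort, quantification of anesthesia/emergence EEG, and supervised
prediction of the behavioral phenotype from emergence-EEG features. This
note documents the models, the numerical conventions, and the design
decisions taken where the problem left the design open.

## Behavioral phenotyping

Each animal is described by 16 behavioral fractions — Barnes-maze
acquisition measures (escape latencies on training days 1–4, the day-1→2
latency change, the session of first successful entry, total successful
entries), probe measures (target-quadrant time, target-hole latency, target
visits), contextual-fear measures (freezing time, freezing bouts,
high-active time, movement time) and open-field measures (distance, center
time). Fractions are standardized column-wise to cohort mean 0 and SD 1.
Conventions are pinned for reproducibility: column scaling uses the
population (1/n) SD; all covariance estimates downstream use the sample
(1/(n−1)) convention. Both are configurable.

**PCA.** The standardized matrix is centered and eigendecomposed
(`C = XᵀX/(n−1)`); scores are `Y = (X − mean)·V_k`. Sign indeterminacy is
resolved by making each component's largest-magnitude entry positive.

**Group separation.** Each group's PCA coordinates are summarized as a
Gaussian (sample mean μ, sample covariance Σ) and pairwise separation is the
squared 2-Wasserstein-type distance

    W² = ‖μ₁ − μ₂‖² + ‖Σ₁^{1/2} − Σ₂^{1/2}‖_F²,

with matrix square roots from eigendecompositions (eigenvalues in
(−10⁻¹⁰, 0) clipped to zero; anything more negative is rejected). The
covariance term equals the Bures metric exactly when the covariances
commute. A `covariance_term="plain"` switch computes ‖Σ₁ − Σ₂‖_F² instead
for comparison. The squared form is returned, no outer square root. WD is
computed in 2-D PCA space by default; any k is supported.

**Constrained K-means.** The surgical animals' standardized fractions are
partitioned into K = 2 clusters with a must-link constraint on the
young-surgery reference group: centroid 1 is initialized to the reference
mean, centroid 2 to a uniformly drawn unconstrained row (seeded), and Lloyd
iterations assign the reference block *jointly* to the cluster minimizing
its summed squared distance at every step, so the constraint holds at
convergence, not just at initialization (`constraint="init-only"` reproduces
the weaker variant). The cluster containing the reference is labelled
non-PND. Convergence is unchanged assignments or 300 iterations; an emptied
cluster is re-seeded from the farthest unconstrained point and logged, never
repaired silently. Clustering runs in the full 16-D fraction space by
default; a PCA-k space option exists because both readings of the original
design are defensible. With a single seeded initialization, bad draws of the
second centroid can converge to a poor local optimum; `stability_across_seeds`
reports the pairwise ARI across seeds precisely to expose this fragility.

## EEG quantification

Signals are single-channel, 1000 Hz, in μV, annotated with half-open phase
intervals (baseline / maintenance / emergence). All operations are
deterministic.

- **Filtering:** 4th-order Butterworth band-pass 1–48 Hz, applied
  forward–backward (zero-phase) by default so feature extraction adds no
  phase distortion; `mode="single-pass"` is the causal alternative.
- **Burst suppression ratio:** maximal runs with |x| ≤ 5 μV lasting ≥ 0.5 s
  count as suppression; BSR = 100 × suppressed/total samples. Runs crossing
  an analysis boundary are truncated there, which makes BSR additive across
  concatenation up to one minimum-duration run. Plain absolute amplitude on
  the filtered signal is used (no envelope).
- **Spectral edge frequency:** STFT with 1 s Hamming windows, 75% overlap;
  per slice, the first frequency at which cumulative power reaches 95% of
  the slice total. All-zero slices yield NaN (undefined), never 0.
- **Welch PSD:** 2 s Hann windows, 50% overlap, density scaling (μV²/Hz) on
  a 0.5 Hz grid; integrating the PSD approximates the signal variance.
- **Band powers:** δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–48 Hz — conventional
  rodent bands tiling the filtered support, fully configurable. Powers are
  accumulated on half-open intervals so ratios sum to exactly 1.
- **Emergence binning:** the emergence interval (anesthetic cessation to
  righting reflex) is normalized to a 0–100% arousal axis and split into 10
  equal bins; one fixed 15 s segment per bin, centered in the bin by default
  (options: first/last) — centering is the least biased placement when the
  within-bin position is unspecified. Heatmap export uses 10·log₁₀(P/P_ref)
  clipped to −20…+20 dB with an explicit reference power (default 1 μV²/Hz)
  and no per-animal normalization.

## The 33-feature emergence descriptor

Emergence EEG is cut into non-overlapping 2 s epochs (trailing remainder
discarded, logged); 33 features are computed per epoch and arithmetically
averaged per animal. The frozen catalog: arithmetic mean, median, SD,
variance, skewness, kurtosis, min, max, range, RMS, mean energy, curve
length, mean Teager energy, zero-crossing rate, mean absolute first/second
difference and their SD-normalized forms, Hjorth activity/mobility/
complexity, log energy entropy (Σ log(x²+ε), ε = 10⁻¹²), Shannon entropy of
a 16-bin amplitude histogram, spectral entropy of the normalized Welch
spectrum, log root sum of sequential variation (log(√Σ(Δx)² + ε)), absolute
band power in the five bands, and relative α/β/δ power. The six headline
features (arithmetic mean, log energy entropy, log RSSV, Hjorth complexity,
α- and β-band power) are individually tested. Undefined per-epoch values
(e.g. Hjorth complexity of a flat epoch) propagate as missing and are
excluded from that feature's average with a logged count. The arithmetic
mean is the raw-signal mean, which on band-passed signals is near zero by
construction. Per-bin trajectories of any feature subset are computed on the
10 emergence segments, each segmented into 2 s epochs internally.

## Classifier benchmark

The cohort for prediction is the 38 surgical animals: the non-PND class
pools the 8 young-surgery reference animals with the aged non-PND animals;
the PND class is the aged PND animals. Twelve families are benchmarked:
logistic regression, gradient boosting (histogram-based), decision tree,
random forest, AdaBoost, extra trees, SVM, Gaussian naive Bayes, KNN, MLP,
XGBoost and LightGBM, each with a small documented hyperparameter grid
(regularization over decades, tree depth {2,3,4}, hidden layers
{(16,),(32,),(16,8)}; all overridable).

Evaluation is a factorial over train:test ratios (6:4, 7:3, 8:2) and split
seeds (42, 300, 600, 800). Splits are stratified hold-outs (the only
defensible default at n = 38; an unstratified option exists). Inside each
training set, hyperparameters are selected by stratified 3-fold grid search
on mean fold AUC — AUC being the primary discrimination metric — with the
StandardScaler inside the pipeline so scaling statistics never touch
validation or test rows; the winner is refit on the full training set and
evaluated once on the untouched test set. Accuracy, precision, recall and F1
come from the confusion matrix with division-by-zero reported as missing
(never silently 0); AUC is trapezoidal integration of the threshold-swept
ROC, with tied scores crossing simultaneously (equivalent to the
Mann–Whitney ties-count-half convention).

**Attribution.** Global feature importance is mean |Shapley value| from a
permutation-sampling Shapley estimator: per sampled feature ordering a
background row is drawn from the training set and features are switched to
the explained value one at a time, crediting each with the output change.
The telescoping sum makes attributions exactly additive per sample.
Per-sample values are retained for swarm-style export. The top-k curve
re-runs the full CV selection on the k best-ranked features (k = 1…10) and
reports the smallest k within 0.01 AUC of the k ≤ 10 maximum ("plateau").

## Synthetic cohort generator

No public dataset accompanies this design, so the generator is a
first-class, tested component that plants known ground truth.

**Behavior.** Groups young-sham/aged-sham/young-surgery/aged-surgery of
8/8/8/30 animals; fractions are drawn directly in standardized units as
Gaussian noise with within-assay-block equicorrelation ρ = 0.15 (shared
latent factor per assay block — latencies from the same maze correlate).
Two-thirds of aged-surgery animals (20 of 30, positions randomized per seed)
are planted vulnerable with a +1.75 SD shift on the 8 learning/memory
fractions (sign reflecting impairment: longer latencies, fewer entries, less
freezing); the preserved component shares the young-surgery mean. The 1.75 SD
magnitude matches the large acquisition-phase contrasts reported between
vulnerable and preserved aged mice (Cohen's d ≈ 1.5–2) and keeps the
single-initialization clustering reliably above ARI 0.8 against truth;
exactly 1.5 SD sits on a knife edge where the typical run misassigns two of
38 animals.

**EEG.** Signals are sums of unit-variance band-limited Gaussian noise
mixed with √weight so each band's power share tracks its weight, scaled to
a target RMS (20 μV awake). Maintenance is δ-dominant (weight 0.70) with
evenly spaced ~3 s suppression episodes of 0.5 μV RMS totalling 30% of the
phase — recoverable by the BSR criterion by construction (suppression well
inside ±5 μV, bursts well outside). Emergence ramps the weights linearly
(sigmoid optional) from maintenance-like to an awake-like endpoint over
180 s (preserved) or 300 s (vulnerable — prolonged emergence); the
vulnerable endpoint retains more δ (0.28 vs 0.15), recovers less α/β (0.18
vs 0.25, with a quadratic ramp lag), and runs at slightly higher amplitude
(22 vs 20 μV, higher-amplitude slow waves), so log energy entropy runs
higher in the PND-like group. Each animal carries multiplicative trait
jitter (band weights log-SD 0.35, RMS log-SD 0.15) so that phenotype
distributions overlap on any single averaged feature while remaining
separable multivariately — without it, single features separate almost
perfectly, which real cohorts do not show.

**What the generator does not emulate:** biophysical EEG generation (no
neural mass dynamics, no 1/f background, no artifacts or electrode noise),
pharmacokinetics of anesthetic washout, non-Gaussian behavioral
distributions, or any coupling between an animal's behavioral severity and
its EEG beyond the binary phenotype. Passing tests therefore demonstrate
that the pipeline recovers structure of this planted form, not that it
would perform identically on measured data.

## Problem sizes and numerical choices

Recovery properties are evaluated at the cohort's own scale: 38 surgical
animals, 300 s maintenance for BSR recovery (±2 percentage points), medians
over 20 generator seeds for clustering ARI (≥ 0.8) and classifier AUC
(≥ 0.8, best of the LR/RF families at the 8:2 split). Oracle equivalences
run exhaustively where enumeration is feasible: all must-link-respecting
2-partitions at n = 10, all score pairs at n ≤ 30. Log guards use ε = 10⁻¹²;
PSD quantities use 64-bit floats throughout; K-means convergence is exact
assignment equality.

## Known limitations

- The single-initialization constrained K-means is sensitive to the random
  second centroid; the stability report quantifies but does not remove this.
- The 33-feature catalog reconstructs a conventional handcrafted-descriptor
  set; the six headline features are guaranteed and individually tested, but
  alternative catalogs are possible and the catalog is configurable.
- Monte-Carlo Shapley estimates carry sampling error O(1/√n_permutations);
  rankings of near-tied features can swap between seeds.
- EDF files can be read (via MNE) but not written; the native signal format
  is NPZ plus a JSON sidecar.
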