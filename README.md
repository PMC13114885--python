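# pndeeg

Emergence-EEG phenotyping and prediction of perioperative neurocognitive
vulnerability in anesthetized mice.

Postoperative neurocognitive disorders (PND) hit aged surgical patients
hardest, but vulnerability varies widely between individuals and is hard to
anticipate. In the preclinical setting this package addresses, young and
aged mice undergo laparotomy under isoflurane with EEG recorded through
baseline, maintenance and emergence; cognition is afterwards quantified by
16 standardized behavioral fractions (Barnes maze, contextual fear
conditioning, open field). `pndeeg` provides the full analysis chain for
researchers working with such cohorts:

- **Phenotyping** — reference-anchored semi-supervised K-means. With
  must-link constraints pinning the young-surgery group together (their
  mean seeding one centroid, μ₁ = (1/m)ΣX_f), two-cluster Lloyd iterations
  minimize the within-cluster sum of squares J = Σᵢ Σ_{x∈Cᵢ} ‖x − μᵢ‖² and
  split the aged-surgery animals into a preserved (non-PND-like) and a
  vulnerable (PND-like) subgroup, with ARI-across-seeds stability
  diagnostics.
- **Behavioral geometry** — PCA embedding of the standardized fractions and
  closed-form Gaussian 2-Wasserstein group separation,
  W² = ‖μ₁−μ₂‖² + ‖Σ₁^{1/2}−Σ₂^{1/2}‖²_F.
- **EEG quantification** — zero-phase 1–48 Hz Butterworth filtering, burst
  suppression ratio (|x| ≤ 5 μV for ≥ 0.5 s), spectral edge frequency
  (SEF95, 1 s Hamming STFT), Welch band powers/ratios (δ/θ/α/β/γ), and a
  normalized 10-bin emergence trajectory with fixed 15 s segments.
- **Prediction** — a leakage-safe benchmark of 12 classifier families on a
  33-feature emergence descriptor (2 s epochs, averaged per animal), with
  stratified hold-outs × CV grid search, ROC/AUC, permutation-Shapley
  feature ranking and top-k feature curves.
- **Synthetic cohorts** — a seeded generator planting known phenotype truth
  in both behavior and EEG, so the whole chain is testable without animal
  data.

## Worked example

```python
import numpy as np
from pndeeg import (SyntheticConfig, gen_behavioral_table,
                    group_separation, PhenotypePartition)

cfg = SyntheticConfig(seed=7)                  # 8/8/8/30 cohort, 20:10 mixture
table = gen_behavioral_table(cfg)              # 54 x 16 standardized fractions

wd = group_separation(table, "young-surgery", "aged-surgery", k=2)
print(f"WD(young-surgery, aged-surgery) = {wd:.2f}")

res = PhenotypePartition.from_behavioral(table).fit(seed=0)
print(res.summary())
```

prints

```
WD(young-surgery, aged-surgery) = 15.43
Constrained K-means phenotype partition
===========================================
samples:            38
feature space:      raw-16d
constraint:         always
seed:               0
iterations:         3
final WCSS:         502.2424
non-PND cluster:    18
PND cluster:        20
must-link size:     8
```

The Wasserstein distance quantifies how far the aged-surgery group's
behavioral distribution sits from the young-surgery reference in PCA space
(here large, because the generator plants a 1.75 SD deficit on 8 fractions
in two-thirds of the aged animals). The partition recovers the planted
20:10 vulnerable:preserved mixture exactly (ARI 1.00 against truth for this
seed); the 18-animal non-PND cluster is the 8 reference animals plus the 10
preserved aged animals — precisely the class definition used downstream by
the classifier benchmark.

From the shell, the same chain runs end to end:

```bash
pndeeg run --config examples/config.yaml --out-dir runs/demo
```

producing behavior/phenotype/feature tables, per-model reports and a
manifest with SHA-256 digests of every output.

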