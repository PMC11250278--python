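# earcount

Wheat-ear counting from RGB field images by hybrid local/global density
estimation.

Counting ears (heads) per image is a core wheat-phenotyping measurement, and
field imagery makes it hard: ears are small, elongated, densely packed,
mutually occluding, and sit on cluttered backgrounds under variable
illumination. `earcount` takes the density-estimation route: each annotated
ear centre \(p_i\) contributes a unit-mass Gaussian bump, giving a
ground-truth density map

```
F(x) = Σ_{i=1..N} δ(x − p_i) ∗ G_σ(x),    ∫ F = N,
```

and a network regresses \(F\) from the image; the predicted count is the
integral of the predicted density map. The network is a hybrid of local and
global feature extractors:

* a four-stage **cross-stage-partial (CSP)** convolutional backbone
  (stride-2 entries; channels 64/256/512/512 → a stride-2/4/8/16 pyramid);
* a **pyramid-pooling transformer** stage on the stride-16 grid — 1×1 patch
  embedding, then multi-head self-attention whose keys/values are
  adaptively pooled token pyramids (1², 2², 3², 6² bins), adding global
  context at constant resolution;
* top-down **attentional feature fusion (AFF)** — a learned per-channel
  convex combination `M ⊙ a + (1−M) ⊙ b` of the upsampled global stream and
  each finer local stream;
* a decoder of parallel dilated 3×3 convolutions projected to two heads:
  a non-negative density map and a sigmoid attention-probability map.

Training minimises `L = L_den + L_c + α·L_att` with `α = 0.1`: pixel-wise
Euclidean density loss, an SSIM local-consistency loss `L_c = 1 − SSIM`,
and binary cross-entropy against a thresholded-smoothed-density attention
mask (`th = 0.001`). Optimisation is Adam (initial learning rate 1e-4;
the desk-scale preset uses 1e-3). Evaluation reports MAE, RMSE and MAPE
over per-image counts.

The whole stack — including a minimal reverse-mode autograd engine — is
pure NumPy/SciPy, so the full train/predict/evaluate loop runs on one CPU.
A seeded synthetic field generator provides images with exact point ground
truth, so nothing needs downloading.

## Worked example

```python
import numpy as np
from earcount import (PRESETS, generate_split, smoke_config, train)
from earcount.training import constant_mean_baseline, evaluate_on_split

spec = PRESETS["tiny"]                      # 64x64 fields, 5-20 ears each
train_anns = generate_split(spec, 40, "scratch/train", seed=101)
generate_split(spec, 12, "scratch/test", seed=202)

model, log = train(smoke_config(seed=0), "scratch/train")
print(log.groupby("epoch")["total"].mean().round(3).tolist())
report, records = evaluate_on_split(model, "scratch/test")
base = constant_mean_baseline([len(a) for a in train_anns], records)
print(f"MAE {report.mae:.2f}  vs constant-mean baseline {base:.2f}")
```

Output (single CPU, ~80 s):

```
[0.165, 0.113, 0.096, 0.085, 0.073]
MAE 2.11  vs constant-mean baseline 4.98
```

The per-epoch mean of the combined loss falls monotonically, and after five
epochs the reduced model counts held-out synthetic fields more than twice as
accurately as always predicting the training-split mean count (predictions
track the true counts, e.g. 17.6 vs 19, 6.1 vs 6).

The same pipeline is available from the shell:

```bash
earcount synth --preset tiny --n 40 --seed 101 --out scratch/train
earcount train scratch/train --out scratch/run
earcount predict scratch/run/checkpoint.npz scratch/train/field_0000.png --out counts.csv
earcount evaluate counts.csv scratch/train/points.csv --width 64 --height 64 --report report.json
```

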