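# glocalmm

Global–local multimodal representation learning for lumbar-spine imaging:
bidirectional image–report contrastive alignment with text-guided region
attention, plus a text-modulated U-Net for anatomical segmentation. The
package targets researchers studying image–text pretraining for
musculoskeletal radiology who want a fully self-contained, CPU-only
testbed: a synthetic phantom generator emulates the structure of a
postoperative lumbar X-ray dataset (vertebral bodies L1–L5, disc spaces,
pedicle-screw/rod instrumentation, degeneration, fusion) with paired
templated reports, pixel masks, image-level labels and patient grouping,
so every experiment regenerates its own data.

## Model

Paired samples `(x_v, x_t)` are encoded into global and local features and
projected into a shared space: unit vectors `v_g, t_g ∈ R^D` and unit
columns `v_l ∈ R^{D×M}` (one per image region), `t_l ∈ R^{D×W}` (one per
report word). Training minimizes

```
L = λ1 (L_g^(v|t) + L_g^(t|v)) + λ2 (L_l^(v|t) + L_l^(t|v)) + λ3 L_seg
```

with λ = 1. The global terms are InfoNCE losses over in-batch pairs with
temperature t1 = 0.07. The local terms score each (image, text) pair by
text-guided attention: relevance map `s = v_lᵀ t_l`, attention
`a_ij = softmax_j(s_ji / t2)`, context vectors `c_i = Σ_j a_ij v_j`, and a
log-sum-exp pooled match score `Z = t3 log Σ_i exp(⟨c_i, t_i⟩ / t3)` that
enters a second bidirectional InfoNCE. The segmentation head is a U-Net
decoder over the visual encoder's pyramid whose stages are modulated by
cross-modal attention (words as queries, spatial positions as keys and
values), trained with soft Dice + cross-entropy.

Everything differentiable runs on a small reverse-mode autodiff engine
over numpy (`glocalmm.nn`), verified by finite differences in the test
suite. See `docs/methods.md` for the architecture of the desk-scale
encoders and all parameter choices.

## Worked example

```python
import numpy as np
from glocalmm.phantom_forge import SamplerParams, generate_dataset, patient_split
from glocalmm.training import (TrainConfig, train_alignment,
                               retrieval_similarity, hit_at_1, _split_samples)

samples = generate_dataset(200, 1, SamplerParams(unique_findings=True), seed=11)
split = patient_split(samples, seed=11)
cfg = TrainConfig.tiny(seed=11, val_every=2)      # batch 16, Adam 1e-4, τ=0.07
model, vocab, hist = train_alignment(samples, split, cfg)

test = _split_samples(samples, split.test)
sim = retrieval_similarity(model, test, vocab, cfg.temps)
print(f"train loss {hist.losses[0]['total']:.2f} -> {hist.losses[-1]['total']:.2f}")
print(f"test image->report hit@1: {hit_at_1(sim):.3f} over {len(test)} candidates")
```

prints (30 epochs, ~90 s on one CPU):

```
train loss 11.02 -> 3.54
test image->report hit@1: 0.825 over 40 candidates
```

The first line shows the summed four-term alignment loss per sample
falling from its chance level (≈ 4·ln 16 ≈ 11.1 for batch 16) as matched
pairs separate from in-batch negatives; the second line says that for 82%
of held-out patients the model ranks the true report first among all 40
test reports. A `glocalmm` command-line tool wraps the same pipeline
(`glocalmm generate`, `train-align`, `train-seg`, `evaluate`).

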