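# sonodescribe

An explainable computer-aided-diagnosis pipeline for breast ultrasound.
Given a grayscale B-mode image, it detects nodule regions of interest,
describes each nodule with the standardized BI-RADS lexicon (shape, margin,
orientation, echogenicity, posterior acoustic feature, echogenic halo, and
the tumor type or "suggestivity"), derives the BI-RADS category 2–5 with an
explainable model, estimates Boolean malignancy, and renders a
natural-language report with the recommended clinical intervention.  A
SIFT-based auditor finds near-duplicate images (zoomed/rotated copies, a
known contamination of public ultrasound datasets) and their label
conflicts before any training.

The package is aimed at researchers building or evaluating descriptor-level
ultrasound CAD: everything is exercised end to end on a built-in synthetic
speckle-phantom generator with known ground truth, so the full pipeline is
trainable and testable with no clinical data.

## The model

The descriptor network encodes a standardized 450×450 ROI (rescaled only if
a side exceeds 450, zero-padded, aspect preserved) into a feature-space
matrix **F** ∈ R^{g²×d} (g = 14, d = 512 by default), batch-normalized.  A
soft-attention layer scores each row with a learned perceptron and pools the
context

&nbsp;&nbsp;&nbsp;&nbsp;**c** = Σᵢ aᵢ **f**ᵢ,&nbsp;&nbsp;
aᵢ = softmax(tanh(**V**·**f**ᵢ)),&nbsp;&nbsp;aᵢ ≥ 0, Σᵢ aᵢ = 1,

whose weights double as a visual attention map.  Six dense heads read the
context, one per descriptor (orientation uses two sigmoid neurons with a
0.3 decision threshold — round nodules are neither parallel nor
anti-parallel); the suggestivity head additionally reads the six descriptor
outputs, and the malignancy head reads descriptors, suggestivity and
context.  The BI-RADS category comes from a multinomial logistic regression
over the seven categorical descriptors only, so each category logit
decomposes exactly into per-feature weight contributions — the explanation
shown to the radiologist.  Two lexicon rules fine-tune the output (round ⇒
no orientation; simple cyst ⇒ 2, complex cyst ⇒ 4A, spiculated ⇒ 5).
Agreement is scored with unweighted Cohen's kappa per descriptor.

The network and its gradients are implemented directly in NumPy with
explicit, numerically checked backward passes; a structurally identical
"tiny" topology (96×96 input, d = 64) trains in minutes on one CPU and is
used throughout the tests.  See `docs/methods.md` for the full account.

## Worked example

```python
from sonodescribe import (make_dataset, tiny_config, train, standardize_roi,
                          predict, BiradsRegression, DescriptorSet,
                          derive_birads, describe, sample_phantom_spec)
from sonodescribe.net import BoundingBox
from sonodescribe.phantom import load_image

manifest = make_dataset(n=60, seed=1, out_dir="data/")
model, history = train(manifest, tiny_config(epochs=12, seed=0, lr=2e-3))

rec = manifest["records"][0]
roi = standardize_roi(load_image(manifest, rec), BoundingBox(*rec["box"]), target=96)
descriptors, p_malignant, attention = predict(model, roi)
print(descriptors.as_dict())
```

prints (from `examples/03_train_descriptor_net.py`, a demonstration-scale
12-epoch run — descriptor accuracy at this scale is partial; the full
600-phantom study in the acceptance script reaches per-descriptor kappa
≥ 0.8):

```
loss: epoch 0 = 10.929, epoch 11 = 6.304
predicted: {'shape': 'round', 'margin': 'indistinct', 'orientation': 'parallel',
            'echogenicity': 'hypoechoic', 'posterior': 'shadowing', 'halo': 'absent',
            'suggestivity': 'no_clear_suggestivity'}
```

The explainable category model and the report generator
(`examples/04_birads_regression.py`, `examples/05_report_generation.py`):

```
predicted category 4C (p=0.69)
  weights toward BI-RADS 4C (+ intercept -0.69):
    posterior=shadowing              +3.99
    shape=irregular                  +3.96
    orientation=anti_parallel        +3.83
    ...
```

```
The nodule presents an irregular shape, spiculated margins, an anti-parallel
orientation, a hypoechoic interior, posterior shadowing, and an echogenic
halo. The finding is suggestive of no clear tumor type. Estimated probability
of malignancy: 93.0%. BI-RADS category 5. Recommended intervention: Biopsy.
```

Each positive weight pushes that category's logit up; the sum of the listed
weights plus the intercept *is* the logit, exactly.  In the report, the rule
module has overridden the regression's 4C with category 5 because the margin
is spiculated.

Every `examples/*.py` script is a runnable narrative of one capability:
simulation, ROI handling, training, explanation, reporting, de-duplication.

A thin CLI wires the stages together:

```bash
sonodescribe simulate --n 600 --seed 1 --out data/
sonodescribe train --manifest data/manifest.json --out model.npz --mlr-out mlr.json
sonodescribe describe --image data/images/img_00000.png --model model.npz \
    --mlr mlr.json --conf-threshold 0.25 --report report.json
sonodescribe dedup --manifest data/manifest.json --out dedup.csv
```

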