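"""Train the tiny attention network on a handful of phantoms (about a
minute on one CPU) and read out its descriptors for one nodule.

This is a demonstration-scale run: 60 training images and 12 epochs show the
loss falling and the multi-head output format; descriptor recovery at the
accuracy the package is tested to needs the full 600-phantom run (see the
acceptance script).
"""

import tempfile

from sonodescribe import make_dataset, predict, standardize_roi, tiny_config, train
from sonodescribe.net import BoundingBox
from sonodescribe.phantom import load_image

with tempfile.TemporaryDirectory() as td:
    manifest = make_dataset(n=60, seed=1, out_dir=td)
    config = tiny_config(epochs=12, seed=0, lr=2e-3)
    model, history = train(manifest, config)
    print(f"loss: epoch 0 = {history[0]['total']:.3f}, "
          f"epoch {len(history)-1} = {history[-1]['total']:.3f}")

    record = manifest["records"][0]
    roi = standardize_roi(load_image(manifest, record),
                          BoundingBox(*record["box"]), target=config.input_size)
    descriptors, p_malignant, attention = predict(model, roi)
    print("predicted:", descriptors.as_dict())
    print("truth:    ", {k: record["spec"][k]
                         for k in descriptors.as_dict()})
    print(f"malignancy probability {p_malignant:.2f}; "
          f"attention map {attention.shape}, mass concentrated where the "
          "network looked")
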