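"""Detect a nodule with the built-in blob detector and standardize its ROI.

The detector thresholds intensity deviation from the background, merges the
nodule with the posterior column it casts, and reports a confidence.  The ROI
is then rescaled only if a side exceeds the target and zero-padded to a
square, preserving the width-height ratio that carries the orientation
descriptor.
"""

from sonodescribe import detect, render_phantom, sample_phantom_spec, standardize_roi

spec = sample_phantom_spec(3)
image, truth = render_phantom(spec)
print(f"phantom: {spec.shape}, {spec.margin}, {spec.echogenicity}, "
      f"posterior {spec.posterior}")
print(f"ground-truth box: ({truth.x0},{truth.y0})-({truth.x1},{truth.y1})")

boxes = detect(image, conf_threshold=0.2)
print(f"detected {len(boxes)} box(es); "
      f"best IoU vs truth = {boxes[0].iou(truth):.2f} "
      f"at confidence {boxes[0].confidence:.2f}")

roi = standardize_roi(image, boxes[0], target=450)
print(f"standardized ROI: {roi.pixels.shape}, scale {roi.scale_factor:.3f}, "
      f"content {roi.content_shape} placed at {roi.pad_offsets}")
x0, y0 = roi.to_image_coords(0, 0)
print(f"inverse mapping of the ROI origin recovers ({x0:.0f},{y0:.0f}) "
      "in the source image")
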