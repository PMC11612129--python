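"""Fit the explainable BI-RADS regression on descriptor tables and read the
per-feature weights behind one prediction.

The regression sees only categorical descriptors, so each category logit is
exactly the sum of the active features' weights plus an intercept — the
explanation below lists those contributions for the two leading categories.
"""

from sonodescribe import BiradsRegression, DescriptorSet, derive_birads, sample_phantom_spec

sets, cats = [], []
for i in range(500):
    spec = sample_phantom_spec(i)
    sets.append(DescriptorSet.from_dict(spec.descriptors()))
    cats.append(derive_birads(spec))

reg = BiradsRegression().fit_sets(sets, cats)
accuracy = sum(reg.predict_explain(d).category == c
               for d, c in zip(sets, cats)) / len(sets)
print(f"training accuracy on {len(sets)} nodules: {accuracy:.3f}")

nodule = DescriptorSet(shape="irregular", margin="microlobulated",
                       orientation="anti_parallel", echogenicity="hypoechoic",
                       posterior="shadowing", halo="present",
                       suggestivity="no_clear_suggestivity")
result = reg.predict_explain(nodule)
print(f"\npredicted category {result.category} "
      f"(p={result.probabilities[result.category]:.2f})")
for category, weights in result.explanation.items():
    print(f"  weights toward BI-RADS {category} "
          f"(+ intercept {result.intercepts[category]:+.2f}):")
    for feature, w in sorted(weights.items(), key=lambda kv: -abs(kv[1])):
        print(f"    {feature:32s} {w:+.2f}")
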