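"""Apply the lexicon rules and render natural-language reports.

Rule 1 removes the orientation of round nodules; rule 2 pins the category of
simple cysts (2), complex cysts (4A) and spiculated nodules (5), with the
malignancy-dominant precedence when they conflict.
"""

from sonodescribe import DescriptorSet, describe

cyst = DescriptorSet(shape="round", margin="circumscribed", orientation="none",
                     echogenicity="anechoic", posterior="enhancement",
                     halo="absent", suggestivity="simple_cyst")
report = describe(cyst, category="3", malignancy_probability=0.02)
print("simple cyst (regression said 3, rule forces 2):")
print(" ", report.narrative, "\n")

spiculated = DescriptorSet(shape="irregular", margin="spiculated",
                           orientation="anti_parallel",
                           echogenicity="hypoechoic", posterior="shadowing",
                           halo="present", suggestivity="no_clear_suggestivity")
report = describe(spiculated, category="4C", malignancy_probability=0.93)
print("spiculated nodule (rule forces 5):")
print(" ", report.narrative, "\n")

print("structured record round-trips losslessly:")
print(report.to_json())
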