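"""Generate a synthetic mid-sagittal study and inspect its ground truth.

The phantom renders a sacrum, alternating discs/vertebrae with tilt and
curvature, per-grade nucleus intensity, and acquisition noise.  Its
truth table is the reference every later stage is checked against.
"""

from spineannot import PhantomConfig, generate, validate

study = generate(PhantomConfig(seed=1, grades=(1, 3, 5), bump=True))

print("label map valid:", validate(study.labels).ok)
print(study.truth.to_string(index=False))
# height_mm is the rendered perpendicular height of each disc; the
# grade-5 disc is collapsed below the 3.0 mm clinical threshold.
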