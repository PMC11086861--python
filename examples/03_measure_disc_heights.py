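"""Measure disc heights geometrically and compare with rendered truth.

For each disc the middle 30% of its superior/inferior boundaries are
fitted with orthogonal-regression lines, a bisecting segment is built
from perpendicular projections, and each endpoint slides to the
strongest directed Prewitt gradient.  Height = endpoint distance x
pixel spacing / 4 (the upscale factor).
"""

from spineannot import PhantomConfig, PipelineConfig, annotate_study, generate

study = generate(PhantomConfig(seed=3, grades=(1, 3, 5), noise_sd=0.0))
records = annotate_study(study.image, study.labels, PipelineConfig(all_discs=True))

truth = dict(zip(study.truth.ivd_name, study.truth.height_mm))
print(f"{'disc':8s} {'measured':>9s} {'truth':>7s} {'error':>7s}")
for rec in records:
    err = rec.height_mm - truth[rec.ivd_name]
    print(f"{rec.ivd_name:8s} {rec.height_mm:7.2f}mm {truth[rec.ivd_name]:5.2f}mm {err:+6.2f}mm")
# On noise-free phantoms every disc recovers within +/-0.5 mm; the
# collapsed disc's measured height (< 3.0 mm) triggers grade 5.
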