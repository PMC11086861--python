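"""End-to-end orchestration: annotate studies, train, and evaluate.

A study is an aligned (MRI image, six-region label map) pair.
Annotation runs: resample to the working frame -> post-process the
label map -> extract and order the spine centerline -> name discs and
vertebrae -> measure each focus disc's height -> brightness-normalize,
detect the nucleus, extract its SSCC feature -> predict the Pfirrmann
grade (height rule first, classifier otherwise).

The training protocol mirrors the clinical setup: classifier features
and heights are computed from ground-truth label maps, while prediction
runs on (post-processed) inferred label maps.  With phantom studies the
ground-truth map doubles as the inferred one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import grading, height_measure, nucleus_features, spine_topology
from .errors import SpineAnnotError
from .imaging_io import GreyImage, WORKING_DIM, resample_to_working
from .labelmap import LabelMap, RegionCode, postprocess
from .nucleus_features import QuantizerConfig

log = logging.getLogger(__name__)

DEFAULT_FOCUS = ("L5/S1", "L4/L5", "L3/L4")


@dataclass
class PipelineConfig:
    k: int = height_measure.DEFAULT_K
    gaussian_sigma: float = height_measure.DEFAULT_SIGMA
    n_gl: int = 30
    gl_max: float = 150.0
    w: int = 2
    d: int = 4
    height_threshold_mm: float = grading.DEFAULT_HEIGHT_THRESHOLD_MM
    gl_vert_mean: float = nucleus_features.DEFAULT_VERT_MEAN
    classifier_family: str = "ensemble"
    cv_folds: int = 10
    seed: int = 0
    focus: tuple = DEFAULT_FOCUS
    all_discs: bool = False

    @property
    def quantizer(self) -> QuantizerConfig:
        return QuantizerConfig(n_gl=self.n_gl, gl_max=self.gl_max)

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class AnnotationRecord:
    study_id: str
    ivd_name: str
    height_mm: float
    grade: int | None
    nucleus_fallback: bool
    truncated: bool
    segment_top: tuple  # refined endpoints, upscaled-frame (x, y)
    segment_bottom: tuple
    feature: object = None
    nucleus_mask: object = None
    ivd_mask_up: object = None

    def to_row(self) -> dict:
        return {
            "study_id": self.study_id,
            "ivd_name": self.ivd_name,
            "height_mm": self.height_mm,
            "grade": self.grade,
            "nucleus_fallback": self.nucleus_fallback,
            "truncated": self.truncated,
            "mpt_x": self.segment_top[0],
            "mpt_y": self.segment_top[1],
            "mpb_x": self.segment_bottom[0],
            "mpb_y": self.segment_bottom[1],
        }


def _focus_names(named, config: PipelineConfig):
    if config.all_discs:
        return [s.name for s in named.ivds]
    return [s.name for s in named.ivds if s.name in config.focus]


def annotate_study(image: GreyImage, labels: LabelMap, config: PipelineConfig = PipelineConfig(),
                   model: grading.GradingModel | None = None, study_id: str = "",
                   do_postprocess: bool = True) -> list:
    """Annotate every focus disc of one study.

    Returns one :class:`AnnotationRecord` per focus disc present.  The
    grade is None when no classifier model is supplied and the height
    rule does not fire.
    """
    if image.pixels.shape != labels.codes.shape:
        raise SpineAnnotError(
            f"image/label shape mismatch: {image.pixels.shape} vs {labels.codes.shape}"
        )
    if image.pixels.shape[0] != WORKING_DIM:
        image = GreyImage(resample_to_working(image.pixels), image.meta)
        labels = LabelMap(resample_to_working(labels.codes, is_label=True), labels.meta)
    if do_postprocess:
        labels = postprocess(labels)

    skeleton = spine_topology.extract_skeleton(labels)
    path = spine_topology.order_path(skeleton)
    named = spine_topology.assign_names(path, labels)

    mri_up, labels_up = height_measure.prepare_images(image, labels, sigma=config.gaussian_sigma)
    field_ = height_measure.prewitt_field(mri_up.pixels)
    vert_mask_up = labels_up.mask(RegionCode.VERTEBRAE)
    sacrum_up = labels_up.mask(RegionCode.SACRUM)

    records = []
    for name in _focus_names(named, config):
        disc = named.ivd(name)
        ivd_up = height_measure.upscale_mask(disc.ccr.mask)
        above_up = height_measure.upscale_mask(named.vertebrae[disc.order].ccr.mask)
        below_up = (
            sacrum_up
            if disc.order == 0
            else height_measure.upscale_mask(named.vertebrae[disc.order - 1].ccr.mask)
        )
        result = height_measure.measure_disc_height(
            field_, ivd_up, above_up, below_up, image.meta, k=config.k, ivd_name=name
        )
        feature, nucleus = nucleus_features.extract_ivd_feature(
            mri_up,
            vert_mask_up,
            ivd_up,
            cfg=config.quantizer,
            w=config.w,
            d=config.d,
            reference_mean=config.gl_vert_mean,
        )
        grade = None
        if model is not None:
            grade = grading.predict(model, feature, result.height_mm)
        else:
            grade = grading.apply_height_rule(result.height_mm, config.height_threshold_mm)
        records.append(
            AnnotationRecord(
                study_id=study_id,
                ivd_name=name,
                height_mm=result.height_mm,
                grade=grade,
                nucleus_fallback=nucleus.fallback,
                truncated=disc.truncated,
                segment_top=tuple(result.segment.Mp_T),
                segment_bottom=tuple(result.segment.Mp_B),
                feature=feature,
                nucleus_mask=nucleus,
                ivd_mask_up=ivd_up,
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


@dataclass
class ExperimentResult:
    report: grading.EvalReport
    model: grading.GradingModel
    per_disc: pd.DataFrame
    config_fingerprint: str
    n_skipped: int = 0


def run_experiment(studies, config: PipelineConfig = PipelineConfig(),
                   train_on_truth_labels: bool = True) -> ExperimentResult:
    """Train on ground-truth-label features, predict, and evaluate a batch.

    ``studies`` are phantom studies (or any objects with ``image``,
    ``labels``, ``truth``, ``study_id``).  Grade-5 training samples are
    excluded (the height rule owns them); prediction runs on the
    post-processed label maps.  Corrupted studies are skipped and
    logged.
    """
    cfg_all = replace(config, all_discs=True)
    train_feats, train_grades = [], []
    eval_rows = []
    n_skipped = 0
    for study in studies:
        try:
            train_recs = annotate_study(
                study.image, study.labels, cfg_all, study_id=study.study_id,
                do_postprocess=not train_on_truth_labels,
            )
        except SpineAnnotError as exc:
            log.warning("skipping study %s: %s", study.study_id, exc)
            n_skipped += 1
            continue
        truth = {row.ivd_name: row for row in study.truth.itertuples()}
        for rec in train_recs:
            t = truth.get(rec.ivd_name)
            if t is None:
                continue
            if t.grade != 5:
                train_feats.append(rec.feature)
                train_grades.append(t.grade)
            eval_rows.append((study.study_id, rec, t.grade))

    model = grading.train(
        train_feats,
        train_grades,
        family=config.classifier_family,
        cv_folds=config.cv_folds,
        seed=config.seed,
        height_threshold_mm=config.height_threshold_mm,
    )

    y_true, y_pred, rows = [], [], []
    for study_id, rec, true_grade in eval_rows:
        pred = grading.predict(model, rec.feature, rec.height_mm)
        y_true.append(true_grade)
        y_pred.append(pred)
        row = rec.to_row()
        row["grade"] = pred
        row["true_grade"] = true_grade
        rows.append(row)
    report = grading.evaluate(y_true, y_pred)
    return ExperimentResult(
        report=report,
        model=model,
        per_disc=pd.DataFrame(rows),
        config_fingerprint=config.fingerprint(),
        n_skipped=n_skipped,
    )


def render_overlay(image: GreyImage, records, path, scale: int = height_measure.SCALE) -> None:
    """Minimal annotation overlay: disc, nucleus, and inner-nucleus
    contours plus the bisecting segment, drawn on the upscaled study."""
    from PIL import Image, ImageDraw
    from skimage.segmentation import find_boundaries
    from skimage.transform import resize

    if not records:
        log.warning("no annotation records: overlay not written")
        return
    n = image.pixels.shape[0] * scale
    base = resize(image.pixels, (n, n), order=1, preserve_range=True)
    rgb = np.stack([base] * 3, axis=-1).astype(np.uint8)
    for rec in records:
        if rec.ivd_mask_up is not None:
            rgb[find_boundaries(rec.ivd_mask_up, mode="inner")] = (255, 0, 255)  # magenta
        if rec.nucleus_mask is not None and not rec.nucleus_mask.fallback:
            rgb[find_boundaries(rec.nucleus_mask.mask, mode="inner")] = (0, 0, 255)
        elif rec.nucleus_mask is not None:
            rgb[find_boundaries(rec.nucleus_mask.mask, mode="inner")] = (255, 0, 0)
    img = Image.fromarray(rgb)
    draw = ImageDraw.Draw(img)
    for rec in records:
        draw.line(
            [tuple(map(float, rec.segment_top)), tuple(map(float, rec.segment_bottom))],
            fill=(255, 255, 0),
            width=2,
        )
    img.save(path)
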