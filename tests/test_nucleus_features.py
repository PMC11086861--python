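import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spineannot.errors import NormalizationError
from spineannot.imaging_io import GreyImage, ImageMeta
from spineannot.nucleus_features import (
    QuantizerConfig,
    adjust_brightness,
    correlogram_matrix,
    detect_nucleus,
    estimate_reference_mean,
    quantize,
    sscc,
    sscc_length,
)


def _img(pixels):
    pixels = np.asarray(pixels, float)
    return GreyImage(pixels, ImageMeta(1.0, pixels.shape[0]))


def test_adjust_brightness_rules():
    base = np.full((10, 10), 100.0)
    vert = np.zeros((10, 10), bool)
    vert[:3] = True

    img = _img(base.copy())
    img.pixels[vert] = 69.0
    out = adjust_brightness(img, vert)
    assert np.array_equal(out.pixels, img.pixels)  # at the reference: no-op

    img = _img(base.copy())
    img.pixels[vert] = 89.0  # overexposed by 20
    out = adjust_brightness(img, vert)
    assert out.pixels[5, 5] == pytest.approx(80.0)

    img = _img(np.full((10, 10), 250.0))
    img.pixels[vert] = 50.0  # underexposed: +19, capped at 255
    out = adjust_brightness(img, vert)
    assert out.pixels[5, 5] == pytest.approx(255.0)

    with pytest.raises(NormalizationError):
        adjust_brightness(img, np.zeros((10, 10), bool))


def test_estimate_reference_mean():
    vm = np.ones((4, 4), bool)
    assert estimate_reference_mean([(np.full((4, 4), 70.0), vm)]) == 70.0
    studies = [(np.full((4, 4), 60.0), vm), (np.full((4, 4), 80.0), vm)]
    assert estimate_reference_mean(studies) == 70.0
    with pytest.raises(NormalizationError):
        estimate_reference_mean([])


def test_reference_mean_recovered_from_phantom_batch():
    from spineannot.labelmap import RegionCode
    from spineannot.phantom import generate_batch

    studies = generate_batch(60, distribution="balanced", seed=17)
    pairs = [(s.image.pixels, s.labels.mask(RegionCode.VERTEBRAE)) for s in studies]
    assert estimate_reference_mean(pairs) == pytest.approx(69.0, abs=2.0)


@pytest.mark.parametrize("gl, expected", [(0, 0), (149, 29), (150, 29), (200, 29), (74.9, 14)])
def test_quantize_defaults(gl, expected):
    assert quantize(gl) == expected


@given(st.floats(min_value=0, max_value=255), st.integers(2, 32))
@settings(deadline=None)
def test_quantize_always_in_range(gl, n_gl):
    cfg = QuantizerConfig(n_gl=n_gl, gl_max=150.0)
    assert 0 <= quantize(gl, cfg) <= n_gl - 1


def test_sscc_length_law():
    for n in range(1, 33):
        for w in range(0, n):
            length = sscc_length(n, w)
            assert length == n * (2 * w + 1) - w * (w + 1)
            # cross-check against direct band enumeration
            cells = [(i, j) for i in range(n) for j in range(n) if abs(i - j) <= w]
            assert length == len(cells)
    assert sscc_length(10, 2) == 44


def test_sscc_uniform_mask_single_cell():
    img = _img(np.full((12, 12), 60.0))
    mask = np.zeros((12, 12), bool)
    mask[2:10, 2:10] = True
    feat = sscc(img, mask, QuantizerConfig(), w=2, d=4)
    c = int(quantize(60.0))
    nonzero = {cell for cell, v in zip(feat.cells, feat.values) if v}
    assert nonzero == {(c, c)}
    assert feat.values[feat.cells.index((c, c))] == 1.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_correlogram_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    img = _img(rng.integers(0, 256, size=(18, 18)).astype(float))
    mask = rng.random((18, 18)) < 0.6
    cfg = QuantizerConfig(n_gl=6, gl_max=180.0)
    d = 4
    probs = correlogram_matrix(img, mask, cfg, d=d)

    bins = quantize(img.pixels, cfg)
    counts = np.zeros((6, 6))
    pts = list(zip(*np.nonzero(mask)))
    for r1, c1 in pts:
        for r2, c2 in pts:
            if max(abs(r1 - r2), abs(c1 - c2)) == d:
                counts[bins[r1, c1], bins[r2, c2]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    oracle = np.where(sums > 0, counts / np.maximum(sums, 1), 0.0)
    assert np.array_equal(probs, oracle)


def test_correlogram_rows_sum_to_one_or_zero():
    rng = np.random.default_rng(7)
    img = _img(rng.integers(0, 256, size=(30, 30)).astype(float))
    mask = rng.random((30, 30)) < 0.5
    probs = correlogram_matrix(img, mask, QuantizerConfig(), d=4)
    sums = probs.sum(axis=1)
    assert np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0))


def _disc_with_ellipse(nucleus_level, annulus_level=35.0, frac=0.4):
    """Rectangular disc mask with a central bright ellipse."""
    img = np.full((80, 80), 10.0)
    mask = np.zeros((80, 80), bool)
    mask[20:40, 10:70] = True
    img[mask] = annulus_level
    yy, xx = np.mgrid[0:80, 0:80]
    a, b = 22.0, 8.0
    ell = ((xx - 40) / a) ** 2 + ((yy - 30) / b) ** 2 <= 1.0
    img[ell & mask] = nucleus_level
    return _img(img), mask, ell


def test_detect_nucleus_bright_ellipse():
    img, mask, ell = _disc_with_ellipse(150.0)
    nuc = detect_nucleus(img, mask)
    assert not nuc.fallback
    assert nuc.mask.sum() > 0
    assert (nuc.mask & ~ell).sum() <= 0.05 * nuc.mask.sum()  # essentially inside


def test_detect_nucleus_uniform_disc_falls_back():
    img = _img(np.full((40, 40), 30.0))
    mask = np.zeros((40, 40), bool)
    mask[10:30, 5:35] = True
    nuc = detect_nucleus(img, mask)
    assert nuc.fallback
    assert nuc.mask.sum() <= 0.8 * mask.sum() + 1
    assert (nuc.mask & ~mask).sum() == 0


def test_detect_nucleus_prefers_larger_blob():
    img = np.full((90, 90), 30.0)
    mask = np.zeros((90, 90), bool)
    mask[15:45, 5:85] = True
    big = np.zeros_like(mask)
    big[20:40, 12:47] = True  # ~40% of the shrunk region
    small = np.zeros_like(mask)
    small[25:33, 60:70] = True
    img[big | small] = 150.0
    nuc = detect_nucleus(_img(img), mask)
    assert not nuc.fallback
    assert (nuc.mask & big).sum() > 0
    assert (nuc.mask & small).sum() == 0


def test_feature_exposure_invariance():
    """The vertebrae-anchored offset correction cancels global exposure."""
    from dataclasses import replace

    from spineannot import height_measure as hm
    from spineannot import spine_topology as stp
    from spineannot.labelmap import RegionCode
    from spineannot.nucleus_features import extract_ivd_feature
    from spineannot.phantom import PhantomConfig, generate

    def feat(study):
        named = stp.assign_names(
            stp.order_path(stp.extract_skeleton(study.labels)), study.labels
        )
        up, lab_up = hm.prepare_images(study.image, study.labels)
        f, _ = extract_ivd_feature(
            up,
            lab_up.mask(RegionCode.VERTEBRAE),
            hm.upscale_mask(named.ivd("L4/L5").ccr.mask),
        )
        return f.values

    base = PhantomConfig(seed=5, grades=(1, 4, 2), noise_sd=0.0)
    f0 = feat(generate(base))
    for off in (-20.0, 20.0):
        assert np.array_equal(feat(generate(replace(base, exposure_offset=off))), f0)
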