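"""Exposure selection and exposure/area-normalized intensity measurement."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk

from quam import (
    ConfigurationError,
    ExposurePolicy,
    MissingConditionError,
    SegmentedObject,
    measure_cell,
    normalize_to_control,
    render_fields,
    segment_field,
    select_exposure,
)

SAT = 4095


def _obj_from_mask(mask, pixel_size_um=1.0):
    area = mask.sum() * pixel_size_um ** 2
    return SegmentedObject(label=1, mask=mask, area_um2=area,
                           equivalent_diameter_um=2 * np.sqrt(area / np.pi),
                           local_background=0.0)


# --------------------------------------------------------------------------
# exposure auto-selection
# --------------------------------------------------------------------------

def _images_with_saturation(sat_pixels_by_exposure, shape=(100, 100)):
    out = {}
    for t, k in sat_pixels_by_exposure.items():
        img = np.full(shape, 500)
        img.ravel()[:k] = SAT
        out[t] = img
    return out


def test_select_longest_exposure_when_nothing_saturates():
    imgs = _images_with_saturation({0.96: 0, 0.48: 0, 0.24: 0})
    assert select_exposure(imgs, ExposurePolicy()) == 0.96


def test_select_steps_down_when_budget_exceeded():
    """Budget: 1000 saturated px per 100 μm². A 100x100 px field at
    0.645 μm/px covers 4160 μm² -> budget is 41,602 px; saturate more than
    that at 0.96 s but not at 0.48 s."""
    imgs = _images_with_saturation({0.96: 9000, 0.48: 100, 0.24: 0},
                                   shape=(100, 100))
    policy = ExposurePolicy(saturation_budget=200.0)
    assert select_exposure(imgs, policy) == 0.48


def test_select_falls_back_to_shortest_with_warning():
    imgs = {t: np.full((50, 50), SAT) for t in (0.96, 0.48, 0.24)}
    policy = ExposurePolicy(saturation_budget=0.0)
    with pytest.warns(UserWarning, match="budget"):
        assert select_exposure(imgs, policy) == 0.24


def test_select_respects_eval_mask():
    img = np.full((100, 100), 500)
    img[:10, :10] = SAT  # saturation confined outside the evaluated objects
    mask = np.zeros((100, 100), dtype=bool)
    mask[50:70, 50:70] = True
    imgs = {t: img for t in (0.96, 0.48, 0.24)}
    policy = ExposurePolicy(saturation_budget=0.0)
    assert select_exposure(imgs, policy, eval_mask=mask) == 0.96


def test_empty_candidate_list_is_a_configuration_error():
    with pytest.raises(ConfigurationError, match="candidates"):
        ExposurePolicy(exposure_candidates=()).validate()


# --------------------------------------------------------------------------
# per-cell measurement
# --------------------------------------------------------------------------

def test_uniform_patch_matches_hand_computation():
    """Object of value v over n pixels: normalized = v n / (A t)."""
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:20, 10:20] = True  # 100 px
    obj = _obj_from_mask(mask, pixel_size_um=0.5)  # A = 25 μm²
    img = np.zeros((40, 40))
    img[mask] = 7.0
    raw, norm = measure_cell(obj, img, exposure_s=2.0, background=0.0)
    assert raw == pytest.approx(700.0)
    assert norm == pytest.approx(700.0 / 25.0 / 2.0)


def test_negative_integral_clamped_to_zero():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:5, 2:5] = True
    obj = _obj_from_mask(mask)
    raw, norm = measure_cell(obj, np.zeros((10, 10)), 1.0, background=50.0)
    assert raw == 0.0 and norm == 0.0


def test_mask_image_shape_mismatch_raises():
    obj = _obj_from_mask(np.ones((10, 10), dtype=bool))
    with pytest.raises(ValueError, match="shape"):
        measure_cell(obj, np.zeros((20, 20)), 1.0, background=0.0)


def test_area_invariance_for_equal_pixel_values():
    """Two uniform objects with the same pixel value but different areas get
    the same normalized intensity."""
    img = np.zeros((60, 120))
    norms = []
    for c, r in [((30, 30), 8), ((30, 90), 16)]:
        rr, cc = draw_disk(c, r)
        mask = np.zeros_like(img, dtype=bool)
        mask[rr, cc] = True
        img[mask] = 9.0
        norms.append(measure_cell(_obj_from_mask(mask), img, 1.0, 0.0)[1])
    assert norms[0] == pytest.approx(norms[1], rel=1e-12)


def _measure_field(field, spec, exposure):
    accepted, _ = segment_field(field.images["pgp"])
    tree = cKDTree(np.c_[field.truth["center_y"], field.truth["center_x"]])
    rows = []
    for o in accepted:
        _, norm = measure_cell(o, field.images["perk"], exposure,
                               spec.background_level, gain=spec.gain)
        _, i = tree.query(o.centroid)
        rows.append((field.truth["cell_id"].iloc[i], norm,
                     field.truth["intensity_perk_baseline"].iloc[i]))
    return pd.DataFrame(rows, columns=["cell_id", "measured", "truth"])


def test_noise_free_render_recovers_true_intensity(noise_free_field, noise_free_spec):
    t = _measure_field(noise_free_field, noise_free_spec, 0.96)
    assert len(t) == len(noise_free_field.truth)
    np.testing.assert_allclose(t["measured"], t["truth"], rtol=0.01)


def test_exposure_invariance_of_normalized_intensity(clean_population, noise_free_spec):
    """The same cells imaged at 0.48 s and 0.96 s (quantized, unclipped)
    yield the same normalized intensities within quantization tolerance."""
    spec = noise_free_spec
    spec_q = type(spec)(**{**spec.__dict__, "quantize": True})
    per_exposure = {}
    for expo in (0.48, 0.96):
        f = render_fields(clean_population, spec_q, expo, seed=12)[0]
        assert f.images["perk"].max() < spec_q.saturation_level  # no clipping
        per_exposure[expo] = _measure_field(f, spec_q, expo).set_index("cell_id")
    joined = per_exposure[0.48].join(per_exposure[0.96], lsuffix="_a", rsuffix="_b")
    # rounding to integer counts biases each uniform cell by up to 0.5 count
    # per pixel, i.e. 0.5 / (pixel_area x exposure x gain) per exposure
    q_step = 0.5 / (spec_q.pixel_size_um ** 2 * spec_q.gain)
    atol = q_step * (1 / 0.48 + 1 / 0.96)
    np.testing.assert_allclose(joined["measured_a"], joined["measured_b"],
                               rtol=0.01, atol=atol)


# --------------------------------------------------------------------------
# control normalization
# --------------------------------------------------------------------------

def _cells(vals_by_condition):
    rows = []
    for cond, vals in vals_by_condition.items():
        for v in vals:
            rows.append({"condition": cond, "intensity_perk": v})
    return pd.DataFrame(rows)


def test_control_scaling_hand_example():
    t = normalize_to_control(_cells({"control": [1.0, 2.0, 3.0]}), "control")
    np.testing.assert_allclose(sorted(t["intensity_perk"]), [0.5, 1.0, 1.5])


def test_control_mean_becomes_exactly_one():
    rng = np.random.default_rng(0)
    t = _cells({"control": rng.lognormal(0, 1.2, 500),
                "stim": rng.lognormal(1, 1.2, 500)})
    out = normalize_to_control(t, "control")
    ctrl_mean = out[out["condition"] == "control"]["intensity_perk"].mean()
    assert abs(ctrl_mean - 1.0) < 1e-12


def test_normalization_is_idempotent():
    rng = np.random.default_rng(1)
    t = _cells({"control": rng.lognormal(0, 1.0, 300)})
    once = normalize_to_control(t, "control")
    twice = normalize_to_control(once, "control")
    pd.testing.assert_frame_equal(once, twice)


def test_normalization_preserves_scenario_cv():
    rng = np.random.default_rng(2)
    vals = rng.lognormal(*__import__("quam").lognormal_params(1.0, 1.8), 40_000)
    out = normalize_to_control(_cells({"control": vals}), "control")
    assert out["intensity_perk"].std(ddof=1) == pytest.approx(1.8, rel=0.12)


def test_missing_or_degenerate_control_raises():
    with pytest.raises(MissingConditionError):
        normalize_to_control(_cells({"stim": [1.0]}), "control")
    with pytest.raises(ConfigurationError, match="zero"):
        normalize_to_control(_cells({"control": [0.0, 0.0]}), "control")
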