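"""Detection correctness: oracle equivalence of the primitive operations,
size gating, sensitivity/precision on ground truth, and invariances."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgpipe.io_formats import MovieStack, StimulusProtocol, Trial
from mgpipe.roi_detection import (DegenerateImageError, detect_active_rois,
                                  expected_disc_area_px, global_signal_mask,
                                  min_image, normalize_to_min, otsu_threshold,
                                  response_image, score_detections)
from mgpipe.synthetic_data import (LayerModel, SimulationConfig,
                                   simulate_calyx_movie, transient_kernel)

from conftest import make_movie, make_protocol


# --- brute-force oracles -----------------------------------------------------

def brute_min(stack):
    t, z, y, x = stack.shape
    out = np.empty((z, y, x), stack.dtype)
    for zi in range(z):
        for yi in range(y):
            for xi in range(x):
                out[zi, yi, xi] = min(stack[ti, zi, yi, xi] for ti in range(t))
    return out


def brute_normalize(stack, m, eps):
    out = np.empty_like(stack, dtype=float)
    t = stack.shape[0]
    for ti in range(t):
        out[ti] = (stack[ti] - m) / (m + eps)
    return out


def brute_otsu(image, nbins=256):
    v = np.asarray(image, float).ravel()
    counts, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    variances = np.full(nbins - 1, -np.inf)
    for k in range(nbins - 1):
        w0, w1 = counts[:k + 1].sum(), counts[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k + 1] * centers[:k + 1]).sum() / w0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    tied = [k for k, var in enumerate(variances) if var == variances.max()]
    return float(edges[tied[len(tied) // 2] + 1])


# --- primitive operations ----------------------------------------------------

def test_min_image_constant_movie():
    movie = make_movie(np.full((4, 1, 5, 5), 7.0))
    assert np.all(min_image(movie) == 7.0)


def test_min_image_matches_brute_force():
    stack = np.random.default_rng(2).random((12, 2, 9, 9)).astype(np.float32)
    assert np.array_equal(min_image(make_movie(stack)), brute_min(stack))


def test_normalize_trivial_cases():
    m = np.full((1, 4, 4), 100.0)
    movie = make_movie(np.full((3, 1, 4, 4), 100.0))
    assert np.all(normalize_to_min(movie, m, eps=1e-9) == 0.0)
    peak = make_movie(np.full((2, 1, 4, 4), 150.0))
    out = normalize_to_min(peak, m, eps=1e-9)
    assert out.max() == pytest.approx(0.5, rel=1e-6)


def test_normalize_matches_elementwise_oracle():
    rng = np.random.default_rng(2)
    stack = (100 + 20 * rng.random((8, 1, 7, 7))).astype(np.float64)
    m = stack.min(axis=0)
    got = normalize_to_min(make_movie(stack), m, eps=0.5)
    want = brute_normalize(stack, m, 0.5)
    assert np.allclose(got, want, rtol=1e-6, atol=1e-7)


def test_otsu_binary_and_bimodal():
    img = np.zeros((16, 16))
    img[:, 8:] = 1.0
    thr = otsu_threshold(img)
    assert 0.0 < thr < 1.0
    rng = np.random.default_rng(0)
    mix = np.concatenate([rng.normal(20, 5, 500), rng.normal(200, 5, 500)])
    assert 50 < otsu_threshold(mix.reshape(20, 50)) < 170


def test_otsu_matches_exhaustive_search_exactly():
    img = np.random.default_rng(9).random((64, 64))
    assert otsu_threshold(img) == brute_otsu(img)


def test_otsu_constant_image_raises():
    with pytest.raises(DegenerateImageError):
        otsu_threshold(np.full((8, 8), 3.0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(16, 64), st.integers(16, 64))
def test_otsu_oracle_equivalence_property(seed, h, w):
    # at realistic image sizes the variance criterion's gaps between distinct
    # split partitions dwarf float rounding, so the argmax agrees exactly
    img = np.random.default_rng(seed).normal(size=(h, w))
    assert otsu_threshold(img) == brute_otsu(img)


# --- full detector -----------------------------------------------------------

def _fixed_amplitude_layer(amp_pct=50.0, active=0.5):
    return LayerModel(layer="PN_BOUTON",
                      odour_log_mean={"Oct": math.log(amp_pct)},
                      odour_log_sd={"Oct": 0.0},
                      active_fraction={"Oct": active})


def test_null_movie_yields_zero_rois(small_config, single_odour_layer):
    layer = dataclasses.replace(single_odour_layer,
                                active_fraction={"Oct": 0.0})
    movie, protocol, _ = simulate_calyx_movie(small_config, layer, ["Oct"])
    roiset = detect_active_rois(movie, protocol, protocol.trials[0])
    assert len(roiset) == 0


def test_size_gate_rejects_speck_keeps_mg():
    """A 1-px 300% speck fails the area band; a 5-um 50% blob passes."""
    t_len, y, x = 60, 64, 64
    rng = np.random.default_rng(0)
    base = np.full((y, x), 1000.0, dtype=np.float32)
    yy, xx = np.mgrid[0:y, 0:x]
    dist = np.hypot(yy - 20.0, xx - 20.0)
    blob = 1.0 / (1.0 + np.exp(2.0 * (dist - 5.0)))  # soft-edged 5-px disc
    t = np.arange(t_len) / 9.0
    kern = transient_kernel(t - 12 / 9.0, 0.2, 1.0)
    data = np.empty((t_len, 1, y, x), dtype=np.float32)
    for ti in range(t_len):
        frame = base * (1.0 + 0.5 * kern[ti] * blob)
        frame[45, 45] = 1000.0 * (1.0 + 3.0 * kern[ti])  # the speck
        data[ti, 0] = frame + rng.normal(0, 5.0, (y, x))
    movie = make_movie(data)
    protocol = make_protocol([("Oct", 10, 55)], baseline_frames=5)
    roiset = detect_active_rois(movie, protocol, protocol.trials[0])
    assert len(roiset) == 1
    assert roiset.dropped_components >= 1
    cy, cx = roiset.rois[0].centroid
    assert math.hypot(cy - 20, cx - 20) < 2.0


def test_detection_sensitivity_and_precision_seed11():
    """~40 active 50%-amplitude MGs among 80: recovery >= 0.9 both ways."""
    cfg = SimulationConfig(rng_seed=11)
    movie, protocol, truth = simulate_calyx_movie(
        cfg, _fixed_amplitude_layer(), ["Oct"])
    m = min_image(movie)
    norm = normalize_to_min(movie, m)
    for trial in protocol.trials:
        roiset = detect_active_rois(movie, protocol, trial, min_img=m,
                                    normalized=norm)
        sens, prec = score_detections(roiset, truth, "Oct",
                                      movie.pixel_size_um)
        assert sens >= 0.9
        assert prec >= 0.9


def test_monotonicity_in_amplitude(single_odour_layer):
    """Raising every amplitude (fixed noise) never loses true positives."""
    cfg = SimulationConfig(field_px=(128, 128), n_mg=10,
                           min_spacing_factor=5.0, n_puffs_per_odour=1,
                           photon_gain=0.0, read_noise_sd=5.0, rng_seed=6)

    def detected_ids(amp):
        movie, protocol, truth = simulate_calyx_movie(
            cfg, single_odour_layer, ["Oct"],
            amplitude_overrides={"Oct": np.full(10, amp)})
        roiset = detect_active_rois(movie, protocol, protocol.trials[0])
        hits = set()
        for rec in roiset.rois:
            for mg in truth:
                cy, cx = mg.center_px(movie.pixel_size_um)
                if math.hypot(rec.centroid[0] - cy, rec.centroid[1] - cx) \
                        <= mg.radius_um / movie.pixel_size_um:
                    hits.add(mg.mg_id)
        return hits

    low, high = detected_ids(35.0), detected_ids(60.0)
    assert low <= high


def test_intensity_scale_invariance(small_config, single_odour_layer):
    movie, protocol, _ = simulate_calyx_movie(small_config,
                                              single_odour_layer, ["Oct"])
    scaled = movie.with_data(movie.data * 3.7)
    r1 = detect_active_rois(movie, protocol, protocol.trials[0])
    r2 = detect_active_rois(scaled, protocol, protocol.trials[0])
    assert np.array_equal(r1.labels, r2.labels)


def test_global_signal_mask_covers_calyx(small_config, single_odour_layer):
    movie, _, _, extras = simulate_calyx_movie(
        small_config, single_odour_layer, ["Oct"], return_extras=True)
    mask = global_signal_mask(movie)
    base = extras["baseline"]
    # bright (calyx) pixels should dominate the mask
    assert base[mask[0]].mean() > base[~mask[0]].mean()
    assert 0.2 < mask.mean() < 0.9


def test_response_image_uses_trial_window():
    data = np.full((20, 1, 6, 6), 100.0, dtype=np.float32)
    data[15, 0, 3, 3] = 200.0  # outside the trial window
    norm = normalize_to_min(make_movie(data), min_image(make_movie(data)),
                            eps=1e-9)
    r = response_image(norm, Trial("Oct", 5, 12), smoothing_frames=1)
    assert r.max() == pytest.approx(0.0, abs=1e-6)
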