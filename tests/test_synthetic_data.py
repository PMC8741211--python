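"""Generator correctness: forward model, amplitude law, placement,
gradients, synapse tables, determinism."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from mgpipe.roi_detection import min_image
from mgpipe.synthetic_data import (ConfigurationError, FractionModel,
                                   LayerModel, SimulationConfig, WeightModel,
                                   ZGradientSpec, noise_sd_for_r2,
                                   place_mg_centers, simulate_calyx_movie,
                                   simulate_synapse_table,
                                   simulate_volumetric_movie,
                                   transient_kernel, uniform_int_sd)


def test_transient_kernel_unit_peak():
    t = np.linspace(0, 10, 20001)
    k = transient_kernel(t, 0.2, 1.0)
    assert k.max() == pytest.approx(1.0, abs=1e-6)
    assert np.all(k[t < 0] == 0) and k[0] == 0


def test_noiseless_single_mg_brightest_pixel_peak(single_odour_layer):
    """A 50% amplitude transient peaks at 50% dF/F at the blob centre."""
    cfg = SimulationConfig(field_px=(64, 64), n_mg=1, n_puffs_per_odour=1,
                           photon_gain=0.0, read_noise_sd=0.0,
                           baseline_heterogeneity=0.0, rng_seed=0)
    centers = np.array([[32.0, 32.0]])  # on the pixel grid
    movie, protocol, truth = simulate_calyx_movie(
        cfg, single_odour_layer, ["Oct"], centers_px=centers,
        amplitude_overrides={"Oct": np.array([50.0])})
    trace = movie.data[:, 0, 32, 32]
    f0 = trace[:protocol.baseline_frames].mean()
    peak = 100.0 * (trace.max() - f0) / f0
    # only temporal sampling of the kernel separates the peak from 50%
    assert peak == pytest.approx(50.0, rel=0.01)


def test_zero_amplitude_movie_is_baseline_plus_noise(single_odour_layer):
    cfg = SimulationConfig(field_px=(64, 64), n_mg=6, n_puffs_per_odour=1,
                           photon_gain=0.0, read_noise_sd=0.0, rng_seed=1)
    layer = dataclasses.replace(single_odour_layer,
                                active_fraction={"Oct": 0.0})
    movie, protocol, truth, extras = simulate_calyx_movie(
        cfg, layer, ["Oct"], return_extras=True)
    base = extras["baseline"].astype(np.float32)
    assert np.array_equal(movie.data[0, 0], base)
    assert np.array_equal(movie.data.min(axis=0)[0], base)
    assert all(not m.active["Oct"] for m in truth)


def test_minimum_image_conservation(single_odour_layer):
    """Zero noise, zero bleach: the min image equals the baseline exactly."""
    cfg = SimulationConfig(field_px=(64, 64), n_mg=6, n_puffs_per_odour=1,
                           photon_gain=0.0, read_noise_sd=0.0, rng_seed=4)
    movie, _, _, extras = simulate_calyx_movie(
        cfg, single_odour_layer, ["Oct"], return_extras=True)
    assert np.array_equal(min_image(movie)[0],
                          extras["baseline"].astype(np.float32))


def test_amplitude_law_oct_mch_ratio_seed1():
    """Empirical Oct/Mch amplitude ratio matches the 1.6x log-mean offset."""
    layer = LayerModel(
        layer="PN_BOUTON",
        odour_log_mean={"Mch": math.log(50.0),
                        "Oct": math.log(50.0) + math.log(1.6)},
        odour_log_sd={"Mch": 0.4, "Oct": 0.4},
        active_fraction={"Mch": 1.0, "Oct": 1.0},
    )
    rng = np.random.default_rng(1)
    mch, _ = layer.draw_amplitudes("Mch", 400, rng)
    oct_, _ = layer.draw_amplitudes("Oct", 400, rng)
    assert 1.4 <= oct_.mean() / mch.mean() <= 1.8


def test_kc_on_normalization_gain_equalizes_log_means():
    layer = LayerModel.default("KC_CLAW_APL_ON", ["Mch", "Oct"])
    mus = [layer.effective_log_mean(o) for o in ("Mch", "Oct")]
    assert mus[0] == pytest.approx(mus[1], abs=1e-12)
    # the ungained layer keeps the contrast
    off = LayerModel.default("KC_CLAW_APL_OFF", ["Mch", "Oct"])
    assert off.effective_log_mean("Oct") > off.effective_log_mean("Mch")


def test_determinism_bit_identical(single_odour_layer, small_config):
    m1, p1, t1 = simulate_calyx_movie(small_config, single_odour_layer, ["Oct"])
    m2, p2, t2 = simulate_calyx_movie(small_config, single_odour_layer, ["Oct"])
    assert np.array_equal(m1.data, m2.data)
    assert p1 == p2
    assert [m.amplitudes for m in t1] == [m.amplitudes for m in t2]
    tab1, meta1, tr1 = simulate_synapse_table(n_pn=30, n_kc=20, rng_seed=9)
    tab2, meta2, tr2 = simulate_synapse_table(n_pn=30, n_kc=20, rng_seed=9)
    pd.testing.assert_frame_equal(tab1.df, tab2.df)
    pd.testing.assert_frame_equal(tr1.weights, tr2.weights)


def test_mg_placement_respects_spacing_and_mask():
    cfg = SimulationConfig(field_px=(120, 120), n_mg=40, rng_seed=2)
    rng = np.random.default_rng(2)
    centers = place_mg_centers(cfg, rng)
    assert len(centers) == 40
    d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    assert d.min() >= cfg.min_spacing_factor * cfg.mg_radius_px - 1e-9
    ay, ax = cfg.calyx_semiaxes_px()
    inside = (((centers[:, 0] - 60) / ay) ** 2
              + ((centers[:, 1] - 60) / ax) ** 2) <= 1.0
    assert inside.all()


def test_mg_placement_infeasible_field_raises():
    cfg = SimulationConfig(field_px=(32, 32), n_mg=200, rng_seed=0)
    with pytest.raises(ConfigurationError):
        place_mg_centers(cfg, np.random.default_rng(0))


@pytest.mark.parametrize("kind,kwargs,expected", [
    ("uniform", dict(low=0.7), [0.7] * 5),
    ("linear", dict(low=0.2), [0.2, 0.4, 0.6, 0.8, 1.0]),
])
def test_gradient_multipliers(kind, kwargs, expected):
    spec = ZGradientSpec("PA", kind=kind, **kwargs)
    assert spec.multipliers(5) == pytest.approx(expected)


def test_logistic_gradient_matches_closed_form():
    spec = ZGradientSpec("PA", kind="logistic", low=0.3, midpoint=3.0,
                         steepness=1.5)
    i = np.arange(1, 6)
    expected = 0.3 + 0.7 / (1.0 + np.exp(-1.5 * (i - 3.0)))
    assert spec.multipliers(5) == pytest.approx(expected)
    rev = ZGradientSpec("PA", kind="logistic", low=0.3, midpoint=3.0,
                        steepness=1.5, reverse=True)
    assert rev.multipliers(5) == pytest.approx(expected[::-1], abs=1e-12)


def test_volumetric_truth_profiles():
    cfg = SimulationConfig(field_px=(48, 48), n_z_slices=5, frame_rate_hz=16.0,
                           n_mg=6, n_puffs_per_odour=1, rng_seed=7)
    layer = LayerModel.default("APL_GLOBAL", ["PA", "MP"])
    grads = {"PA": ZGradientSpec("PA", kind="linear", low=0.25),
             "MP": ZGradientSpec("MP", kind="uniform")}
    _, _, truth = simulate_volumetric_movie(cfg, layer, grads,
                                            odour_sequence=["PA", "MP"])
    ratio = truth.expected_ratio_profile("PA", "MP")
    assert np.all(np.diff(ratio) > 0)  # rising gradient over uniform
    uniform_truth_ratio = truth.expected_slice_amplitude["MP"]
    assert np.ptp(uniform_truth_ratio) == pytest.approx(0.0)
    mean_pa = np.mean([m.amplitudes["PA"] for m in truth.mgs])
    assert truth.expected_slice_amplitude["PA"] == pytest.approx(
        mean_pa * grads["PA"].multipliers(5))


def test_synapse_table_zero_noise_perfect_linearity():
    wm = WeightModel(slope=1.0, intercept=0.0, noise_sd=0.0, w_min=5, w_max=60)
    table, meta, truth = simulate_synapse_table(
        n_pn=40, n_kc=10, weight_model=wm, n_pn_one_directional=0,
        n_pn_absent=0, rng_seed=5)
    pn = truth.weights[truth.weights["cell_class"] == "PN"]
    assert np.array_equal(pn["w_to_apl"], pn["w_from_apl"])
    assert truth.realized_r2["PN"] == pytest.approx(1.0)


def test_synapse_table_all_bouton_when_fraction_one():
    table, meta, _ = simulate_synapse_table(
        n_pn=20, n_kc=5, bouton_fraction_model=FractionModel(mean=0.999999,
                                                             sd=0.0),
        rng_seed=6)
    pn_ids = set(meta.loc[meta["cell_class"] == "PN", "neuron_id"])
    apl_to_pn = table.df[(table.df["region_label"] == "CA(R)")
                         & table.df["post_id"].isin(pn_ids)
                         & (table.df["pre_id"] == 1_000_000)]
    assert (apl_to_pn["compartment_tag"] == "bouton").all()


def test_noise_tuning_recovers_target_r2():
    """noise_sd_for_r2 lands the realized r2 near the requested value."""
    wm = WeightModel(slope=0.9, intercept=60.0,
                     noise_sd=noise_sd_for_r2(0.9, uniform_int_sd(10, 130), 0.63),
                     w_min=10, w_max=130)
    r2s = []
    for seed in range(6):
        _, _, truth = simulate_synapse_table(n_pn=120, n_kc=5, weight_model=wm,
                                             n_pn_one_directional=0,
                                             n_pn_absent=0, rng_seed=seed)
        r2s.append(truth.realized_r2["PN"])
    assert np.mean(r2s) == pytest.approx(0.63, abs=0.05)


def test_negative_weights_clipped_and_reported():
    wm = WeightModel(slope=0.1, intercept=-30.0, noise_sd=5.0, w_min=1,
                     w_max=10)
    _, _, truth = simulate_synapse_table(n_pn=50, n_kc=5, weight_model=wm,
                                         rng_seed=0)
    assert truth.clipped_weights > 0
    assert (truth.weights["w_from_apl"] >= 0).all()
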