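"""Region filtering, reciprocal weights, correlations and localization
fractions on synthetic APL-hub synapse tables."""

import numpy as np
import pandas as pd
import pytest

from mgpipe.connectome import (compartment_fractions, filter_region,
                               reciprocal_weights, subtype_localization_compare,
                               weight_correlation)
from mgpipe.io_formats import SynapseTable
from mgpipe.synthetic_data import (APL_BODY_ID, FractionModel, WeightModel,
                                   simulate_synapse_table)


def _table(rows):
    df = pd.DataFrame(rows, columns=["pre_id", "post_id", "x", "y", "z",
                                     "region_label", "compartment_tag"])
    return SynapseTable(df=df)


def test_filter_region_exact_match():
    rows = [(1, 2, 0, 0, 0, "CA(R)", "bouton")] * 5 \
        + [(1, 2, 0, 0, 0, "LH(R)", "bouton")] * 3
    out = filter_region(_table(rows), "CA(R)")
    assert len(out) == 5
    missing = filter_region(_table(rows), "PED(R)")
    assert len(missing) == 0


def test_filter_region_matches_generator_bookkeeping():
    table, _, truth = simulate_synapse_table(n_pn=25, n_kc=15, rng_seed=4)
    kept = filter_region(table, "CA(R)")
    assert len(kept) == truth.n_region_rows["CA(R)"]


def test_reciprocal_weight_counting():
    rows = [(99, 1, 0, 0, 0, "CA(R)", "bouton")] * 3 \
        + [(1, 99, 0, 0, 0, "CA(R)", "bouton")] * 5 \
        + [(99, 2, 0, 0, 0, "CA(R)", "dendrite")] * 2  # incoming only
    w = reciprocal_weights(_table(rows), hub_id=99)
    n1 = w.set_index("neuron_id").loc[1]
    assert n1["w_from_apl"] == 3 and n1["w_to_apl"] == 5 and n1["interacting"]
    n2 = w.set_index("neuron_id").loc[2]
    assert n2["w_from_apl"] == 2 and n2["w_to_apl"] == 0
    assert not n2["interacting"]  # one-directional: in the raw list only


def test_reciprocal_weights_match_generator_exactly():
    table, meta, truth = simulate_synapse_table(n_pn=30, n_kc=20, rng_seed=3)
    calyx = filter_region(table, "CA(R)")
    w = reciprocal_weights(calyx, APL_BODY_ID, meta).set_index("neuron_id")
    present = truth.weights[(truth.weights["w_to_apl"] > 0)
                            | (truth.weights["w_from_apl"] > 0)]
    assert len(w) == len(present)
    for _, row in present.iterrows():
        got = w.loc[row["neuron_id"]]
        assert got["w_to_apl"] == row["w_to_apl"]
        assert got["w_from_apl"] == row["w_from_apl"]
    # counting is exact: per-neuron sums tile the hub's outgoing rows
    assert w["w_from_apl"].sum() == int((calyx.df["pre_id"] == APL_BODY_ID).sum())


def test_weight_correlation_hand_computed_r2():
    w = pd.DataFrame({"neuron_id": [1, 2, 3], "w_to_apl": [1, 2, 3],
                      "w_from_apl": [1, 2, 4], "interacting": True,
                      "cell_class": "PN", "kc_subtype": "unknown"})
    res = weight_correlation(w, cell_class="PN")
    # Sxy = 3, Sxx = 2, Syy = 14/3  ->  r^2 = 3^2 / (2 * 14/3) = 27/28
    assert res.r2 == pytest.approx(27.0 / 28.0, abs=1e-12)
    perfect = w.assign(w_from_apl=[2, 4, 6])
    assert weight_correlation(perfect).r2 == pytest.approx(1.0)


def test_weight_correlation_axis_exchange_preserves_r2():
    table, meta, _ = simulate_synapse_table(n_pn=40, n_kc=10, rng_seed=8)
    w = reciprocal_weights(filter_region(table, "CA(R)"), APL_BODY_ID, meta)
    fwd = weight_correlation(w, cell_class="PN")
    swapped = w.rename(columns={"w_to_apl": "w_from_apl",
                                "w_from_apl": "w_to_apl"})
    rev = weight_correlation(swapped, cell_class="PN")
    assert fwd.r2 == pytest.approx(rev.r2, abs=1e-12)
    assert fwd.slope != pytest.approx(rev.slope)


def test_weight_correlation_degenerate_predictor_raises():
    w = pd.DataFrame({"neuron_id": [1, 2, 3], "w_to_apl": [5, 5, 5],
                      "w_from_apl": [1, 2, 3], "interacting": True,
                      "cell_class": "PN", "kc_subtype": "unknown"})
    with pytest.raises(ValueError, match="variance"):
        weight_correlation(w)


def test_compartment_fractions_trivial_cases():
    rows = [(99, 1, 0, 0, 0, "CA(R)", "bouton")] * 3 \
        + [(99, 1, 0, 0, 0, "CA(R)", "dendrite")] \
        + [(99, 2, 0, 0, 0, "CA(R)", "bouton")] * 4
    fs = compartment_fractions(_table(rows), hub_id=99, tag="bouton")
    per = fs.per_neuron.set_index("neuron_id")
    assert per.loc[1, "fraction"] == pytest.approx(0.75)
    assert per.loc[2, "fraction"] == pytest.approx(1.0)
    all_bouton = _table([(99, 1, 0, 0, 0, "CA(R)", "bouton")] * 5
                        + [(99, 2, 0, 0, 0, "CA(R)", "bouton")] * 5)
    fs2 = compartment_fractions(all_bouton, hub_id=99, tag="bouton")
    assert fs2.mean == pytest.approx(1.0) and fs2.sem == pytest.approx(0.0)


def test_compartment_fractions_excludes_unknown_only_neurons():
    rows = [(99, 1, 0, 0, 0, "CA(R)", "bouton")] * 2 \
        + [(99, 2, 0, 0, 0, "CA(R)", "unknown")] * 3
    fs = compartment_fractions(_table(rows), hub_id=99, tag="bouton")
    assert fs.excluded == 1
    assert list(fs.per_neuron["neuron_id"]) == [1]


def test_group_fraction_recovery_at_scale():
    """120 PNs, bouton fraction model 0.84: recovered mean within 0.02."""
    recovered = []
    for seed in range(5):
        table, meta, truth = simulate_synapse_table(
            n_pn=120, n_kc=5, rng_seed=seed,
            bouton_fraction_model=FractionModel(0.84, 0.10))
        fs = compartment_fractions(filter_region(table, "CA(R)"),
                                   APL_BODY_ID, "bouton", meta,
                                   cell_class="PN")
        recovered.append(fs.mean)
    assert np.mean(recovered) == pytest.approx(0.84, abs=0.02)


def test_subtype_anova_matches_hand_computation():
    fr = pd.DataFrame({"neuron_id": range(9),
                       "fraction": [0.8, 0.9, 0.85, 0.6, 0.5, 0.55,
                                    0.82, 0.88, 0.86]})
    w = pd.DataFrame({"neuron_id": range(9),
                      "kc_subtype": ["gamma"] * 3 + ["alpha_beta"] * 3
                      + ["alpha_prime_beta_prime"] * 3})
    f_stat, p, contrasts = subtype_localization_compare(fr, w, n_per_group=3)
    groups = [np.array([0.8, 0.9, 0.85]), np.array([0.6, 0.5, 0.55]),
              np.array([0.82, 0.88, 0.86])]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_hand = (ss_between / 2) / (ss_within / 6)
    assert f_stat == pytest.approx(f_hand, rel=1e-9)
    assert len(contrasts) == 3


def test_subtype_shift_detected_at_spec_sample_size():
    """alpha/beta claw fractions ~0.2 lower: significant at 70/group."""
    ps = []
    for seed in range(5):
        table, meta, _ = simulate_synapse_table(n_pn=5, n_kc=300,
                                                rng_seed=seed)
        calyx = filter_region(table, "CA(R)")
        w = reciprocal_weights(calyx, APL_BODY_ID, meta)
        fs = compartment_fractions(calyx, APL_BODY_ID, "claw", meta,
                                   cell_class="KC")
        _, p, contrasts = subtype_localization_compare(
            fs.per_neuron, w, n_per_group=70, rng_seed=seed)
        ps.append(p)
        ab = contrasts[(contrasts["group_1"] == "alpha_beta")
                       | (contrasts["group_2"] == "alpha_beta")]
        assert (ab["p_adj"] < 0.05).all()
    assert all(p < 1e-4 for p in ps)


def test_subtype_null_p_uniformish():
    """Identical subtype distributions: no systematic rejection."""
    from mgpipe.synthetic_data import FractionModel
    same = {k: FractionModel(0.75, 0.08) for k in
            ("gamma", "alpha_beta", "alpha_prime_beta_prime")}
    ps = []
    for seed in range(10):
        table, meta, _ = simulate_synapse_table(
            n_pn=5, n_kc=240, claw_fraction_models=same, rng_seed=seed)
        calyx = filter_region(table, "CA(R)")
        w = reciprocal_weights(calyx, APL_BODY_ID, meta)
        fs = compartment_fractions(calyx, APL_BODY_ID, "claw", meta,
                                   cell_class="KC")
        _, p, _ = subtype_localization_compare(fs.per_neuron, w,
                                               n_per_group=70, rng_seed=seed)
        ps.append(p)
    assert sum(p < 0.05 for p in ps) <= 3
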