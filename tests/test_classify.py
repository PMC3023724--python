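"""Histogram building, intersection cutoffs, subgroup and time-course summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quam import (
    ConfigurationError,
    MissingConditionError,
    ScenarioConfig,
    build_histogram,
    classify_positive,
    classify_responders,
    generate_population,
    intersection_cutoff,
    sample_blocked_control,
    shared_histograms,
    subgroup_profiles,
    summarize_timecourse,
)


# --------------------------------------------------------------------------
# histograms
# --------------------------------------------------------------------------

def test_uniform_sample_has_unit_density():
    rng = np.random.default_rng(0)
    h = build_histogram(rng.uniform(0, 1, 100_000),
                        edges=np.linspace(0, 1, 11))
    np.testing.assert_allclose(h.density, 1.0, atol=0.05)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 1e3), min_size=2, max_size=200),
       st.integers(5, 80))
def test_density_integrates_to_one(values, bins):
    h = build_histogram(values, bins=bins)
    integral = float(np.sum(h.density * h.widths))
    assert integral == pytest.approx(1.0, abs=1e-9)


def test_histogram_requires_two_values():
    with pytest.raises(ValueError, match="2 finite"):
        build_histogram([1.0])


def test_lognormal_histogram_mode_below_mean():
    rng = np.random.default_rng(1)
    from quam import lognormal_params
    vals = rng.lognormal(*lognormal_params(1.0, 1.8), 50_000)
    h = build_histogram(vals, bins=100)
    mode = h.centers[np.argmax(h.density)]
    assert mode < vals.mean()
    assert np.percentile(vals, 99) > 5 * np.median(vals)  # long right tail


# --------------------------------------------------------------------------
# intersection cutoff
# --------------------------------------------------------------------------

def test_separable_mixture_recovered_exactly():
    rng = np.random.default_rng(2)
    ctrl = rng.uniform(0.1, 1.0, 3000)
    test = np.concatenate([rng.uniform(0.1, 1.0, 1200),
                           rng.uniform(5.0, 9.0, 1800)])
    res = classify_positive(ctrl, test)
    assert res.fraction_above_test == pytest.approx(0.6, abs=1e-12)
    assert 1.0 < res.cutoff < 5.0
    assert res.labels.sum() == 1800


def test_identical_sample_yields_no_responders():
    rng = np.random.default_rng(3)
    x = rng.lognormal(0, 1.2, 5000)
    res = classify_positive(x, x)
    assert res.diagnostic == "no_responders"
    assert res.fraction_above_test == 0.0
    assert not res.labels.any()


def test_independent_null_draws_yield_near_zero_fraction():
    fracs = []
    for seed in range(6):
        pop = generate_population(ScenarioConfig(
            n_cells=4000, responder_fraction=0.0, seed=seed))
        res = classify_positive(pop["intensity_perk_baseline"].to_numpy(),
                                pop["intensity_perk_stimulated"].to_numpy())
        fracs.append(res.fraction_above_test)
    assert np.mean(fracs) < 0.05


def test_complete_shift_classifies_everything_positive():
    rng = np.random.default_rng(4)
    ctrl = rng.uniform(1.0, 2.0, 2000)
    test = rng.uniform(10.0, 20.0, 2000)
    res = classify_positive(ctrl, test)
    assert res.fraction_above_test == 1.0


def test_swapping_conditions_inverts_the_positive_side():
    rng = np.random.default_rng(5)
    lo = rng.uniform(0.1, 1.0, 3000)
    hi = rng.uniform(5.0, 9.0, 3000)
    mixed = np.concatenate([lo[:1500], hi[:1500]])
    fwd = classify_positive(lo, mixed)
    assert fwd.fraction_above_test == pytest.approx(0.5, abs=0.01)
    rev = classify_positive(hi, mixed)
    # with the bright sample as reference, the excess is on the low side,
    # so no cells classify as above-reference responders
    assert rev.fraction_above_test <= 0.05


def test_mismatched_edges_raise():
    rng = np.random.default_rng(6)
    a = build_histogram(rng.normal(0, 1, 100), edges=np.linspace(-3, 3, 20))
    b = build_histogram(rng.normal(0, 1, 100), edges=np.linspace(-2, 2, 20))
    with pytest.raises(ValueError, match="share"):
        intersection_cutoff(a, b)


def test_ib4_mixture_recovery_against_truth():
    sc = ScenarioConfig(n_cells=20_000, seed=7)
    pop = generate_population(sc)
    blocked = sample_blocked_control(sc, 5000, seed=107)
    res = classify_positive(blocked, pop["intensity_ib4"].to_numpy())
    true_frac = (pop["ib4_status"] == "positive").mean()
    assert res.fraction_above_test == pytest.approx(true_frac, abs=0.04)
    # agreement at the single-cell level, not just in aggregate
    agree = (pd.Series(res.labels).to_numpy()
             == (pop["ib4_status"] == "positive").to_numpy()).mean()
    assert agree > 0.95


def test_conservative_under_overlap():
    """Weak response (1.5-fold): mean recovered fraction stays within
    3 Monte-Carlo SEs of (and never far above) the true fraction."""
    fracs = []
    for seed in range(8):
        pop = generate_population(ScenarioConfig(
            n_cells=4000, responder_fraction=0.5, responder_fold_change=1.5,
            seed=seed))
        res = classify_positive(pop["intensity_perk_baseline"].to_numpy(),
                                pop["intensity_perk_stimulated"].to_numpy())
        fracs.append(res.fraction_above_test)
    mc_se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert np.mean(fracs) <= 0.5 + 3 * mc_se


def test_classify_responders_table_interface():
    pop = generate_population(ScenarioConfig(n_cells=3000, seed=8))
    cells = pd.concat([
        pd.DataFrame({"condition": "control",
                      "culture_id": np.repeat([1, 2, 3], 1000),
                      "intensity_perk": pop["intensity_perk_baseline"]}),
        pd.DataFrame({"condition": "NGF",
                      "culture_id": np.repeat([1, 2, 3], 1000),
                      "intensity_perk": pop["intensity_perk_stimulated"]}),
    ], ignore_index=True)
    res = classify_responders(cells, "control", "NGF", "perk",
                              culture_col="culture_id")
    assert res.fraction_above_test == pytest.approx(0.5, abs=0.08)
    assert len(res.per_culture) == 3
    assert res.per_culture["n_cells"].sum() == 3000
    assert res.fraction_spread is not None


def test_classify_responders_guards():
    cells = pd.DataFrame({"condition": ["control"] * 300 + ["NGF"] * 100,
                          "intensity_perk": np.r_[np.ones(300), np.ones(100) * 5]})
    with pytest.raises(ConfigurationError, match="minimum"):
        classify_responders(cells, "control", "NGF", "perk")
    with pytest.raises(MissingConditionError):
        classify_responders(cells, "control", "GDNF", "perk", min_cells=10,
                            warn_below=0)
    with pytest.warns(UserWarning, match="only"):
        classify_responders(cells, "control", "NGF", "perk", min_cells=50)


# --------------------------------------------------------------------------
# subgroup profiles and time courses
# --------------------------------------------------------------------------

def test_subgroup_means_and_sems_match_hand_computation():
    cells = pd.DataFrame({
        "intensity_perk": [1.0, 2.0, 3.0, 10.0, 20.0],
        "equivalent_diameter_um": [20, 22, 24, 28, 30],
    })
    labels = np.array([False, False, False, True, True])
    s = subgroup_profiles(cells, labels, name_a="pos", name_b="neg")
    row = s.channel_stats.iloc[0]
    assert s.n_a == 2 and s.n_b == 3
    assert row["mean_pos"] == pytest.approx(15.0)
    assert row["sem_pos"] == pytest.approx(np.std([10, 20], ddof=1) / np.sqrt(2))
    assert row["mean_neg"] == pytest.approx(2.0)
    assert row["sem_neg"] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))


def test_subgroup_diameter_histogram_modes_in_truth_ranges():
    pop = generate_population(ScenarioConfig(n_cells=8000, seed=9))
    pop["equivalent_diameter_um"] = pop["diameter_um"]
    pop["intensity_perk"] = pop["intensity_perk_baseline"]
    labels = (pop["ib4_status"] == "positive").to_numpy()
    s = subgroup_profiles(pop, labels, name_a="ib4pos", name_b="ib4neg")
    h = s.diameter_hist
    mode_pos = h.loc[h["count_ib4pos"].idxmax(), "bin_left_um"]
    mode_neg = h.loc[h["count_ib4neg"].idxmax(), "bin_left_um"]
    assert 22 <= mode_pos <= 32
    assert 14 <= mode_neg <= 24
    assert np.all(np.diff(h["bin_left_um"]) == pytest.approx(2.0))


def test_identical_subgroups_give_uniformish_pvalues():
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(60):
        cells = pd.DataFrame({"intensity_perk": rng.lognormal(0, 1, 400)})
        labels = rng.random(400) < 0.5
        s = subgroup_profiles(cells, labels)
        ps.append(s.channel_stats["p_value"].iloc[0])
    assert 0.35 < np.mean(ps) < 0.65


def test_empty_subgroup_skips_test():
    cells = pd.DataFrame({"intensity_perk": [1.0, 2.0]})
    s = subgroup_profiles(cells, [False, False])
    assert s.n_a == 0
    assert np.isnan(s.channel_stats["p_value"].iloc[0])


def test_timecourse_flat_and_ramp():
    rng = np.random.default_rng(11)
    times = np.repeat([0, 5, 15, 30], 800)
    flat = pd.DataFrame({"t": times, "y": rng.normal(1.0, 0.1, times.size)})
    out = summarize_timecourse(flat, "y", "t")
    assert list(out["t"]) == [0, 5, 15, 30]
    assert list(out["n"]) == [800] * 4
    np.testing.assert_allclose(out["mean"], 1.0, atol=0.02)

    ramp_mean = {0: 1.0, 5: 2.0, 15: 4.0, 30: 4.0}  # rises then plateaus
    ramp = pd.DataFrame({"t": times,
                         "y": [rng.normal(ramp_mean[t], 0.2) for t in times]})
    out = summarize_timecourse(ramp, "y", "t")
    diffs = np.diff(out["mean"])
    assert (diffs > -3 * out["sem"].iloc[1:].to_numpy()).all()  # monotone to plateau
    assert out["mean"].iloc[2] == pytest.approx(out["mean"].iloc[3], abs=0.1)
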