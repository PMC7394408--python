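"""PulSA gating, log binning, inclusion-fraction surfaces, stall ratios."""

import numpy as np
import pandas as pd
import pytest

import inclusiontools as it
from inclusiontools.cytometry import TMR_CATEGORIES, _assign
from inclusiontools.errors import CalibrationError, SeparabilityWarning


# -- gate -------------------------------------------------------------------


def test_gate_concordance_at_default_separation(gate_calibration):
    events = it.simulate_population(it.PopulationSpec(n_events=10_000, seed=1))
    flags = it.pulsa_gate(events, gate_calibration)
    concordance = (flags == events["true_inclusion"].to_numpy()).mean()
    assert concordance >= 0.95


def test_gate_null_separation_warns_and_flips_coins(gate_calibration):
    null = it.PopulationSpec(n_events=2000, pulse_width_shift=0.0,
                             pulse_height_shift=0.0)
    neg = it.simulate_population(
        it.PopulationSpec(**{**null.__dict__, "logistic_intercept": -30.0,
                             "seed": 31}))
    pos = it.simulate_population(
        it.PopulationSpec(**{**null.__dict__, "logistic_intercept": 30.0,
                             "seed": 32}))
    events = it.simulate_population(it.PopulationSpec(n_events=5000, seed=33))
    with pytest.warns(SeparabilityWarning):
        flags = it.pulsa_gate(events, {"negative": neg, "positive": pos})
    accuracy = (flags == events["true_inclusion"].to_numpy()).mean()
    assert 0.3 < accuracy < 0.7


def test_gate_deterministic_on_reapplication(gate_calibration, small_population):
    gate = it.fit_pulsa_gate(gate_calibration["negative"],
                             gate_calibration["positive"])
    f1 = gate.apply(small_population)
    f2 = gate.apply(small_population)
    np.testing.assert_array_equal(f1, f2)


def test_gate_rejects_small_and_identical_calibration(gate_calibration):
    tiny = gate_calibration["negative"].head(50)
    with pytest.raises(CalibrationError):
        it.fit_pulsa_gate(tiny, gate_calibration["positive"])
    same = gate_calibration["negative"]
    with pytest.raises(CalibrationError):
        it.fit_pulsa_gate(same, same)


# -- binning ----------------------------------------------------------------


def test_log_bin_edges_constant_factor():
    events = pd.DataFrame({"cerulean_area": np.concatenate([[1.0, 1e4],
                                                            np.full(98, 50.0)]),
                           "tmr_area": np.full(100, 10.0),
                           "construct": "97Q"})
    edges = it.make_bins(events)
    ratios = edges.cerulean_edges[1:] / edges.cerulean_edges[:-1]
    np.testing.assert_allclose(ratios, 10 ** 0.2, rtol=1e-9)
    assert len(edges.cerulean_edges) == 21


def test_all_tmr_below_floor_is_none_category(small_population):
    events = small_population.copy()
    events["tmr_area"] = 1e-6
    edges = it.make_bins(events, tmr_floor=1.0)
    grids = it.inclusion_fraction(events,
                                  events["true_inclusion"].to_numpy(), edges)
    grid = grids["97Q"]
    assert grid.counts[:, 1:].sum() == 0
    assert grid.counts[:, 0].sum() == len(events)


def test_interior_edge_value_goes_to_higher_bin():
    edges = np.array([1.0, 10.0, 100.0, 1000.0])
    idx = _assign(np.array([10.0]), edges)
    assert idx[0] == 1  # [10, 100) bin, not [1, 10)
    assert _assign(np.array([1000.0]), edges)[0] == 2  # last bin closed


def test_binning_conserves_events_and_is_permutation_invariant(
        small_population, gate_calibration):
    events = small_population
    flags = it.pulsa_gate(events, gate_calibration)
    edges = it.make_bins(events)
    grid = it.inclusion_fraction(events, flags, edges)["97Q"]
    assert grid.counts.sum() == len(events)

    perm = np.random.default_rng(0).permutation(len(events))
    shuffled = events.iloc[perm].reset_index(drop=True)
    grid2 = it.inclusion_fraction(shuffled, flags[perm], edges)["97Q"]
    np.testing.assert_array_equal(grid.counts, grid2.counts)
    np.testing.assert_array_equal(grid.inclusion_counts, grid2.inclusion_counts)


def test_fraction_simple_count_and_empty_bins_flagged():
    events = pd.DataFrame({
        "construct": "97Q",
        "cerulean_area": np.concatenate([np.full(10, 5.0), [1.0, 1e4]]),
        "tmr_area": np.full(12, 1e-9),
    })
    flags = np.array([True] * 3 + [False] * 9)
    edges = it.make_bins(events, tmr_floor=1.0)
    grid = it.inclusion_fraction(events, flags, edges)["97Q"]
    populated = grid.counts[:, 0] == 10
    assert grid.fraction[populated, 0] == pytest.approx(0.3)
    assert np.isnan(grid.fraction[grid.counts == 0]).all()


def test_observed_fractions_track_logistic_model():
    """Per-bin inclusion fractions lie within 3 binomial SE of the
    generator's logistic probabilities (n = 50,000)."""
    events = it.simulate_population(it.PopulationSpec(n_events=50_000, seed=2))
    flags = events["true_inclusion"].to_numpy()
    edges = it.make_bins(events)
    ci = _assign(events["cerulean_area"].to_numpy(), edges.cerulean_edges)
    p_true = events["true_probability"].to_numpy()
    for b in range(20):
        sel = ci == b
        n = sel.sum()
        if n < 20:
            continue
        expected = p_true[sel].mean()
        se = np.sqrt(max(expected * (1 - expected), 1e-12) / n)
        assert abs(flags[sel].mean() - expected) <= 3 * se + 1e-12


def test_suppressor_modifier_non_increasing_across_tmr(gate_calibration):
    """Negative-modifier populations show non-increasing inclusion fractions
    across TMR categories within each expression bin (suppression pattern)."""
    events = it.simulate_population(
        it.PopulationSpec(n_events=50_000, logistic_beta_modifier=-0.8,
                          logistic_intercept=-4.0, seed=14))
    flags = it.pulsa_gate(events, gate_calibration)
    grid = it.inclusion_fraction(events, flags,
                                 it.make_bins(events))["97Q"]
    frac, counts = grid.fraction, grid.counts
    for i in range(20):
        for j in range(3):
            if counts[i, j] >= 50 and counts[i, j + 1] >= 50:
                se = np.sqrt(frac[i, j] * (1 - frac[i, j]) / counts[i, j]
                             + frac[i, j + 1] * (1 - frac[i, j + 1])
                             / counts[i, j + 1] + 1e-12)
                assert frac[i, j + 1] <= frac[i, j] + 3 * se


def test_null_modifier_tmr_curves_indistinguishable():
    events = it.simulate_population(
        it.PopulationSpec(n_events=50_000, logistic_beta_modifier=0.0, seed=15))
    flags = events["true_inclusion"].to_numpy()
    grid = it.inclusion_fraction(events, flags, it.make_bins(events))["97Q"]
    frac, counts = grid.fraction, grid.counts
    for i in range(20):
        for j in range(4):
            for k in range(j + 1, 4):
                if counts[i, j] >= 100 and counts[i, k] >= 100:
                    se = np.sqrt(frac[i, j] * (1 - frac[i, j]) / counts[i, j]
                                 + frac[i, k] * (1 - frac[i, k]) / counts[i, k]
                                 + 1e-12)
                    assert abs(frac[i, j] - frac[i, k]) < 3.5 * se


def test_tidy_grid_schema(small_population, gate_calibration):
    from inclusiontools.table_schemas import validate

    flags = it.pulsa_gate(small_population, gate_calibration)
    grid = it.inclusion_fraction(small_population, flags,
                                 it.make_bins(small_population))["97Q"]
    tidy = grid.to_tidy()
    validate(tidy, "bingrid")
    assert set(tidy["tmr_category"]) == set(TMR_CATEGORIES)
    assert tidy["n"].sum() == len(small_population)


# -- stall ratios -----------------------------------------------------------


def test_stall_ratio_identity_population():
    events = pd.DataFrame({"construct": "ctrl",
                           "gfp_area": [10.0, 20.0, 30.0],
                           "mcherry_area": [10.0, 20.0, 30.0]})
    summary = it.stall_ratios(events)
    assert summary.median("ctrl") == 1.0


@pytest.mark.parametrize("efficiency", [0.0, 0.5, 0.9])
def test_stall_efficiency_recovered_within_2pct(efficiency):
    events = it.stall_population("test", efficiency, n_events=50_000, seed=6)
    med = it.stall_ratios(events).median("test")
    assert abs(med - (1 - efficiency)) / (1 - efficiency + 1e-12) < 0.02


def test_stall_construct_ordering():
    """Strong-stall construct sits far below the control; polyQ constructs
    are indistinguishable from the control."""
    frames = [it.stall_population(name, eff, n_events=20_000, seed=40 + i)
              for i, (name, eff) in enumerate(
                  [("control", 0.0), ("25Q", 0.0), ("97Q", 0.0), ("20K", 0.9)])]
    events = pd.concat(frames, ignore_index=True)
    summary = it.stall_ratios(events)
    assert summary.median("20K") < 0.2 * summary.median("control")
    assert summary.median("25Q") == pytest.approx(summary.median("control"),
                                                  rel=0.05)
    assert summary.median("97Q") == pytest.approx(summary.median("control"),
                                                  rel=0.05)


def test_stall_gfp_floor_exclusion_counted():
    events = pd.DataFrame({"construct": "x",
                           "gfp_area": [0.0, 5.0, 10.0],
                           "mcherry_area": [1.0, 5.0, 5.0]})
    summary = it.stall_ratios(events, gfp_floor=1.0)
    row = summary.table.iloc[0]
    assert row["n"] == 2 and row["n_excluded"] == 1


def test_stall_all_below_floor_raises():
    events = pd.DataFrame({"construct": "x", "gfp_area": [0.1, 0.2],
                           "mcherry_area": [1.0, 1.0]})
    with pytest.raises(ValueError):
        it.stall_ratios(events, gfp_floor=1.0)
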