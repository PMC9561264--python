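"""Position histograms, specificity, occupancy, bend decomposition,
replicate t-tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from afm_dnacomplex import GeneratorConfig, emit_measurement_table
from afm_dnacomplex.core import (InvalidConfigError, SmallSampleError,
                                 fold_position_pct)
from afm_dnacomplex.stats import (build_position_histogram,
                                  compare_replicates, decompose_bend_states,
                                  fit_position_model, occupancy_at_site,
                                  specificity, specificity_from_fit,
                                  uniform_background_gof, _position_model)


def _frame(positions, replicate="r1"):
    n = len(positions)
    return pd.DataFrame({
        "molecule_id": np.arange(n), "position_pct_folded": positions,
        "bend_angle_deg": np.zeros(n), "volume_nm3": np.full(n, 100.0),
        "max_height_nm": np.full(n, 1.5), "is_qd": False,
        "condition": "c", "replicate": replicate,
    })


def test_histogram_counts_per_dna_arithmetic():
    """100 events at 47% over 200 DNA with 5% bins: the 45-50% bin holds
    0.5 events per DNA."""
    hist = build_position_histogram(_frame(np.full(100, 47.0)),
                                    bin_width_pct=5.0, n_dna=200)
    assert hist.counts[-1] == 100
    assert hist.counts_per_dna[-1] == pytest.approx(0.5)
    assert hist.counts.sum() == 100


def test_histogram_empty_and_errors():
    hist = build_position_histogram(_frame(np.empty(0)), 2.0, n_dna=10)
    assert hist.counts.sum() == 0
    with pytest.raises(InvalidConfigError):
        build_position_histogram(_frame(np.empty(0)), 2.0, n_dna=0)
    with pytest.raises(InvalidConfigError):
        build_position_histogram(_frame(np.empty(0)), 3.3, n_dna=10)


def test_histogram_top_bin_right_inclusive_and_total_invariant():
    pos = np.array([0.0, 25.0, 50.0, 49.999, 45.0])
    hist = build_position_histogram(_frame(pos), 5.0, n_dna=7)
    assert hist.counts.sum() == len(pos)
    assert hist.counts[-1] == 3  # 45.0, 49.999 and exactly 50.0
    assert hist.counts_per_dna.sum() * hist.n_dna == pytest.approx(len(pos))


def test_uniform_background_not_rejected():
    rng = np.random.default_rng(0)
    folded = fold_position_pct(rng.uniform(0, 100, 4000))
    assert uniform_background_gof(folded) > 0.01


def test_position_fit_recovers_exact_histogram():
    """A noiseless histogram built from the model itself is recovered to
    3 significant figures."""
    edges = np.linspace(0, 50, 26)
    truth = (200.0, 49.8, 1.5, 3.0)  # area, center, sd, background
    counts = _position_model(edges, *truth)
    from afm_dnacomplex.stats import PositionHistogram
    h = PositionHistogram(bin_edges=edges, counts=counts, n_dna=1000)
    fit = fit_position_model(h, site_pct=49.8)
    (mu, sd, area), bg = fit.components[0], fit.background_level
    assert area == pytest.approx(200.0, rel=1e-3)
    assert mu == pytest.approx(49.8, abs=0.05)
    assert sd == pytest.approx(1.5, rel=1e-3)
    assert bg == pytest.approx(3.0, rel=1e-3)


def test_position_fit_zero_signal_has_small_area():
    rng = np.random.default_rng(1)
    folded = fold_position_pct(rng.uniform(0, 100, 2000))
    hist = build_position_histogram(_frame(folded), 2.0, n_dna=4000)
    fit = fit_position_model(hist, 49.8)
    area = fit.components[0][2]
    assert abs(area) < 2 * np.sqrt(2000)


def test_specificity_formula_and_errors():
    assert specificity(0.0, 10.0, 505) == 1.0
    assert specificity(7.0, 7.0, 505) == 506.0
    with pytest.raises(ZeroDivisionError):
        specificity(1.0, 0.0, 505)
    with pytest.raises(InvalidConfigError):
        specificity(1.0, 1.0, 0)


@settings(deadline=None, max_examples=60)
@given(st.floats(min_value=0.0, max_value=1e3),
       st.floats(min_value=1e-3, max_value=1e3),
       st.floats(min_value=1e-3, max_value=1e3))
def test_specificity_monotonicity(a_sp, a_nsp, delta):
    """S increases with A_sp and decreases with A_nsp; S >= 1."""
    s = specificity(a_sp, a_nsp)
    assert s >= 1.0
    assert specificity(a_sp + delta, a_nsp) >= s
    assert specificity(a_sp, a_nsp + delta) <= s


def test_specificity_recovery_from_tabular_construction():
    """Tabular data built with equal specific and nonspecific event
    counts (A_sp/A_nsp = 1) recovers S within 15% of 506."""
    cfg = GeneratorConfig(n_molecules=3000, occupancy_specific=0.3,
                          nonspecific_rate=0.3)
    df = emit_measurement_table(cfg, np.random.default_rng(1))
    hist = build_position_histogram(df, 2.0, cfg.n_molecules)
    fit = fit_position_model(hist, 49.8)
    res = specificity_from_fit(fit, hist, 505)
    assert res.S == pytest.approx(506.0, rel=0.15)


def test_occupancy_trivial_cases():
    mean, sd, per = occupancy_at_site(_frame(np.full(5, 20.0)), 100)
    assert mean == 0.0
    df = pd.concat([_frame(np.full(18, 47.0), f"r{i}") for i in range(3)])
    mean, sd, per = occupancy_at_site(df, 100)
    assert mean == pytest.approx(0.18)
    assert sd == pytest.approx(0.0)
    # single replicate: SD is reported as unavailable, not zero
    mean, sd, per = occupancy_at_site(_frame(np.full(18, 47.0)), 100)
    assert sd is None


def test_occupancy_additive_background_oracle():
    """Specific occupancy 0.10 plus uniform background 0.2/DNA leaks
    0.2 * (5/49) extra events into the 45-50% bin."""
    cfg = GeneratorConfig(n_molecules=2000, occupancy_specific=0.10,
                          nonspecific_rate=0.2)
    frames = [emit_measurement_table(
        cfg.with_(replicate=f"r{i}"), np.random.default_rng(10 + i))
        for i in range(3)]
    df = pd.concat(frames, ignore_index=True)
    mean, sd, per = occupancy_at_site(df, 2000)
    # uniform positions on [1, 99]% fold to [1, 50]; the bin covers 5/49
    expected = 0.10 + 0.2 * (10.0 / 98.0)
    n_total = 3 * 2000
    se = np.sqrt(expected / n_total)
    assert abs(mean - expected) < 3 * se


def test_occupancy_molecule_mode_counts_each_dna_once():
    df = _frame(np.full(4, 47.0))
    df.loc[:, "molecule_id"] = [0, 0, 1, 2]
    mean_ev, _, _ = occupancy_at_site(df, 10, mode="events")
    mean_mol, _, _ = occupancy_at_site(df, 10, mode="molecules")
    assert mean_ev == pytest.approx(0.4)
    assert mean_mol == pytest.approx(0.3)


def test_bend_decomposition_three_state_mixture():
    rng = np.random.default_rng(2)
    cfg = GeneratorConfig(n_molecules=400, occupancy_specific=1.0,
                          nonspecific_rate=0.0)
    df = emit_measurement_table(cfg, rng)
    res = decompose_bend_states(df.bend_angle_deg.to_numpy()[:300], k=3)
    means = [c[0] for c in res.components]
    for got, want in zip(means, (0.0, 35.0, 70.0)):
        assert got == pytest.approx(want, abs=5.0)


def test_bend_decomposition_single_20deg_state():
    """The single ~20 deg state measured for ternary complexes at the
    lesion is recovered within 3 deg with k = 1."""
    rng = np.random.default_rng(3)
    angles = np.abs(rng.normal(20.0, 8.0, 300))
    res = decompose_bend_states(angles, k=1, init_means=(20.0,))
    assert res.components[0][0] == pytest.approx(20.0, abs=3.0)


def test_bend_decomposition_zero_state_dominant():
    rng = np.random.default_rng(4)
    angles = np.abs(rng.normal(0.0, 8.0, 300))
    res = decompose_bend_states(angles, k=3)
    comps = sorted(res.components, key=lambda c: -c[2])
    assert comps[0][0] == pytest.approx(0.0, abs=5.0)
    assert comps[0][2] > 0.7 * 300


def test_bend_decomposition_small_sample_refused():
    with pytest.raises(SmallSampleError):
        decompose_bend_states(np.full(20, 35.0), k=1, init_means=(35.0,))


def test_bend_decomposition_self_consistency_round_trip():
    """Sampling from the fitted parameters and refitting returns the
    same state means within tolerance."""
    rng = np.random.default_rng(5)
    cfg = GeneratorConfig(n_molecules=600, occupancy_specific=1.0,
                          nonspecific_rate=0.0)
    df = emit_measurement_table(cfg, rng)
    first = decompose_bend_states(df.bend_angle_deg.to_numpy(), k=3)
    resampled = []
    for mu, sd, area in first.components:
        resampled.append(np.abs(rng.normal(mu, sd, int(round(area)))))
    second = decompose_bend_states(np.concatenate(resampled), k=3)
    for c1, c2 in zip(first.components, second.components):
        assert c2[0] == pytest.approx(c1[0], abs=5.0)


def test_compare_replicates_identical_groups():
    res = compare_replicates((0.1, 0.1, 0.1), (0.1, 0.1, 0.1))
    assert res.t_statistic == 0.0 and res.p_value == 1.0
    assert res.stars == "ns" and res.degrees_freedom == 4


def test_compare_replicates_matches_textbook_pooled_t():
    """t and p agree with an independently coded pooled-variance formula
    to 6 decimals."""
    a = np.array([0.10, 0.10, 0.11])
    b = np.array([0.18, 0.17, 0.19])
    res = compare_replicates(a, b)
    # independent oracle: classic pooled two-sample t with df = 4
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 4.0
    t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    from scipy.stats import t as t_dist
    p_oracle = 2 * t_dist.sf(abs(t_oracle), 4)
    assert res.t_statistic == pytest.approx(t_oracle, abs=1e-6)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-6)
    assert res.stars == "***"  # p ~ 0.0003 < 0.005


def test_star_thresholds():
    from afm_dnacomplex.stats import _stars
    assert _stars(0.04) == "*"
    assert _stars(0.009) == "**"
    assert _stars(0.004) == "***"
    assert _stars(0.06) == "ns"


def test_compare_replicates_zero_variance_unequal_means():
    res = compare_replicates((0.1, 0.1, 0.1), (0.2, 0.2, 0.2))
    assert res.infinite_t
    assert np.isinf(res.t_statistic)
    with pytest.raises(InvalidConfigError):
        compare_replicates((0.1, 0.1), (0.2, 0.2, 0.2))


def test_occupancy_estimator_calibration():
    """Over 50 seeded simulations the 45-50% bin occupancy estimator is
    unbiased: the Monte-Carlo mean sits within 2 SE of the analytic
    expectation."""
    cfg = GeneratorConfig(n_molecules=500, occupancy_specific=0.15,
                          nonspecific_rate=0.2)
    vals = []
    for seed in range(50):
        df = emit_measurement_table(cfg, np.random.default_rng(1000 + seed))
        mean, _, _ = occupancy_at_site(df, cfg.n_molecules)
        vals.append(mean)
    vals = np.asarray(vals)
    p_site = (norm.cdf(55, 49.8, 1.5) - norm.cdf(45, 49.8, 1.5))
    expected = 0.15 * p_site + 0.2 * (10.0 / 98.0)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < 2 * se + 1e-3
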