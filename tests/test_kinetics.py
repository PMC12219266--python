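"""Mechanism discrimination and kinetic-constant extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hisatkin.kinetics import (
    MMFit,
    TernaryGlobalFit,
    TernaryModel,
    classify_mechanism,
    compare_routes,
    estimate_constants,
    exclude_inhibited_series,
    fit_mm,
    global_fit_ternary,
    hanes_transform,
    ping_pong_rate,
    secondary_km_his_fit,
    secondary_vmax_fit,
    ternary_rate,
)
from hisatkin.synth import SimScenario, simulate_rate_grid

from conftest import ENZYME_UM, KI_HIS, TRUTH

HIS_GRID = np.array([20.0, 50.0, 120.0, 300.0, 720.0, 1800.0, 4500.0])
ACCOA_GRID = np.array([5.0, 10.0, 25.0, 50.0, 125.0, 500.0])


def apparent_fits(model, accoa_grid=ACCOA_GRID):
    """Noise-free apparent MM fits straight from the closed forms."""
    return [
        MMFit(accoa_fixed=a, vmax_app=model.vmax_app(a), km_app=model.km_app(a))
        for a in accoa_grid
    ]


# ---------------------------------------------------------------------------
# rate law

def test_rate_law_limits(wt_model):
    assert ternary_rate(wt_model, 1e12, 1e12) == pytest.approx(wt_model.vmax, rel=1e-6)
    # at S = Km_His and saturating A the Ki term vanishes: v = Vmax/2
    assert ternary_rate(wt_model, wt_model.km_his, 1e12) == pytest.approx(
        wt_model.vmax / 2, rel=1e-6
    )
    assert ternary_rate(wt_model, 0.0, 100.0) == 0.0
    assert ternary_rate(wt_model, 100.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        ternary_rate(wt_model, -1.0, 10.0)


def test_model_validates_positivity():
    with pytest.raises(ValueError):
        TernaryModel(0.0, 20.0, 200.0, 200.0)


# ---------------------------------------------------------------------------
# Michaelis-Menten fit at fixed Ac-CoA

def test_fit_mm_round_trip_on_generating_model():
    vmax_app, km_app = 1.0, 100.0
    v = vmax_app * HIS_GRID / (km_app + HIS_GRID)
    fit = fit_mm(HIS_GRID, v, accoa_fixed=50.0)
    assert fit.vmax_app == pytest.approx(vmax_app, rel=1e-6)
    assert fit.km_app == pytest.approx(km_app, rel=1e-6)


def test_fit_mm_recovers_apparent_closed_forms(wt_model):
    """Noise-free ternary data at fixed A yields the closed-form apparent
    constants Vmax*A/(Km_A+A) and (Ki*Km_A+Km_His*A)/(Km_A+A)."""
    for a in ACCOA_GRID:
        v = ternary_rate(wt_model, HIS_GRID, a)
        fit = fit_mm(HIS_GRID, v, accoa_fixed=a)
        assert fit.vmax_app == pytest.approx(wt_model.vmax_app(a), rel=1e-6)
        assert fit.km_app == pytest.approx(wt_model.km_app(a), rel=1e-6)


def test_fit_mm_half_saturating_accoa(wt_model):
    """At A = Km_AcCoA the apparent Vmax is half of kcat*E."""
    a = TRUTH["km_accoa"]
    v = ternary_rate(wt_model, HIS_GRID, a)
    fit = fit_mm(HIS_GRID, v, accoa_fixed=a)
    assert fit.vmax_app == pytest.approx(0.5 * TRUTH["kcat"] * ENZYME_UM, rel=1e-6)


def test_fit_mm_needs_four_concentrations():
    with pytest.raises(ValueError):
        fit_mm([10.0, 100.0], [0.1, 0.5], accoa_fixed=50.0)


# ---------------------------------------------------------------------------
# Hanes transform and mechanism call

def test_hanes_algebra():
    line = hanes_transform(MMFit(accoa_fixed=50.0, vmax_app=2.0, km_app=100.0))
    assert line.slope == pytest.approx(0.5)
    assert line.intercept == pytest.approx(50.0)
    assert line.km_app == pytest.approx(100.0)


def test_hanes_points_lie_on_line(wt_model):
    a = 25.0
    v = ternary_rate(wt_model, HIS_GRID, a)
    line = hanes_transform(fit_mm(HIS_GRID, v, accoa_fixed=a))
    resid = HIS_GRID / v - (line.intercept + line.slope * HIS_GRID)
    assert np.max(np.abs(resid)) < 1e-9


def brute_force_intersections(lines):
    """Independent oracle: solve each 2x2 linear system explicitly."""
    out = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            A = np.array([[lines[i].slope, -1.0], [lines[j].slope, -1.0]])
            b = np.array([-lines[i].intercept, -lines[j].intercept])
            out.append(np.linalg.solve(A, b)[0])
    return np.array(out)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    vmax=st.floats(0.1, 10.0),
    km_a=st.floats(5.0, 100.0),
    km_s=st.floats(20.0, 1000.0),
    ki=st.floats(20.0, 1000.0),
)
def test_hanes_intersection_theorem(vmax, km_a, km_s, ki):
    """Exact sequential-mechanism lines all intersect at S = -Ki_His."""
    model = TernaryModel(vmax, km_a, km_s, ki)
    lines = [hanes_transform(f) for f in apparent_fits(model)]
    xs = brute_force_intersections(lines)
    np.testing.assert_allclose(xs, -ki, rtol=1e-8)
    call = classify_mechanism(lines)
    assert call.intersection_abscissa == pytest.approx(-ki, rel=1e-8)
    # a sequential mechanism is only distinguishable when Ki exceeds the
    # discrimination tolerance; below it the axis pattern is genuine
    if ki > call.tolerance:
        assert call.verdict == "ternary_complex"
    else:
        assert call.verdict == "substituted_enzyme"


def test_ping_pong_classified_substituted_enzyme():
    """Ping-pong lines share the ordinate intercept: abscissa 0."""
    vmax, km_a, km_s = 0.73, 19.8, 215.0
    lines = []
    for a in ACCOA_GRID:
        v = ping_pong_rate(vmax, km_a, km_s, HIS_GRID, a)
        lines.append(hanes_transform(fit_mm(HIS_GRID, v, accoa_fixed=a)))
    intercepts = [ln.intercept for ln in lines]
    np.testing.assert_allclose(intercepts, km_s / vmax, rtol=1e-6)
    call = classify_mechanism(lines)
    assert call.verdict == "substituted_enzyme"
    assert abs(call.intersection_abscissa) <= call.tolerance


def test_mechanism_call_preconditions(wt_model):
    line = hanes_transform(MMFit(accoa_fixed=5.0, vmax_app=1.0, km_app=50.0))
    with pytest.raises(ValueError):
        classify_mechanism([line])
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            classify_mechanism([line, line])  # parallel pair only


def test_mechanisms_never_confused_at_low_noise(wt_model, rng):
    """2% rate noise never flips the verdict either way (20 seeded plates)."""
    vmax, km_a, km_s = wt_model.vmax, wt_model.km_accoa, wt_model.km_his
    for _ in range(20):
        tern_lines, pp_lines = [], []
        for a in ACCOA_GRID:
            noise = 1.0 + rng.normal(0.0, 0.02, size=len(HIS_GRID))
            v_t = ternary_rate(wt_model, HIS_GRID, a) * noise
            v_p = ping_pong_rate(vmax, km_a, km_s, HIS_GRID, a) * noise
            tern_lines.append(hanes_transform(fit_mm(HIS_GRID, v_t, a)))
            pp_lines.append(hanes_transform(fit_mm(HIS_GRID, v_p, a)))
        assert classify_mechanism(tern_lines).verdict != "substituted_enzyme"
        assert classify_mechanism(pp_lines).verdict != "ternary_complex"


# ---------------------------------------------------------------------------
# secondary plots

def test_secondary_vmax_round_trip(wt_model):
    vmax, km_a = secondary_vmax_fit(apparent_fits(wt_model))
    assert vmax == pytest.approx(wt_model.vmax, rel=1e-9)
    assert km_a == pytest.approx(wt_model.km_accoa, rel=1e-9)


def test_secondary_vmax_invariant_to_ki(wt_model):
    """Vmax_app contains no Ki term, so Ki of the generator is irrelevant."""
    other = TernaryModel(wt_model.vmax, wt_model.km_accoa, wt_model.km_his,
                         wt_model.ki_his * 10)
    assert secondary_vmax_fit(apparent_fits(other)) == pytest.approx(
        secondary_vmax_fit(apparent_fits(wt_model)), rel=1e-9
    )


def test_secondary_km_his_round_trip(wt_model):
    vmax, km_a = secondary_vmax_fit(apparent_fits(wt_model))
    km_his, slope = secondary_km_his_fit(apparent_fits(wt_model), vmax)
    assert km_his == pytest.approx(wt_model.km_his, rel=1e-9)
    # slope = Ki_His * Km_AcCoA / Vmax gives a Ki estimate
    assert slope * vmax / km_a == pytest.approx(wt_model.ki_his, rel=1e-9)


def test_secondary_km_his_ping_pong_signature():
    """Ping-pong apparent values give Km_app/Vmax_app constant in A: zero
    slope, hence Ki estimate 0."""
    vmax, km_a, km_s = 0.73, 19.8, 215.0
    fits = [
        MMFit(accoa_fixed=a, vmax_app=vmax * a / (km_a + a),
              km_app=km_s * a / (km_a + a))
        for a in ACCOA_GRID
    ]
    vm, ka = secondary_vmax_fit(fits)
    km_his, slope = secondary_km_his_fit(fits, vm)
    assert km_his == pytest.approx(km_s, rel=1e-9)
    assert slope == pytest.approx(0.0, abs=1e-9)


def test_secondary_fit_preconditions(wt_model):
    with pytest.raises(ValueError):
        secondary_vmax_fit(apparent_fits(wt_model)[:2])


# ---------------------------------------------------------------------------
# substrate-inhibition exclusion

def test_automatic_exclusion_matches_known_truth(wt_model):
    """With the uncompetitive damping 1/(1+A/Ki_si) the exclusion set is
    exactly the declining Vmax_app tail, known analytically."""
    ki_si = 150.0
    fits = [
        MMFit(accoa_fixed=a,
              vmax_app=wt_model.vmax_app(a) / (1 + a / ki_si),
              km_app=wt_model.km_app(a))
        for a in ACCOA_GRID
    ]
    eff = np.array([f.vmax_app for f in fits])
    expect = np.maximum.accumulate(eff) * (1 - 0.02) > eff
    out = exclude_inhibited_series(fits)
    assert [f.excluded for f in out] == list(expect)
    assert any(f.excluded for f in out)


def test_cutoff_exclusion(wt_model):
    fits = apparent_fits(wt_model)
    out = exclude_inhibited_series(fits, accoa_cutoff=130.0, automatic=False)
    assert [f.accoa_fixed for f in out if f.excluded] == [500.0]
    for f in out:
        if f.excluded:
            assert "cutoff" in f.exclusion_reason


def test_no_inhibition_nothing_excluded(wt_model):
    out = exclude_inhibited_series(apparent_fits(wt_model))
    assert not any(f.excluded for f in out)


def test_excluding_everything_is_an_error(wt_model):
    with pytest.raises(ValueError):
        exclude_inhibited_series(apparent_fits(wt_model), accoa_cutoff=1.0,
                                 automatic=False)


# ---------------------------------------------------------------------------
# global fit

def test_global_fit_exact_recovery(wt_model, noise_free_grid):
    gf = global_fit_ternary(noise_free_grid.his_uM, noise_free_grid.accoa_uM,
                            noise_free_grid.v0_uM_s)
    for name in ("vmax", "km_accoa", "km_his", "ki_his"):
        assert getattr(gf.model_, name) == pytest.approx(
            getattr(wt_model, name), rel=1e-6
        )


def test_global_fit_single_accoa_unidentifiable(wt_model):
    his = np.tile(HIS_GRID, 2)
    accoa = np.full_like(his, 50.0)
    v = ternary_rate(wt_model, his, accoa)
    with pytest.raises(ValueError, match="ki_his"):
        global_fit_ternary(his, accoa, v)


def test_global_fit_noisy_kcat_accuracy(wt_model):
    """5% noise, many seeds: median |kcat error| < 5%."""
    errs = []
    for seed in range(100):
        sc = SimScenario(model=wt_model, noise_sd=0.05, seed=seed + 1000)
        g = simulate_rate_grid(sc)
        g = g[g.his_uM > 0]
        gf = global_fit_ternary(g.his_uM, g.accoa_uM, g.v0_uM_s, init=wt_model)
        errs.append(abs(gf.model_.vmax / ENZYME_UM - TRUTH["kcat"]) / TRUTH["kcat"])
    assert np.median(errs) < 0.05


# ---------------------------------------------------------------------------
# constant orchestration

def series_frame(model, seed=0, noise=0.0):
    sc = SimScenario(model=model, noise_sd=noise, seed=seed)
    g = simulate_rate_grid(sc)
    return g[g.his_uM > 0]


def test_estimate_constants_table1_round_trip(wt_model):
    kc = estimate_constants({"1": series_frame(wt_model)}, enzyme_uM=ENZYME_UM)
    assert kc.mean["kcat"] == pytest.approx(36.5, rel=1e-6)
    assert kc.mean["km_accoa"] == pytest.approx(19.8, rel=1e-6)
    assert kc.mean["km_his"] == pytest.approx(215.0, rel=1e-6)
    assert kc.mean["kcat_over_km_accoa"] == pytest.approx(36.5 / 19.8, rel=1e-6)
    assert kc.mean["kcat_over_km_his"] == pytest.approx(36.5 / 215.0, rel=1e-6)


def test_three_identical_series_zero_sd(wt_model):
    frames = {s: series_frame(wt_model) for s in "123"}
    kc = estimate_constants(frames, enzyme_uM=ENZYME_UM)
    assert all(sd == pytest.approx(0.0, abs=1e-9) for sd in kc.sd.values())


def test_kcat_scales_inversely_with_enzyme(wt_model):
    f = series_frame(wt_model)
    kc1 = estimate_constants({"1": f}, enzyme_uM=ENZYME_UM)
    kc2 = estimate_constants({"1": f}, enzyme_uM=2 * ENZYME_UM)
    assert kc2.mean["kcat"] == pytest.approx(kc1.mean["kcat"] / 2)
    assert kc2.mean["km_accoa"] == pytest.approx(kc1.mean["km_accoa"])
    assert kc2.mean["km_his"] == pytest.approx(kc1.mean["km_his"])


def test_constants_invariant_to_generator_ki(wt_model):
    """Recovered kcat and both Km are independent of the simulated Ki_His."""
    alt = TernaryModel(wt_model.vmax, wt_model.km_accoa, wt_model.km_his,
                       KI_HIS * 10)
    kc1 = estimate_constants({"1": series_frame(wt_model)}, enzyme_uM=ENZYME_UM)
    kc2 = estimate_constants({"1": series_frame(alt)}, enzyme_uM=ENZYME_UM)
    for key in ("kcat", "km_accoa", "km_his"):
        assert kc2.mean[key] == pytest.approx(kc1.mean[key], rel=1e-6)


def test_ratio_aggregations_both_reported(wt_model):
    models = [
        TernaryModel(wt_model.vmax * f, wt_model.km_accoa * g, wt_model.km_his,
                     KI_HIS)
        for f, g in [(0.9, 1.1), (1.0, 1.0), (1.1, 0.9)]
    ]
    frames = {str(i): series_frame(m) for i, m in enumerate(models, 1)}
    kc = estimate_constants(frames, enzyme_uM=ENZYME_UM)
    mean_of_ratios = kc.mean["kcat_over_km_accoa"]
    ratio_of_means = kc.ratio_of_means["kcat_over_km_accoa"]
    # distinct aggregations of per-series ratios
    assert mean_of_ratios != pytest.approx(ratio_of_means, rel=1e-6)
    per = kc.per_series
    assert mean_of_ratios == pytest.approx(
        np.mean([v["kcat_over_km_accoa"] for v in per.values()]), rel=1e-12
    )


def test_secondary_and_global_routes_agree_noise_free(wt_model):
    frames = {"1": series_frame(wt_model)}
    res = compare_routes(frames, ENZYME_UM)
    for key in ("kcat", "km_accoa", "km_his"):
        assert res["secondary"][key] == pytest.approx(res["global"][key], rel=1e-6)
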