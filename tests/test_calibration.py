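"""Weighted calibration fitting, SSE and LOD/LOQ estimation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenoquant.calibration import (
    average_sensitivity,
    compute_sse,
    estimate_lod_loq,
    fit_calibration,
    normalize_by_is,
)
from xenoquant.simulate import generate_batch
from xenoquant.types import TruthRecord


def oracle_weighted_fit(x, y, w):
    """Independent oracle: weighted normal equations via lstsq on the
    sqrt-weighted design matrix."""
    x, y, w = map(np.asarray, (x, y, w))
    A = np.sqrt(w)[:, None] * np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, np.sqrt(w) * y, rcond=None)
    return coef[1], coef[0]  # slope, intercept


def test_exact_line_recovered():
    pts = [(1, 2), (2, 4), (3, 6), (4, 8), (5, 10)]
    c = fit_calibration(pts)
    assert c.slope == pytest.approx(2.0)
    assert c.intercept == pytest.approx(0.0, abs=1e-12)
    assert c.r2 == pytest.approx(1.0)
    assert (c.range_min, c.range_max) == (1.0, 5.0)


def test_matches_normal_equations_oracle_on_random_data():
    rng = np.random.default_rng(11)
    for _ in range(100):
        x = np.sort(rng.uniform(0.01, 50, size=7))
        y = 3.0 * x + 1.0 + rng.normal(0, 0.2 * np.sqrt(x))  # heteroscedastic
        c = fit_calibration(list(zip(x, y)))
        slope, intercept = oracle_weighted_fit(x, y, 1.0 / x)
        assert c.slope == pytest.approx(slope, rel=1e-10)
        assert c.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)


def test_too_few_levels_error():
    with pytest.raises(ValueError, match="insufficient"):
        fit_calibration([(1, 2), (1, 3), (2, 4), (2, 5)])


def test_zero_conc_excluded_under_inverse_x():
    pts = [(0, 0.5)] + [(i, 2 * i) for i in range(1, 6)]
    c = fit_calibration(pts)
    assert c.n_points == 5
    assert c.slope == pytest.approx(2.0)


def test_weighted_equals_unweighted_on_noiseless_line():
    pts = [(i, 5 * i + 3) for i in range(1, 8)]
    w = fit_calibration(pts, "inverse_x")
    u = fit_calibration(pts, "none")
    assert w.slope == pytest.approx(u.slope)
    assert w.intercept == pytest.approx(u.intercept)


# --- internal standard ----------------------------------------------------


def _mtable(**cols):
    base = {"sample_id": [], "analyte": [], "area": [], "is_area": []}
    base.update(cols)
    return pd.DataFrame(base)


def test_is_ratio_and_unmapped_passthrough():
    df = _mtable(sample_id=["a", "b"], analyte=["x", "y"],
                 area=[100.0, 100.0], is_area=[50.0, 50.0])
    out = normalize_by_is(df, {"x": "x-13C"})
    assert out.loc[out["analyte"] == "x", "response"].iloc[0] == pytest.approx(2.0)
    assert out.loc[out["analyte"] == "y", "response"].iloc[0] == pytest.approx(100.0)


def test_missing_is_area_drops_measurement():
    df = _mtable(sample_id=["a", "b"], analyte=["x", "x"],
                 area=[100.0, 90.0], is_area=[50.0, np.nan])
    out = normalize_by_is(df, {"x": "x-13C"})
    assert list(out["sample_id"]) == ["a"]


def test_is_cancels_day_effect(single_analyte):
    """With a shared day drift, the IS-ratio RSD beats the raw-area RSD."""
    spec, truth = single_analyte
    spec = spec.model_copy(update={"internal_standard": "probe-13C"})
    df, _ = generate_batch([spec], [truth],
                           {"day_effect_sd": 0.7, "unknowns": 0}, seed=21)
    spikes = df[(df["role"] == "spike") & (df["batch"] != "rep")]
    lvl = spikes[spikes["nominal_conc"] == spikes["nominal_conc"].max()]
    raw_rsd = lvl["area"].std() / lvl["area"].mean()
    ratio = lvl["area"] / lvl["is_area"]
    is_rsd = ratio.std() / ratio.mean()
    assert is_rsd < raw_rsd


# --- SSE ------------------------------------------------------------------


def _curve(slope, analyte="x", matrix="milk"):
    pts = [(i, slope * i) for i in range(1, 6)]
    return fit_calibration(pts, analyte=analyte, matrix=matrix)


def test_sse_identity_and_arithmetic():
    assert compute_sse(_curve(1.0), _curve(1.0, matrix="solvent")) == pytest.approx(100.0)
    assert compute_sse(_curve(0.8), _curve(1.0, matrix="solvent")) == pytest.approx(80.0)


def test_sse_noiseless_generator_truth(noiseless):
    panel, truths = noiseless
    t = truths[0].model_copy(update={"sse_true": 0.5})
    df, _ = generate_batch(panel[:1], [t], seed=0)
    mat = df[df["role"] == "calibrant"]
    sol = df[df["role"] == "solvent_calibrant"]
    mc = fit_calibration(list(zip(mat["nominal_conc"], mat["area"])), analyte="a")
    sc = fit_calibration(list(zip(sol["nominal_conc"], sol["area"])), analyte="a")
    assert compute_sse(mc, sc) == pytest.approx(50.0, abs=1e-8)


def test_sse_unusable_solvent_curve():
    neg = fit_calibration([(i, -2.0 * i) for i in range(1, 6)], analyte="x",
                          matrix="solvent")
    with pytest.raises(ValueError, match="unusable solvent"):
        compute_sse(_curve(1.0), neg)


# --- LOD/LOQ --------------------------------------------------------------


def _cal_table(concs, snr_per_conc, noise=1.0):
    return pd.DataFrame({
        "nominal_conc": concs,
        "area": [s * noise for s in snr_per_conc],
        "noise": noise,
    })


def test_noiseless_data_snr_undefined(noiseless):
    panel, truths = noiseless
    df, _ = generate_batch(panel[:1], truths[:1], seed=0)
    calib = df[df["role"] == "calibrant"]
    with pytest.raises(ValueError, match="noise"):
        estimate_lod_loq(calib)


def test_linear_snr_model_interpolates_exactly():
    """S/N = 200*conc crosses 10 at 0.05 and 3 at 0.015."""
    concs = [0.01, 0.03, 0.09, 0.27, 0.81]
    table = _cal_table(concs, [200 * c for c in concs])
    est = estimate_lod_loq(table, analyte="x", matrix="milk")
    assert est.loq == pytest.approx(0.05, rel=1e-9)
    assert est.lod == pytest.approx(0.015, rel=1e-9)
    assert est.loq / est.lod == pytest.approx(10 / 3, rel=1e-9)
    assert est.method == "interpolated"
    # dense-grid oracle: smallest grid conc whose modelled S/N >= threshold
    grid = np.linspace(0.001, 1, 200000)
    assert grid[np.argmax(200 * grid >= 10)] == pytest.approx(est.loq, rel=1e-3)
    assert grid[np.argmax(200 * grid >= 3)] == pytest.approx(est.lod, rel=1e-3)


def test_all_points_below_detection_errors():
    table = _cal_table([1, 2, 3], [0.5, 1.0, 2.0])
    with pytest.raises(ValueError, match="not detectable"):
        estimate_lod_loq(table, analyte="x", matrix="milk")


def test_loq_monotone_in_noise():
    concs = [0.01, 0.03, 0.09, 0.27, 0.81]
    areas = [200 * c for c in concs]
    base = estimate_lod_loq(
        pd.DataFrame({"nominal_conc": concs, "area": areas, "noise": 1.0}),
        analyte="x", matrix="milk")
    noisier = estimate_lod_loq(
        pd.DataFrame({"nominal_conc": concs, "area": areas, "noise": 2.5}),
        analyte="x", matrix="milk")
    assert noisier.loq >= base.loq
    assert noisier.lod >= base.lod


def test_loq_monte_carlo_recovers_truth(single_analyte):
    """Mean LOQ estimate within 20% of the generator's closed-form truth."""
    spec, _ = single_analyte
    truth = TruthRecord(analyte="probe", matrix="milk", true_slope=1000.0,
                        sse_true=1.0, noise_floor=2.0, noise_cv=0.05)
    assert truth.loq_true == pytest.approx(0.02)
    ests = []
    for seed in range(100):
        df, _ = generate_batch([spec], [truth], {"unknowns": 0}, seed=seed)
        calib = df[df["role"] == "calibrant"]
        curve = fit_calibration(list(zip(calib["nominal_conc"], calib["area"])),
                                analyte="probe")
        ests.append(estimate_lod_loq(calib, curve, "probe", "milk").loq)
    assert np.mean(ests) == pytest.approx(truth.loq_true, rel=0.20)


def test_average_sensitivity_is_arithmetic_mean():
    from xenoquant.types import SensitivityEstimate

    ests = [SensitivityEstimate(analyte="x", matrix="milk", lod=l, loq=q,
                                method="interpolated")
            for l, q in [(0.01, 0.03), (0.02, 0.05)]]
    avg = average_sensitivity(ests)
    assert avg.lod == pytest.approx(0.015)
    assert avg.loq == pytest.approx(0.04)


@settings(max_examples=50, deadline=None)
@given(slope=st.floats(0.5, 100), intercept=st.floats(-5, 5))
def test_weighted_r2_is_one_on_any_exact_line(slope, intercept):
    pts = [(c, slope * c + intercept) for c in (0.1, 0.5, 2.0, 8.0, 32.0)]
    c = fit_calibration(pts)
    assert c.r2 == pytest.approx(1.0, abs=1e-9)
    assert c.slope == pytest.approx(slope, rel=1e-9)
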