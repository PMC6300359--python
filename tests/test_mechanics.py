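"""PCSA, force-frequency fitting, stiffness and tension decomposition."""

import math

import numpy as np
import pytest

from titinmech import simulate
from titinmech.errors import FitError, InvalidInputError
from titinmech.mechanics import (
    PassiveCurve,
    SigmoidParams,
    compare_curves_ftest,
    compute_pcsa,
    decompose_passive_tension,
    fit_force_frequency,
    sigmoid_eval,
    window_stiffness,
)


def test_pcsa_examples():
    assert compute_pcsa(0.01, 0.0, 1.0, density_g_cm3=1.0) == pytest.approx(0.01)
    base = compute_pcsa(0.01, 0.0, 1.0)
    angled = compute_pcsa(0.01, 11.3, 1.0)
    assert angled / base == pytest.approx(math.cos(math.radians(11.3)))


def test_pcsa_rejects_bad_inputs():
    with pytest.raises(InvalidInputError):
        compute_pcsa(0.01, 90.0, 1.0)
    with pytest.raises(InvalidInputError):
        compute_pcsa(0.01, 0.0, 0.0)


def test_sigmoid_eval_examples():
    p = SigmoidParams(0.0, 100.0, 60.0, 10.0)
    assert sigmoid_eval(p, 60.0) == pytest.approx(50.0)
    assert sigmoid_eval(p, 80.0) == pytest.approx(100 / (1 + math.exp(-2)))
    assert sigmoid_eval(p, 1e6) == pytest.approx(100.0)


def test_sigmoid_monotone_in_frequency():
    p = SigmoidParams(1.0, 90.0, 55.0, 15.0)
    f = np.linspace(1, 300, 500)
    assert np.all(np.diff(sigmoid_eval(p, f)) > 0)


def test_fit_recovers_noiseless_params(ff_params):
    data = simulate.simulate_ff_data(ff_params, noise_sd=0.0)
    fitted, info = fit_force_frequency(data.frequency_hz, data.tension_mn_mm2)
    assert fitted.p0_min == pytest.approx(ff_params.p0_min, rel=1e-3, abs=1e-3)
    assert fitted.p0_max == pytest.approx(ff_params.p0_max, rel=1e-3)
    assert fitted.f_half == pytest.approx(ff_params.f_half, rel=1e-3)
    assert fitted.k == pytest.approx(ff_params.k, rel=1e-3)
    assert info["half_maximal_frequency_hz"] == pytest.approx(fitted.f_half)


def test_fit_flat_data_is_flagged_failure():
    freq = np.array([1, 10, 40, 80, 150], dtype=float)
    with pytest.raises(FitError):
        fit_force_frequency(freq, np.full(5, 50.0))


def test_fit_needs_five_frequencies():
    with pytest.raises(InvalidInputError):
        fit_force_frequency([1, 10, 40, 80], [1, 5, 50, 90])


def test_fhalf_median_bias_under_noise(ff_params):
    """5% noise, 10 frequencies: median Fhalf bias below 2%."""
    estimates = []
    for seed in range(60):
        data = simulate.simulate_ff_data(
            ff_params, noise_sd=0.05 * ff_params.p0_max, seed=seed
        )
        fitted, _ = fit_force_frequency(data.frequency_hz, data.tension_mn_mm2)
        estimates.append(fitted.f_half)
    bias = abs(np.median(estimates) - ff_params.f_half) / ff_params.f_half
    assert bias < 0.02


def test_ftest_identical_datasets(ff_params):
    data = simulate.simulate_ff_data(ff_params, noise_sd=2.0, seed=3)
    pair = (data.frequency_hz.to_numpy(), data.tension_mn_mm2.to_numpy())
    f, p = compare_curves_ftest(pair, pair)
    assert f == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_ftest_detects_shifted_fhalf(ff_params):
    """Fhalf shifted well beyond the noise scale: detected in most replicates."""
    shifted = SigmoidParams(
        ff_params.p0_min, ff_params.p0_max, ff_params.f_half * 1.4, ff_params.k
    )
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        a = simulate.simulate_ff_data(ff_params, noise_sd=2.0, seed=seed)
        b = simulate.simulate_ff_data(shifted, noise_sd=2.0, seed=1000 + seed)
        _, p = compare_curves_ftest(
            (a.frequency_hz, a.tension_mn_mm2), (b.frequency_hz, b.tension_mn_mm2)
        )
        hits += p < 0.05
    assert hits >= 0.9 * n_rep


def test_ftest_detects_doubled_tension(ff_params):
    a = simulate.simulate_ff_data(ff_params, noise_sd=ff_params.p0_max / 20, seed=5)
    b = a.copy()
    b["tension_mn_mm2"] = 2 * b["tension_mn_mm2"]
    _, p = compare_curves_ftest(
        (a.frequency_hz, a.tension_mn_mm2), (b.frequency_hz, b.tension_mn_mm2)
    )
    assert p < 0.01


def test_ftest_log_model_identical_curves():
    sl = np.arange(2.2, 3.21, 0.1)
    tension = 1.0 + 8.0 * np.log(sl - 1.9)
    f, p = compare_curves_ftest((sl, tension), (sl, tension), model="log")
    assert f < 0.01  # numerically near-perfect fits on both routes
    assert p > 0.99


def _linear_curve(state="skinned", slope=10.0, offset=0.0):
    sl = np.arange(2.2, 3.21, 0.05)
    return PassiveCurve(state, sl, offset + slope * (sl - 2.2))


def test_window_stiffness_linear_curve():
    assert window_stiffness(_linear_curve(slope=10.0)) == pytest.approx(10.0)


def test_window_stiffness_two_point_curve_at_bounds():
    curve = PassiveCurve("skinned", np.array([2.45, 2.75]), np.array([1.0, 4.0]))
    assert window_stiffness(curve) == pytest.approx((4.0 - 1.0) / 0.3)


def test_window_stiffness_offset_invariant_and_scales():
    base = window_stiffness(_linear_curve(slope=7.0))
    shifted = window_stiffness(_linear_curve(slope=7.0, offset=5.0))
    scaled = window_stiffness(
        PassiveCurve("skinned", _linear_curve().sarcomere_length_um,
                     3.0 * _linear_curve().tension_mn_mm2)
    )
    assert shifted == pytest.approx(base)
    assert scaled == pytest.approx(3.0 * window_stiffness(_linear_curve()))


def test_window_stiffness_requires_coverage():
    curve = PassiveCurve("skinned", np.array([2.5, 2.6]), np.array([1.0, 2.0]))
    with pytest.raises(InvalidInputError):
        window_stiffness(curve)


def test_decompose_simple_arithmetic():
    sl = np.array([2.3, 2.5, 2.7])
    skinned = PassiveCurve("skinned", sl, np.array([10.0, 10.0, 10.0]))
    extracted = PassiveCurve("extracted", sl, np.array([3.0, 3.0, 3.0]))
    dec = decompose_passive_tension(skinned, extracted)
    assert np.allclose(dec.titin_tension, 7.0)
    assert np.allclose(dec.ecm_tension, 3.0)
    assert dec.titin_fraction_percent == pytest.approx(70.0)


def test_decompose_identical_curves_gives_zero_titin():
    sl = np.array([2.3, 2.5, 2.7])
    curve = PassiveCurve("skinned", sl, np.array([5.0, 6.0, 7.0]))
    ext = PassiveCurve("extracted", sl, np.array([5.0, 6.0, 7.0]))
    dec = decompose_passive_tension(curve, ext)
    assert np.allclose(dec.titin_tension, 0.0)
    assert dec.titin_fraction_percent == pytest.approx(0.0)


def test_decompose_additivity_is_exact():
    spec = simulate.PassiveCurveSpec(noise_sd=0.3, seed=11)
    curves = simulate.simulate_passive_curve(spec)
    dec = decompose_passive_tension(curves["skinned"], curves["extracted"])
    assert np.allclose(dec.titin_tension + dec.ecm_tension, dec.skinned_tension)


def test_decompose_recovers_generator_truth():
    spec = simulate.PassiveCurveSpec(noise_sd=0.0, seed=0)
    curves = simulate.simulate_passive_curve(spec)
    truth = simulate.passive_curve_truth(spec)
    dec = decompose_passive_tension(curves["skinned"], curves["extracted"])
    assert np.allclose(dec.titin_tension, truth.titin_tension, atol=1e-9)


def test_decompose_disjoint_support_rejected():
    a = PassiveCurve("skinned", np.array([2.2, 2.4]), np.array([1.0, 2.0]))
    b = PassiveCurve("extracted", np.array([2.8, 3.0]), np.array([1.0, 2.0]))
    with pytest.raises(InvalidInputError):
        decompose_passive_tension(a, b)


def test_short_spring_is_stiffer_by_over_threefold():
    """1600 -> 420 residues at fixed extension data: window stiffness > 3x."""
    stiff = {}
    for res in (1600, 420):
        curves = simulate.simulate_passive_curve(
            simulate.PassiveCurveSpec(n_residues=res, noise_sd=0.0)
        )
        stiff[res] = window_stiffness(curves["skinned"])
    assert stiff[420] / stiff[1600] > 3.0
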