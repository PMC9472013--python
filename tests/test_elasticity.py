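"""Hertz forward model, contact detection, single- and two-layer fits."""

from dataclasses import replace

import numpy as np
import pytest

from ovomech import (
    HertzParams,
    SynthConfig,
    baseline_correct,
    detect_contact,
    fit_single_hertz,
    fit_two_layer,
    gen_force_curve,
    gen_grid,
    hertz_force,
    summarize_grid,
)
from ovomech.curveio import IndentationCurve
from ovomech.elasticity import NoContactError
from ovomech.workflow import analyze_curve, prepare_indentation, single_layer_modulus

from conftest import make_toy_curve


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def test_hertz_closed_form_value():
    # independent hand evaluation: (4/3)*(160/0.75)*sqrt(2.25)*1^1.5 * 1e-3 nN
    p = HertzParams(E=160.0, nu=0.5, R=2.25)
    expected = (4.0 / 3.0) * (160.0 / 0.75) * 1.5 * 1e-3
    assert hertz_force(1.0, p) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.4267, abs=5e-4)


def test_hertz_zero_contact_and_linearity_in_E():
    p = HertzParams(E=100.0)
    assert hertz_force(0.0, p) == 0.0
    assert hertz_force(0.7, HertzParams(E=200.0)) == pytest.approx(
        2.0 * hertz_force(0.7, p), rel=1e-12
    )
    delta = np.linspace(0, 2, 50)
    f = hertz_force(delta, p)
    assert np.all(np.diff(f) > 0)


def test_hertz_negative_indentation_rejected():
    with pytest.raises(ValueError):
        hertz_force(-0.1, HertzParams(E=100.0))


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------


def test_detect_contact_on_noise_free_curve():
    cfg = SynthConfig(seed=11, noise_sd_force=0.0)
    curve = baseline_correct(gen_force_curve(cfg))
    cz = detect_contact(curve)
    dz = np.median(np.diff(np.sort(curve.z[curve.mask("approach")])))
    assert abs(cz - curve.extra["truth"]["contact_z_um"]) <= 2 * dz


def test_detect_contact_pure_noise_errors(probe):
    rng = np.random.default_rng(0)
    curve = make_toy_curve(probe, n=256)
    curve.d = rng.normal(0, 1e-4, len(curve.d))
    with pytest.raises(NoContactError):
        detect_contact(curve)


def test_detect_contact_threshold_monotonicity():
    cfg = SynthConfig(seed=12)
    curve = baseline_correct(gen_force_curve(cfg))
    cz1 = detect_contact(curve, threshold=3.0)
    cz2 = detect_contact(curve, threshold=6.0)
    assert cz2 >= cz1  # a stricter threshold never detects earlier


# ---------------------------------------------------------------------------
# Single-layer fit
# ---------------------------------------------------------------------------


def test_single_fit_exact_on_noise_free_curve():
    cfg = SynthConfig(seed=13, e1=90.0, e2=None, noise_sd_force=0.0)
    fit = single_layer_modulus(gen_force_curve(cfg))
    assert abs(fit.E - 90.0) / 90.0 < 1e-3
    assert fit.converged


def test_single_fit_ooplasm_modulus_at_one_percent_noise():
    cfg = SynthConfig(seed=14, e1=90.0, e2=None)
    fit = single_layer_modulus(gen_force_curve(cfg))
    assert abs(fit.E - 90.0) / 90.0 < 0.05


def test_single_fit_range_self_consistency():
    # a true single layer fits the same modulus on half and full depth ranges
    cfg = SynthConfig(seed=15, e1=280.0, e2=None)
    ind = prepare_indentation(gen_force_curve(cfg))
    full = fit_single_hertz(ind)
    dmax = float(ind.delta[ind.segment == "approach"].max())
    half = fit_single_hertz(ind, delta_max=dmax / 2.0)
    assert abs(half.E - full.E) / full.E < 0.05


def test_single_fit_too_few_contact_samples_errors(probe):
    ind = IndentationCurve(
        delta=np.linspace(-1, 0.01, 30),
        force=np.zeros(30),
        segment=np.array(["approach"] * 30, dtype=object),
        meta=probe,
    )
    with pytest.raises(Exception, match="in-contact"):
        fit_single_hertz(ind)


# ---------------------------------------------------------------------------
# Two-layer fit
# ---------------------------------------------------------------------------


def test_two_layer_exact_on_noise_free_curve():
    cfg = SynthConfig(seed=16, noise_sd_force=0.0)
    fit, _ = analyze_curve(gen_force_curve(cfg))
    assert fit.second_layer_supported
    assert abs(fit.E1 - 50.0) / 50.0 < 0.005
    assert abs(fit.E2 - 160.0) / 160.0 < 0.005
    assert abs(fit.contact2_delta - 0.8) < 0.02


def test_two_layer_recovers_thawed_oocyte_means_with_noise():
    cfg = SynthConfig(seed=17)
    e1s, e2s = [], []
    for s in range(8):
        fit, _ = analyze_curve(gen_force_curve(cfg, seed=300 + s))
        assert fit.second_layer_supported
        e1s.append(fit.E1)
        e2s.append(fit.E2)
    assert abs(np.mean(e1s) - 50.0) / 50.0 < 0.10
    assert abs(np.mean(e2s) - 160.0) / 160.0 < 0.10


def test_two_layer_flags_single_layer_input_as_unsupported():
    cfg = SynthConfig(seed=18, e1=200.0, e2=None)
    ind = prepare_indentation(gen_force_curve(cfg))
    fit = fit_two_layer(ind)
    assert not fit.second_layer_supported
    assert np.isnan(fit.contact2_delta)
    assert fit.E2 == pytest.approx(fit.E1)  # degenerates to the single modulus


def test_two_layer_robust_to_2x_subsampling():
    cfg = SynthConfig(seed=19, noise_sd_force=0.0)
    curve = gen_force_curve(cfg)
    sub = replace(cfg, n_samples=cfg.n_samples // 2)
    curve2 = gen_force_curve(sub)
    f1, _ = analyze_curve(curve)
    f2, _ = analyze_curve(curve2)
    assert abs(f2.E2 - f1.E2) / f1.E2 < 0.02


def test_population_mean_recovery_lognormal_e2():
    # E2 lognormal around 160 Pa with CV 10%: estimator population mean
    # within 5% of the generating mean at n=50
    rng = np.random.default_rng(20)
    sigma = np.sqrt(np.log(1 + 0.10**2))
    cfg = SynthConfig(seed=20)
    truths, est = [], []
    for s in range(50):
        e2 = 160.0 * rng.lognormal(-sigma**2 / 2, sigma)
        fit, _ = analyze_curve(gen_force_curve(replace(cfg, e2=e2), seed=500 + s))
        truths.append(e2)
        est.append(fit.E2)
    assert abs(np.mean(est) - 160.0) / 160.0 < 0.05


# ---------------------------------------------------------------------------
# Grid aggregation
# ---------------------------------------------------------------------------


def test_grid_has_27_curves_and_summary_counts():
    curves = gen_grid(SynthConfig(seed=21))
    assert len(curves) == 27  # 3x3 positions x 3 replicates
    fits = [analyze_curve(c)[0] for c in curves[:6]]
    summary = summarize_grid(fits, layout=(3, 2, 1),
                             positions=[c.position for c in curves[:6]])
    assert summary.n_curves == 6


def test_identical_fits_give_zero_sd_and_replicate_permutation_invariance():
    cfg = SynthConfig(seed=22, noise_sd_force=0.0)
    fit, _ = analyze_curve(gen_force_curve(cfg))
    fits = [fit] * 9
    s = summarize_grid(fits, layout=(3, 3, 1))
    assert s.sd_E2 == 0.0
    shuffled = summarize_grid(list(reversed(fits)), layout=(3, 3, 1))
    assert shuffled.mean_E2 == s.mean_E2


def test_grid_heterogeneity_contrast_outer_vs_inner_layer():
    # outer-layer scatter dominates: CV(E1) > CV(E2) across grid positions
    curves = gen_grid(SynthConfig(seed=23))
    fits = [analyze_curve(c)[0] for c in curves]
    s = summarize_grid(fits, positions=[c.position for c in curves])
    cv1 = s.sd_E1 / s.mean_E1
    cv2 = s.sd_E2 / s.mean_E2
    assert cv1 > cv2
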