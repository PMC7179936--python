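import numpy as np
import pandas as pd
import pytest

from proclean.calibration import (
    RateDataset,
    bootstrap_identifiability,
    closed_form_estimates,
    fit_inhibition_params,
    goodness_of_fit,
    predict_exponential_rates,
)
from proclean.params import producer_params
from proclean.synthetic import default_calibration_design, generate_rate_dataset

STEP1_KEYS = ("k_g", "k_over", "k_a", "Y_g", "Y_a")
STEP2_KEYS = ("Theta_a", "n", "Theta_g", "m")


@pytest.fixture(scope="module")
def fixed(cfg):
    return {k: cfg[k] for k in ("K_g", "K_a", "l", "k_deg")}


@pytest.fixture(scope="module")
def truth(cfg):
    return producer_params(cfg, Y_h=0.0)


@pytest.fixture(scope="module")
def noiseless(truth):
    return generate_rate_dataset(truth, default_calibration_design(noise_cv=0.0, replicates=1))


def test_predicted_exponential_rates(truth):
    mu, rupg, net = predict_exponential_rates(truth, 1e9, 0.0)
    # saturating glucose: mu+ = Y_g k_g - Y_a k_over (k_g - l) - k_deg
    assert mu == pytest.approx(0.44 * 1.53 - 0.298 * 0.17 * (1.53 - 0.7) - 0.0044, abs=1e-6)
    assert net == pytest.approx(-0.17 * (1.53 - 0.7), abs=1e-6)
    mu, _, net = predict_exponential_rates(truth, 0.0, 1e9)
    assert mu == pytest.approx(0.298 * 0.97 - 0.0044, abs=1e-6)
    assert net == pytest.approx(0.97, abs=1e-6)
    mu, _, _ = predict_exponential_rates(truth, 0.0, 0.0)
    assert mu == pytest.approx(-truth.k_deg)


def test_closed_forms_recover_truth_exactly(noiseless, fixed, truth):
    est = closed_form_estimates(noiseless, fixed)
    for key in STEP1_KEYS:
        assert est[key] == pytest.approx(getattr(truth, key), rel=1e-10), key


def test_closed_form_single_record_inversion(fixed, truth):
    # acetate-only record at saturating A: Y_a = (mu+ + k_deg)/r_up_a+
    mu, _, net = predict_exponential_rates(truth, 0.0, 50.0)
    assert (mu + truth.k_deg) / net == pytest.approx(truth.Y_a, rel=1e-6)


def test_closed_forms_require_both_condition_classes(noiseless, fixed):
    only_glc = RateDataset(noiseless.table[noiseless.table.condition != "acetate_only"])
    with pytest.raises(ValueError, match="acetate_only"):
        closed_form_estimates(only_glc, fixed)
    only_ace = RateDataset(noiseless.table[noiseless.table.condition != "glucose_only"])
    with pytest.raises(ValueError, match="glucose_only"):
        closed_form_estimates(only_ace, fixed)


def test_closed_forms_reject_record_without_overflow(fixed, truth):
    # glucose so low that uptake stays below the threshold: k_over inestimable
    mu, rupg, net = predict_exponential_rates(truth, 0.05, 0.0)
    assert rupg < truth.l
    table = pd.DataFrame(
        [
            dict(condition="glucose_only", G=0.05, A=0.0, mu_plus=mu,
                 rupg_plus=rupg, net_acetate_plus=net),
            dict(condition="acetate_only", G=0.0, A=1.0, mu_plus=0.1,
                 rupg_plus=0.0, net_acetate_plus=0.3),
        ]
    )
    with pytest.raises(ValueError, match="overflow"):
        closed_form_estimates(RateDataset(table), fixed)


def test_step2_recovers_truth_on_noiseless_data(noiseless, truth):
    fit = fit_inhibition_params(noiseless, truth)
    for key in STEP2_KEYS:
        assert fit.estimates[key] == pytest.approx(getattr(truth, key), abs=1e-4), key
    assert fit.rss < 1e-12
    assert all(v == pytest.approx(1.0) for v in fit.r2.values())


def test_step2_flags_unidentifiable_acetate_terms(truth):
    mu, rupg, net = predict_exponential_rates(truth, 2.7, 0.0)
    table = pd.DataFrame(
        [
            dict(condition="glucose_plus_acetate", G=2.7, A=0.0, mu_plus=mu,
                 rupg_plus=rupg, net_acetate_plus=net)
        ]
    )
    fit = fit_inhibition_params(RateDataset(table), truth, n_starts=2)
    assert any("unidentifiable" in f for f in fit.flags)


def test_median_recovery_error_under_noise(fixed, cfg, truth):
    """5% multiplicative noise: median estimates stay within 5% of truth."""
    errs = {k: [] for k in STEP1_KEYS}
    for seed in range(20):
        data = generate_rate_dataset(
            truth, default_calibration_design(noise_cv=0.05, seed=seed)
        )
        est = closed_form_estimates(data, fixed)
        for k in STEP1_KEYS:
            errs[k].append(est[k] / getattr(truth, k) - 1.0)
    for k, v in errs.items():
        assert abs(np.median(v)) < 0.05, (k, np.median(v))


def test_goodness_of_fit_formula(rng):
    obs = rng.normal(1.0, 0.3, 40)
    assert goodness_of_fit({"x": obs}, {"x": obs})["x"] == pytest.approx(1.0)
    mean = np.full_like(obs, obs.mean())
    assert goodness_of_fit({"x": mean}, {"x": obs})["x"] == pytest.approx(0.0, abs=1e-12)
    resid = np.linspace(-0.1, 0.1, 40)
    r2 = goodness_of_fit({"x": obs - resid}, {"x": obs})["x"]
    expected = 1.0 - np.sum(resid**2) / np.sum((obs - obs.mean()) ** 2)
    assert r2 == pytest.approx(expected)
    assert np.isnan(goodness_of_fit({"x": [1.0, 2.0]}, {"x": [1.0, 1.0]})["x"])


def test_bootstrap_is_deterministic_and_tight_at_zero_noise(noiseless, truth):
    fit = fit_inhibition_params(noiseless, truth)
    b1 = bootstrap_identifiability(noiseless, truth, fit, n_boot=20, seed=42)
    b2 = bootstrap_identifiability(noiseless, truth, fit, n_boot=20, seed=42)
    assert b1["ci"] == b2["ci"]
    assert b1["n_failures"] == 0
    for k, (lo, hi) in b1["ci"].items():
        assert hi - lo < 1e-3, k
        assert lo - 1e-3 <= getattr(truth, k) <= hi + 1e-3


def test_bootstrap_ci_covers_truth_under_noise(fixed, cfg, truth):
    data = generate_rate_dataset(truth, default_calibration_design(noise_cv=0.05, seed=11))
    est = closed_form_estimates(data, fixed)
    base = producer_params({**cfg, **est}, Y_h=0.0)
    fit = fit_inhibition_params(data, base)
    boot = bootstrap_identifiability(data, base, fit, n_boot=100, seed=7)
    covered = sum(
        lo <= getattr(truth, k) <= hi for k, (lo, hi) in boot["ci"].items()
    )
    assert covered >= 3  # at most one of the four intervals may miss here
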