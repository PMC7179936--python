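import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proclean.rates import (
    RateTriple,
    cleaner_rates,
    overflow_onset_dilution,
    producer_rates,
    rate_partials,
    specific_growth_rate,
    strain_rates,
)

floats01 = st.floats(0.0, 50.0, allow_nan=False)


def test_no_substrate_no_rates(producer_wt, cleaner):
    assert producer_rates(0.0, 0.0, producer_wt) == RateTriple(0.0, 0.0, 0.0)
    assert cleaner_rates(0.0, 0.0, cleaner) == RateTriple(0.0, 0.0, 0.0)


def test_saturation_limits(producer_wt, cleaner):
    assert producer_rates(1e12, 0.0, producer_wt).r_up_g == pytest.approx(producer_wt.k_g)
    assert cleaner_rates(1e12, 0.0, cleaner).r_up_g == pytest.approx(cleaner.k_dPTS)
    # at G = 0 the CCR factor is 1, so acetate uptake saturates at k_a + k_Acs
    assert cleaner_rates(0.0, 1e12, cleaner).r_up_a == pytest.approx(2.43, abs=1e-6)


def test_half_inhibition_at_theta_a(producer_wt):
    # with n = 1 and A = Theta_a the inhibition factor is exactly 1/2
    G = 1.3
    r = producer_rates(G, producer_wt.Theta_a, producer_wt)
    assert r.r_up_g == pytest.approx(0.5 * producer_wt.k_g * G / (G + producer_wt.K_g))


def test_overflow_is_proportional_to_excess_uptake(producer_wt):
    # pick G so glucose uptake lands near 0.8, above the threshold l = 0.7
    G = 0.8 * producer_wt.K_g / (producer_wt.k_g - 0.8)
    r = producer_rates(G, 0.0, producer_wt)
    assert r.r_up_g == pytest.approx(0.8, rel=1e-12)
    assert r.r_over_a == pytest.approx(0.17 * (0.8 - 0.7))
    assert r.r_over_a == pytest.approx(0.017)


def test_overflow_kink_is_continuous(producer_wt):
    # glucose level where uptake hits the threshold exactly
    p = producer_wt
    G_star = p.l * p.K_g / (p.k_g - p.l)
    for eps in (1e-8, 1e-10):
        below = producer_rates(G_star * (1 - eps), 0.0, p).r_over_a
        above = producer_rates(G_star * (1 + eps), 0.0, p).r_over_a
        assert below == 0.0
        assert 0.0 <= above < 1e-6


def test_variant_mismatch_rejected(producer_wt, cleaner):
    with pytest.raises(ValueError):
        producer_rates(1.0, 0.0, cleaner)
    with pytest.raises(ValueError):
        cleaner_rates(1.0, 0.0, producer_wt)
    with pytest.raises(ValueError):
        producer_rates(-1.0, 0.0, producer_wt)


@settings(derandomize=True, max_examples=60)
@given(G1=floats01, G2=floats01, A=floats01)
def test_glucose_uptake_monotone_in_glucose(producer_wt, G1, G2, A):
    lo, hi = sorted((G1, G2))
    assert (
        strain_rates(lo, A, producer_wt).r_up_g
        <= strain_rates(hi, A, producer_wt).r_up_g + 1e-12
    )


@settings(derandomize=True, max_examples=60)
@given(G=floats01, A1=floats01, A2=floats01)
def test_acetate_inhibits_glucose_uptake_and_feeds_uptake(producer_wt, G, A1, A2):
    lo, hi = sorted((A1, A2))
    r_lo = strain_rates(G, lo, producer_wt)
    r_hi = strain_rates(G, hi, producer_wt)
    assert r_hi.r_up_g <= r_lo.r_up_g + 1e-12
    assert r_hi.r_up_a >= r_lo.r_up_a - 1e-12


@settings(derandomize=True, max_examples=40)
@given(G=st.floats(1e-3, 30.0), A=st.floats(1e-3, 10.0))
def test_rate_partials_match_finite_differences(producer_wt, cleaner, G, A):
    for p in (producer_wt, cleaner):
        r0, dG, dA = rate_partials(G, A, p)
        if abs(r0.r_up_g - p.l) < 1e-4:
            continue  # skip the overflow kink, derivative is one-sided there
        h = 1e-6
        rp, rm = strain_rates(G + h, A, p), strain_rates(G - h, A, p)
        for got, a, b in zip(dG, rp, rm):
            assert got == pytest.approx((a - b) / (2 * h), rel=1e-4, abs=1e-7)
        rp, rm = strain_rates(G, A + h, p), strain_rates(G, A - h, p)
        for got, a, b in zip(dA, rp, rm):
            assert got == pytest.approx((a - b) / (2 * h), rel=1e-4, abs=1e-7)


def test_growth_rate_examples(producer_wt):
    p = producer_wt
    # no substrate: pure biomass degradation
    assert specific_growth_rate(RateTriple(0, 0, 0), 1.0, 1.0, p) == pytest.approx(-0.0044)
    # uptake exactly at the overflow threshold, no acetate exchange
    mu = specific_growth_rate(RateTriple(p.l, 0, 0), 1.0, 1.0, p)
    assert mu == pytest.approx(0.44 * 0.7 - 0.0044)
    with pytest.raises(ValueError):
        specific_growth_rate(RateTriple(0, 0, 0), 0.0, 0.0, p)


def test_growth_rate_with_product_burden(producer):
    # at steady state the catalytic fraction is 1 - Y_h, which reproduces the
    # steady-state growth law mu* = (1-Y_h) r - k_deg
    p = producer
    r = RateTriple(1.0, 0.2, 0.05)
    spec = p.Y_g * 1.0 + p.Y_a * (0.2 - 0.05)
    mu = specific_growth_rate(r, 1.0 - p.Y_h, 1.0, p)
    assert mu == pytest.approx((1 - p.Y_h) * spec - p.k_deg)


def test_overflow_onset_dilution(producer_wt, producer):
    assert overflow_onset_dilution(producer_wt) == pytest.approx(0.3036)
    assert overflow_onset_dilution(producer) == pytest.approx(0.242)
    # diverting nearly all biomass synthesis to product leaves no feasible onset
    nearly_all = producer.replace(Y_h=0.999)
    assert overflow_onset_dilution(nearly_all) < 0
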