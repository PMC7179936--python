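"""Specific uptake/overflow rate laws and growth-rate expressions.

Glucose uptake follows a Monod term in glucose multiplied by an acetate
growth-inhibition factor Theta_a^n / (A^n + Theta_a^n). Acetate uptake is a
Monod term in acetate repressed by carbon catabolite repression (CCR), a
factor Theta_g^m / (r_up_g^m + Theta_g^m) driven by the glucose uptake rate
itself. Acetate overflow is piecewise linear: zero below the uptake threshold
``l`` and proportional (constant ``k_over``) to the excess above it. The
cleaner variant uses the residual uptake rate ``k_dPTS`` in place of ``k_g``
and gains an additive Acs-mediated acetate uptake term.

Rates at exactly zero concentrations are defined by continuous extension.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import StrainParams

__all__ = [
    "RateTriple",
    "strain_rates",
    "producer_rates",
    "cleaner_rates",
    "rate_partials",
    "specific_growth_rate",
    "biomass_specific_rate",
    "overflow_onset_dilution",
]


class RateTriple(NamedTuple):
    """Specific rates [g gDW^-1 h^-1]: glucose uptake, acetate uptake, acetate overflow."""

    r_up_g: float
    r_up_a: float
    r_over_a: float


def _check_conc(G, A) -> None:
    if np.any(np.asarray(G) < 0) or np.any(np.asarray(A) < 0):
        raise ValueError(f"concentrations must be >= 0, got G={G}, A={A}")


def strain_rates(G, A, p: StrainParams, overflow: bool | None = None) -> RateTriple:
    """Evaluate the rate laws of one strain at ambient (G, A).

    ``overflow`` forces the overflow branch (True: linear excess form,
    False: zero) instead of the exact max(0, .) kink; used by the piecewise
    steady-state analysis. Accepts scalars or numpy arrays.
    """
    _check_conc(G, A)
    G = np.asarray(G, dtype=float)
    A = np.asarray(A, dtype=float)
    kg = p.glucose_uptake_vmax

    inhib = p.Theta_a**p.n / (A**p.n + p.Theta_a**p.n)
    with np.errstate(invalid="ignore"):
        monod_g = np.where(G > 0, G / (G + p.K_g), 0.0)
    r_g = kg * monod_g * inhib

    ccr = p.Theta_g**p.m / (r_g**p.m + p.Theta_g**p.m)
    with np.errstate(invalid="ignore"):
        monod_a = np.where(A > 0, A / (A + p.K_a), 0.0)
    r_a = p.k_a * monod_a * ccr
    if p.is_cleaner:
        with np.errstate(invalid="ignore"):
            r_a = r_a + p.k_Acs * np.where(A > 0, A / (A + p.K_Acs), 0.0)

    excess = r_g - p.l
    if overflow is None:
        r_o = p.k_over * np.maximum(0.0, excess)
    elif overflow:
        r_o = p.k_over * excess
    else:
        r_o = np.zeros_like(r_g)
    if r_g.ndim == 0:
        return RateTriple(float(r_g), float(r_a), float(r_o))
    return RateTriple(r_g, r_a, r_o)


def producer_rates(G, A, p: StrainParams) -> RateTriple:
    if p.is_cleaner:
        raise ValueError("producer_rates called with cleaner parameters")
    return strain_rates(G, A, p)


def cleaner_rates(G, A, p: StrainParams) -> RateTriple:
    if not p.is_cleaner:
        raise ValueError("cleaner_rates called with producer parameters")
    return strain_rates(G, A, p)


def rate_partials(
    G: float, A: float, p: StrainParams, overflow: bool | None = None
) -> tuple[RateTriple, RateTriple, RateTriple]:
    """Rates and their partial derivatives w.r.t. G and A (scalar inputs).

    Returns ``(rates, d/dG, d/dA)`` as RateTriples. On the overflow kink
    (r_up_g == l) the derivative of the overflow term is taken one-sided from
    the no-overflow branch unless ``overflow`` forces the other branch.

    At A = 0 with inhibition/CCR exponents below 1 the exact one-sided
    derivative diverges; the continuous-extension value 0 is returned for the
    diverging factor (documented limitation, the calibrated exponents are 1).
    """
    _check_conc(G, A)
    kg = p.glucose_uptake_vmax

    mg = G / (G + p.K_g) if G > 0 else 0.0
    dmg = p.K_g / (G + p.K_g) ** 2

    tn = p.Theta_a**p.n
    h = tn / (A**p.n + tn)
    if A > 0:
        dh = -p.n * A ** (p.n - 1.0) * tn / (A**p.n + tn) ** 2
    else:
        dh = -1.0 / p.Theta_a if p.n == 1.0 else 0.0

    r_g = kg * mg * h
    r_g_G = kg * dmg * h
    r_g_A = kg * mg * dh

    tm = p.Theta_g**p.m
    c = tm / (r_g**p.m + tm)
    if r_g > 0:
        dc = -p.m * r_g ** (p.m - 1.0) * tm / (r_g**p.m + tm) ** 2
    else:
        dc = -1.0 / p.Theta_g if p.m == 1.0 else 0.0

    ma = A / (A + p.K_a) if A > 0 else 0.0
    dma = p.K_a / (A + p.K_a) ** 2

    r_a = p.k_a * ma * c
    r_a_G = p.k_a * ma * dc * r_g_G
    r_a_A = p.k_a * (dma * c + ma * dc * r_g_A)
    if p.is_cleaner:
        macs = A / (A + p.K_Acs) if A > 0 else 0.0
        r_a += p.k_Acs * macs
        r_a_A += p.k_Acs * p.K_Acs / (A + p.K_Acs) ** 2

    over = overflow if overflow is not None else (r_g > p.l)
    if over:
        r_o = p.k_over * (r_g - p.l) if overflow is not None else p.k_over * max(0.0, r_g - p.l)
        r_o_G = p.k_over * r_g_G
        r_o_A = p.k_over * r_g_A
    else:
        r_o = 0.0
        r_o_G = 0.0
        r_o_A = 0.0

    return (
        RateTriple(r_g, r_a, r_o),
        RateTriple(r_g_G, r_a_G, r_o_G),
        RateTriple(r_g_A, r_a_A, r_o_A),
    )


def biomass_specific_rate(rates: RateTriple, p: StrainParams) -> float:
    """Specific biomass-production rate r = Y_g r_up_g + Y_a (r_up_a - r_over_a)."""
    return p.Y_g * rates.r_up_g + p.Y_a * (rates.r_up_a - rates.r_over_a)


def specific_growth_rate(rates: RateTriple, B: float, B_tot: float, p: StrainParams) -> float:
    """Specific growth rate mu = r * B / B_tot - k_deg.

    ``B`` is the catalytic biomass, ``B_tot`` the total (catalytic + product)
    biomass; for a strain without product the two coincide. Undefined for
    ``B_tot = 0``.
    """
    if not B_tot > 0:
        raise ValueError("growth rate undefined for B_tot = 0")
    if not 0 <= B <= B_tot * (1 + 1e-12):
        raise ValueError("need 0 <= B <= B_tot")
    return biomass_specific_rate(rates, p) * B / B_tot - p.k_deg


def overflow_onset_dilution(p: StrainParams) -> float:
    """Dilution rate at which steady-state glucose uptake reaches the overflow threshold.

    D = (1 - Y_h) Y_g l - k_deg; below this D the producer secretes no
    acetate at steady state.
    """
    return (1.0 - p.Y_h) * p.Y_g * p.l - p.k_deg
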