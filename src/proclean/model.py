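"""Right-hand sides and Jacobian of the producer / producer-cleaner ODEs.

State vector x = (G, A, B_P, H, B_C): glucose, acetate, producer catalytic
biomass, heterologous protein, cleaner biomass (all in g L^-1 / gDW L^-1).
With the cleaner absent (B_C = 0, or ``cleaner=None``) the equations reduce
to the producer-only model. In fed-batch mode the glucose balance is removed
structurally (dG/dt = 0, D = 0) and glucose is held at its initial level by
an implied feed.
"""

from __future__ import annotations

import numpy as np

from .params import ReactorInputs, StrainParams
from .rates import RateTriple, biomass_specific_rate, rate_partials, strain_rates

__all__ = [
    "consortium_rhs",
    "consortium_jacobian",
    "growth_rates",
    "glucose_uptake_flux",
    "state_partition",
]

_ZERO = RateTriple(0.0, 0.0, 0.0)


def consortium_rhs(
    x: np.ndarray,
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
    branch: tuple[bool, bool] | None = None,
) -> np.ndarray:
    """Time derivative of (G, A, B_P, H, B_C).

    ``branch`` optionally forces the overflow branch of (producer, cleaner),
    selecting the smooth piece of the rate laws used by the piecewise
    steady-state analysis; by default the exact max(0, .) form is used.
    """
    G, A, B_P, H, B_C = x
    if min(G, A) < 0:
        # tiny undershoot is the integrator's business; rates need G, A >= 0
        G, A = max(G, 0.0), max(A, 0.0)
    rp = strain_rates(G, A, producer, overflow=None if branch is None else branch[0])
    if cleaner is not None:
        rc = strain_rates(G, A, cleaner, overflow=None if branch is None else branch[1])
    else:
        rc = _ZERO
        B_C = 0.0

    D = u.D
    r_P = biomass_specific_rate(rp, producer)
    dG = -rp.r_up_g * B_P - rc.r_up_g * B_C + D * (u.G_in - G)
    dA = (rp.r_over_a - rp.r_up_a) * B_P + (rc.r_over_a - rc.r_up_a) * B_C - D * A
    dB_P = (1.0 - producer.Y_h) * r_P * B_P - producer.k_deg * B_P - D * B_P
    dH = producer.Y_h * r_P * B_P - producer.k_deg * H - D * H
    if cleaner is not None:
        r_C = biomass_specific_rate(rc, cleaner)
        dB_C = r_C * B_C - cleaner.k_deg * B_C - D * B_C
    else:
        dB_C = 0.0
    if u.mode == "fedbatch":
        dG = 0.0
    return np.array([dG, dA, dB_P, dH, dB_C])


def consortium_jacobian(
    x: np.ndarray,
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
    branch: tuple[bool, bool] | None = None,
) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`consortium_rhs` w.r.t. the state.

    On the overflow kink the one-sided derivative of the state's own branch
    is used (or the branch forced by ``branch``).
    """
    G, A, B_P, H, B_C = np.maximum(x, 0.0)
    if cleaner is None:
        B_C = 0.0
    bp = None if branch is None else branch[0]
    bc = None if branch is None else branch[1]
    rp, rp_G, rp_A = rate_partials(G, A, producer, overflow=bp)
    if cleaner is not None:
        rc, rc_G, rc_A = rate_partials(G, A, cleaner, overflow=bc)
    else:
        rc = rc_G = rc_A = _ZERO

    D = u.D
    Yh = producer.Y_h
    J = np.zeros((5, 5))

    # dG/dt row (identically zero in fed-batch: glucose balance removed)
    if u.mode != "fedbatch":
        J[0, 0] = -rp_G.r_up_g * B_P - rc_G.r_up_g * B_C - D
        J[0, 1] = -rp_A.r_up_g * B_P - rc_A.r_up_g * B_C
        J[0, 2] = -rp.r_up_g
        J[0, 4] = -rc.r_up_g

    # dA/dt row
    J[1, 0] = (rp_G.r_over_a - rp_G.r_up_a) * B_P + (rc_G.r_over_a - rc_G.r_up_a) * B_C
    J[1, 1] = (rp_A.r_over_a - rp_A.r_up_a) * B_P + (rc_A.r_over_a - rc_A.r_up_a) * B_C - D
    J[1, 2] = rp.r_over_a - rp.r_up_a
    J[1, 4] = rc.r_over_a - rc.r_up_a

    r_P = biomass_specific_rate(rp, producer)
    r_P_G = producer.Y_g * rp_G.r_up_g + producer.Y_a * (rp_G.r_up_a - rp_G.r_over_a)
    r_P_A = producer.Y_g * rp_A.r_up_g + producer.Y_a * (rp_A.r_up_a - rp_A.r_over_a)

    # dB_P/dt row
    J[2, 0] = (1 - Yh) * r_P_G * B_P
    J[2, 1] = (1 - Yh) * r_P_A * B_P
    J[2, 2] = (1 - Yh) * r_P - producer.k_deg - D

    # dH/dt row
    J[3, 0] = Yh * r_P_G * B_P
    J[3, 1] = Yh * r_P_A * B_P
    J[3, 2] = Yh * r_P
    J[3, 3] = -producer.k_deg - D

    # dB_C/dt row
    if cleaner is not None:
        r_C = biomass_specific_rate(rc, cleaner)
        r_C_G = cleaner.Y_g * rc_G.r_up_g + cleaner.Y_a * (rc_G.r_up_a - rc_G.r_over_a)
        r_C_A = cleaner.Y_g * rc_A.r_up_g + cleaner.Y_a * (rc_A.r_up_a - rc_A.r_over_a)
        J[4, 0] = r_C_G * B_C
        J[4, 1] = r_C_A * B_C
        J[4, 4] = r_C - cleaner.k_deg - D
    return J


def growth_rates(
    x: np.ndarray,
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
) -> tuple[float, float]:
    """Population growth rates (mu_P, mu_C) at state x.

    mu_P is defined through the total producer biomass B_totP = B_P + H:
    d(B_totP)/dt = (mu_P - D) B_totP; mu_C analogously for the cleaner.
    Returns nan for an absent population (zero biomass).
    """
    G, A, B_P, H, B_C = x
    rp = strain_rates(max(G, 0.0), max(A, 0.0), producer)
    B_totP = B_P + H
    if B_totP > 0:
        mu_P = biomass_specific_rate(rp, producer) * B_P / B_totP - producer.k_deg
    else:
        mu_P = float("nan")
    if cleaner is not None and B_C > 0:
        rc = strain_rates(max(G, 0.0), max(A, 0.0), cleaner)
        mu_C = biomass_specific_rate(rc, cleaner) - cleaner.k_deg
    else:
        mu_C = float("nan")
    return mu_P, mu_C


def glucose_uptake_flux(
    x: np.ndarray,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
) -> float:
    """Total volumetric glucose uptake r_up_Pg B_P + r_up_Cg B_C [g L^-1 h^-1].

    In fed-batch this equals the implied feed rate that holds G constant.
    """
    G, A, B_P, H, B_C = x
    rp = strain_rates(max(G, 0.0), max(A, 0.0), producer)
    flux = rp.r_up_g * B_P
    if cleaner is not None:
        rc = strain_rates(max(G, 0.0), max(A, 0.0), cleaner)
        flux += rc.r_up_g * B_C
    return float(flux)


def state_partition(
    x: np.ndarray, producer: StrainParams, cleaner: StrainParams | None = None
) -> str:
    """Overflow partition X1..X4 containing the state.

    X1: neither strain overflows; X2: only the cleaner; X3: only the
    producer; X4: both. With the cleaner absent only X1/X3 occur.
    """
    G, A = max(x[0], 0.0), max(x[1], 0.0)
    over_p = strain_rates(G, A, producer).r_up_g > producer.l
    over_c = (
        strain_rates(G, A, cleaner).r_up_g > cleaner.l if cleaner is not None else False
    )
    return {
        (False, False): "X1",
        (False, True): "X2",
        (True, False): "X3",
        (True, True): "X4",
    }[(bool(over_p), bool(over_c))]
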