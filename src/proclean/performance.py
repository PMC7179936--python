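"""Productivity and process-yield analysis in chemostat and fed-batch.

Chemostat productivity is the steady-state product outflow D * H*
[g L^-1 h^-1]; the process yield is the product outflow per substrate inflow
(D H*) / (D G_in) = H*/G_in, which at steady state equals Y_h B_totP*/G_in.
In fed-batch the productivity index is the exponential-regime rate of
increase of H, and the yield is the instantaneous (dH/dt) per total glucose
uptake flux, constant in the exponential window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ReactorInputs, StrainParams
from .simulate import ExpRegimeStats
from .steady_state import DEFAULT_X0, SteadyStateResult, _solve_cell

__all__ = [
    "PerformancePoint",
    "ComparisonResult",
    "chemostat_performance",
    "performance_curve",
    "compare_consortium_vs_producer",
    "total_biomass_comparison",
    "fedbatch_performance",
    "cleaner_without_glucose_uptake_scenario",
]


@dataclass
class PerformancePoint:
    """Steady-state performance of one operating point."""

    D: float
    G_in: float
    productivity: float       # D * H* [g L^-1 h^-1]
    process_yield: float      # H*/G_in [-]; nan when G_in = 0
    B_totP: float
    B_C: float
    regime: str
    variant: str              # 'consortium' or 'producer_alone'


def chemostat_performance(
    res: SteadyStateResult, u: ReactorInputs, variant: str = "consortium"
) -> PerformancePoint:
    """Productivity D H* and process yield H*/G_in at a converged steady state."""
    if not res.converged:
        raise ValueError("performance undefined for a non-converged steady state")
    productivity = u.D * res.H
    process_yield = res.H / u.G_in if u.G_in > 0 else float("nan")
    return PerformancePoint(
        D=u.D,
        G_in=u.G_in,
        productivity=float(productivity),
        process_yield=float(process_yield),
        B_totP=float(res.B_totP),
        B_C=float(res.B_C),
        regime=res.regime,
        variant=variant,
    )


def _point(D, G_in, producer, cleaner, variant, **kw) -> PerformancePoint:
    res = _solve_cell(D, G_in, producer, cleaner, DEFAULT_X0, **kw)
    u = ReactorInputs(D=D, G_in=G_in, mode="chemostat")
    return chemostat_performance(res, u, variant)


def performance_curve(
    producer: StrainParams,
    cleaner: StrainParams | None,
    G_in: float,
    D_grid,
    variant: str | None = None,
    **kw,
) -> list[PerformancePoint]:
    if variant is None:
        variant = "consortium" if cleaner is not None else "producer_alone"
    return [_point(D, G_in, producer, cleaner, variant, **kw) for D in np.asarray(D_grid)]


def _golden_max(f, lo, hi, tol=1e-3):
    """Golden-section maximisation of a unimodal scalar function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = 0.5 * (a + b)
    return x, f(x)


def _refine_max(values, D_grid, f, tol=1e-3):
    i = int(np.argmax(values))
    lo = D_grid[max(i - 1, 0)]
    hi = D_grid[min(i + 1, len(D_grid) - 1)]
    if hi <= lo:
        return float(D_grid[i]), float(values[i])
    return _golden_max(f, lo, hi, tol=tol)


@dataclass
class ComparisonResult:
    """Paired performance curves and maxima for consortium vs producer alone."""

    consortium: list[PerformancePoint]
    producer_alone: list[PerformancePoint]
    summary: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.consortium + self.producer_alone])


def compare_consortium_vs_producer(
    producer: StrainParams,
    cleaner: StrainParams,
    G_in: float,
    D_grid,
    refine_tol: float = 1e-3,
    **kw,
) -> ComparisonResult:
    """Productivity/yield curves over D for the consortium and the lone producer.

    The producer-alone variant uses the identical producer parameters with the
    cleaner biomass fixed at zero. Grid maxima of productivity and yield are
    refined by golden-section search to ``refine_tol`` in D; the relative
    productivity gain of the consortium is reported in percent.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    curves = {
        "consortium": performance_curve(producer, cleaner, G_in, D_grid, **kw),
        "producer_alone": performance_curve(producer, None, G_in, D_grid, **kw),
    }
    summary = {}
    for variant, curve in curves.items():
        cl = cleaner if variant == "consortium" else None
        prod = np.array([p.productivity for p in curve])
        yld = np.array([p.process_yield for p in curve])
        D_prod, max_prod = _refine_max(
            prod, D_grid,
            lambda D: _point(D, G_in, producer, cl, variant, **kw).productivity,
            tol=refine_tol,
        )
        D_yld, max_yld = _refine_max(
            yld, D_grid,
            lambda D: _point(D, G_in, producer, cl, variant, **kw).process_yield,
            tol=refine_tol,
        )
        summary[variant] = dict(
            max_productivity=max_prod,
            argmax_productivity_D=D_prod,
            max_yield=max_yld,
            argmax_yield_D=D_yld,
        )
    mc = summary["consortium"]["max_productivity"]
    mp = summary["producer_alone"]["max_productivity"]
    summary["productivity_gain_percent"] = 100.0 * (mc - mp) / mp if mp > 0 else float("nan")
    return ComparisonResult(curves["consortium"], curves["producer_alone"], summary)


def total_biomass_comparison(
    producer: StrainParams,
    cleaner: StrainParams,
    G_in: float,
    D_grid,
    **kw,
) -> pd.DataFrame:
    """Total steady-state biomass (producer + product + cleaner) for both variants."""
    rows = []
    for D in np.asarray(D_grid, dtype=float):
        both = _solve_cell(D, G_in, producer, cleaner, DEFAULT_X0, **kw)
        alone = _solve_cell(D, G_in, producer, None, DEFAULT_X0, **kw)
        rows.append(
            dict(
                D=D,
                consortium_total=float(both.B_totP + both.B_C),
                producer_alone_total=float(alone.B_totP),
                regime=both.regime,
            )
        )
    return pd.DataFrame(rows)


def fedbatch_performance(
    consortium_stats: ExpRegimeStats, producer_stats: ExpRegimeStats
) -> dict:
    """Fed-batch productivity/yield trade-off summary at a common held glucose level."""
    return {
        "consortium": {
            "dlogH_plus": consortium_stats.dlogH_plus,
            "yield_plus": consortium_stats.yield_plus,
        },
        "producer_alone": {
            "dlogH_plus": producer_stats.dlogH_plus,
            "yield_plus": producer_stats.yield_plus,
        },
        "consortium_more_productive": consortium_stats.dlogH_plus > producer_stats.dlogH_plus,
        "producer_higher_yield": producer_stats.yield_plus > consortium_stats.yield_plus,
    }


def cleaner_without_glucose_uptake_scenario(
    producer: StrainParams,
    cleaner: StrainParams,
    G_in: float,
    D_grid,
    **kw,
) -> ComparisonResult:
    """Performance comparison with a hypothetical cleaner lacking residual glucose uptake."""
    return compare_consortium_vs_producer(
        producer, cleaner.replace(k_dPTS=0.0), G_in, D_grid, **kw
    )
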