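"""Steady states of the consortium in chemostat: computation, stability, regimes.

Two complementary routes are provided, mirroring each other as oracles:

* :func:`steady_state_by_integration` — long-horizon integration from a state
  with both biomasses present, accelerated by Newton polishing of the
  integration endpoint on the active (nonzero) components;
* :func:`steady_state_by_rootfinding` — direct enumeration of equilibrium
  candidates per overflow branch of the piecewise rate laws (the overflow
  term is zero or linear on each piece, partitioning the state space into
  X1..X4), split into washout / single-strain / interior coexistence
  families, each solved by multi-start damped Newton iteration and screened
  by the branch inequalities, nonnegativity and Jacobian stability.

Stability is strict: all eigenvalues of the Jacobian have negative real part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

from .model import consortium_jacobian, consortium_rhs, state_partition
from .params import ReactorInputs, StrainParams
from .rates import strain_rates

__all__ = [
    "SteadyStateResult",
    "PhaseDiagram",
    "classify_regime",
    "jacobian",
    "finite_difference_jacobian",
    "steady_state_by_integration",
    "steady_state_by_rootfinding",
    "sweep_dilution",
    "scan_phase_diagram",
    "coexistence_boundaries",
    "refine_transition",
]

DEFAULT_X0 = np.array([0.0, 0.0, 0.01, 0.0, 0.01])
PRESENCE_THRESHOLD = 1e-6  # gDW/L, biomass counted as present above this


@dataclass
class SteadyStateResult:
    """An equilibrium state with stability verdict and regime label."""

    state: np.ndarray
    u: ReactorInputs
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    regime: str
    partition: str
    converged: bool = True
    method: str = "integration"

    @property
    def G(self):
        return self.state[0]

    @property
    def A(self):
        return self.state[1]

    @property
    def B_P(self):
        return self.state[2]

    @property
    def H(self):
        return self.state[3]

    @property
    def B_C(self):
        return self.state[4]

    @property
    def B_totP(self):
        return self.state[2] + self.state[3]


def classify_regime(state: np.ndarray, presence_threshold: float = PRESENCE_THRESHOLD) -> str:
    """Label an equilibrium by which populations persist."""
    B_totP = state[2] + state[3]
    B_C = state[4]
    p = B_totP > presence_threshold
    c = B_C > presence_threshold
    if p and c:
        return "coexistence"
    if p:
        return "producer_only"
    if c:
        return "cleaner_only"
    return "washout"


def jacobian(
    x: np.ndarray,
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
    branch: tuple[bool, bool] | None = None,
) -> np.ndarray:
    """Analytic Jacobian of the ODE right-hand side at ``x``.

    Exactly on the overflow kink the one-sided derivative of the state's own
    partition is used and a warning is emitted.
    """
    if branch is None:
        for p in (producer, cleaner):
            if p is None:
                continue
            r = strain_rates(max(x[0], 0.0), max(x[1], 0.0), p).r_up_g
            if r == p.l:
                warnings.warn(
                    "state lies exactly on the overflow kink; using the "
                    "no-overflow one-sided derivative",
                    stacklevel=2,
                )
    return consortium_jacobian(x, u, producer, cleaner, branch=branch)


def finite_difference_jacobian(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian (test oracle for the analytic one)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    f0 = np.asarray(fun(x))
    J = np.zeros((f0.size, n))
    for j in range(n):
        step = h * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2 * step)
    return J


def _make_result(
    x: np.ndarray,
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None,
    converged: bool,
    method: str,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> SteadyStateResult:
    x = np.clip(x, 0.0, None)
    res = float(np.max(np.abs(consortium_rhs(x, u, producer, cleaner))))
    J = consortium_jacobian(x, u, producer, cleaner)
    eig = np.linalg.eigvals(J)
    return SteadyStateResult(
        state=x,
        u=u,
        residual=res,
        eigenvalues=eig,
        stable=bool(np.max(eig.real) < 0.0),
        regime=classify_regime(x, presence_threshold),
        partition=state_partition(x, producer, cleaner),
        converged=converged,
        method=method,
    )


def _polish(
    x: np.ndarray,
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None,
    tol: float,
    active_tol: float = 1e-7,
) -> np.ndarray | None:
    """Newton-polish an integration endpoint on its active components.

    Biomass components below ``active_tol`` are pinned at zero; G and A are
    always free. Returns the polished state, or None if the polish fails,
    leaves the nonnegative orthant, or lands on an unstable equilibrium.
    """
    free = [0, 1] + [i for i in (2, 3, 4) if x[i] > active_tol]
    if cleaner is None and 4 in free:
        free.remove(4)

    def assemble(z):
        xx = np.zeros(5)
        xx[free] = z
        return xx

    def fun(z):
        return consortium_rhs(np.clip(assemble(z), 0.0, None), u, producer, cleaner)[free]

    def jac(z):
        J = consortium_jacobian(np.clip(assemble(z), 0.0, None), u, producer, cleaner)
        return J[np.ix_(free, free)]

    sol = root(fun, x[free], method="hybr", jac=jac)
    if not sol.success:
        return None
    xs = assemble(sol.x)
    if np.min(xs) < -1e-12:
        return None
    xs = np.clip(xs, 0.0, None)
    # active biomasses must remain present, otherwise the active set was wrong
    if any(xs[i] <= 0 for i in free if i >= 2):
        return None
    if np.max(np.abs(consortium_rhs(xs, u, producer, cleaner))) > tol:
        return None
    eig = np.linalg.eigvals(consortium_jacobian(xs, u, producer, cleaner))
    if not np.max(eig.real) < 0.0:
        return None
    return xs


def steady_state_by_integration(
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
    x0: np.ndarray = DEFAULT_X0,
    horizon: float = 1e6,
    tol: float = 1e-9,
    polish: bool = True,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> SteadyStateResult:
    """Stable steady state reached from ``x0`` by long-horizon integration.

    Integrates in geometrically growing time chunks, checking the residual
    ||f(x)||_inf after each; with ``polish`` the endpoint of each chunk is
    refined by a Newton step on the active components (accepted only when it
    stays in the nonnegative orthant and is strictly stable), which shortcuts
    the slow terminal approach. Non-convergence within ``horizon`` yields a
    flagged (``converged=False``) result, not an exception.
    """
    if u.mode != "chemostat":
        raise ValueError("steady-state analysis is defined for chemostat mode")
    x = np.asarray(x0, dtype=float).copy()
    if cleaner is None:
        x[4] = 0.0  # the cleaner equation is absent from the producer-only model
    t_done = 0.0
    chunk = 200.0
    while t_done < horizon:
        t_next = min(t_done + chunk, horizon)
        sol = solve_ivp(
            lambda t, s: consortium_rhs(s, u, producer, cleaner),
            (t_done, t_next),
            x,
            method="BDF",
            jac=lambda t, s: consortium_jacobian(s, u, producer, cleaner),
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            return _make_result(x, u, producer, cleaner, False, "integration",
                                presence_threshold)
        x = np.clip(sol.y[:, -1], 0.0, None)
        t_done = t_next
        chunk *= 5.0
        if np.max(np.abs(consortium_rhs(x, u, producer, cleaner))) < tol:
            return _make_result(x, u, producer, cleaner, True, "integration",
                                presence_threshold)
        if polish:
            xs = _polish(x, u, producer, cleaner, tol)
            if xs is not None:
                return _make_result(xs, u, producer, cleaner, True,
                                    "integration+polish", presence_threshold)
    return _make_result(x, u, producer, cleaner, False, "integration", presence_threshold)


# ---------------------------------------------------------------------------
# root finding


def _branch_rates(G, A, p, over):
    return strain_rates(max(G, 0.0), max(A, 0.0), p, overflow=over)


def _balance(r, p, with_yh):
    r_spec = p.Y_g * r.r_up_g + p.Y_a * (r.r_up_a - r.r_over_a)
    if with_yh:
        r_spec *= 1.0 - p.Y_h
    return r_spec - p.k_deg


def _candidate_roots_family(
    u, producer, cleaner, family, branch, starts, xtol=1e-12
) -> list[np.ndarray]:
    """Solve one equilibrium family on one overflow branch from many starts.

    ``family`` is one of 'producer', 'cleaner', 'interior'; unknowns are the
    free components (G, A and the present biomasses), with H tied to B_P by
    the steady-state product ratio H = Y_h/(1-Y_h) B_P.
    """
    D, Gin = u.D, u.G_in
    Yh = producer.Y_h
    ratio = Yh / (1.0 - Yh)
    b_p, b_c = branch
    out = []

    def residuals(z):
        if family == "producer":
            G, A, BP = z
            BC = 0.0
        elif family == "cleaner":
            G, A, BC = z
            BP = 0.0
        else:
            G, A, BP, BC = z
        rp = _branch_rates(G, A, producer, b_p)
        eqs = [0.0, 0.0]
        eqs[0] = -rp.r_up_g * BP + D * (Gin - G)
        eqs[1] = (rp.r_over_a - rp.r_up_a) * BP - D * A
        if cleaner is not None and family != "producer":
            rc = _branch_rates(G, A, cleaner, b_c)
            eqs[0] -= rc.r_up_g * BC
            eqs[1] += (rc.r_over_a - rc.r_up_a) * BC
        if family != "cleaner":
            eqs.append(_balance(rp, producer, with_yh=True) - D)
        if family != "producer":
            rc = _branch_rates(G, A, cleaner, b_c)
            eqs.append(_balance(rc, cleaner, with_yh=False) - D)
        return np.array(eqs)

    for z0 in starts:
        sol = root(residuals, z0, method="hybr", options={"xtol": xtol})
        if not sol.success:
            continue
        z = sol.x
        if np.min(z) < -1e-10:
            continue
        z = np.clip(z, 0.0, None)
        if family == "producer":
            G, A, BP = z
            BC = 0.0
        elif family == "cleaner":
            G, A, BC = z
            BP = 0.0
        else:
            G, A, BP, BC = z
        if family != "cleaner" and BP <= 1e-9:
            continue  # collapsed onto a lower-dimensional family
        if family != "producer" and BC <= 1e-9:
            continue
        x = np.array([G, A, BP, ratio * BP, BC])
        # branch consistency: the defining rate inequality of each strain
        # present in this family must hold at the candidate
        if family != "cleaner" and (
            (strain_rates(G, A, producer).r_up_g > producer.l) != b_p
        ):
            continue
        if family != "producer" and (
            (strain_rates(G, A, cleaner).r_up_g > cleaner.l) != b_c
        ):
            continue
        out.append(x)
    return out


def steady_state_by_rootfinding(
    u: ReactorInputs,
    producer: StrainParams,
    cleaner: StrainParams | None = None,
    n_starts: int = 32,
    seed: int = 0,
    residual_tol: float = 1e-8,
    dedup_tol: float = 1e-6,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> list[SteadyStateResult]:
    """All equilibria found by the piecewise, family-wise root enumeration.

    Families: closed-form full washout; producer-only and cleaner-only
    (reduced 3-dimensional problems); interior coexistence (4 unknowns with
    H tied to B_P), each per overflow branch. Stability verdicts are kept for
    every retained root; the caller selects stable ones.
    """
    if u.mode != "chemostat":
        raise ValueError("steady-state analysis is defined for chemostat mode")
    D, Gin = u.D, u.G_in
    rng = np.random.default_rng(seed)
    Bmax = max(producer.Y_g * Gin, 1.0)

    candidates: list[np.ndarray] = [np.array([Gin, 0.0, 0.0, 0.0, 0.0])]

    if D > 0:
        # single-strain families, a handful of log-spaced starts per branch
        def lhs_starts(n, lows, highs):
            sampler = qmc.LatinHypercube(d=len(lows), seed=rng.integers(2**31))
            unit = sampler.random(n)
            lo = np.log(np.asarray(lows))
            hi = np.log(np.asarray(highs))
            return np.exp(lo + unit * (hi - lo))

        n_single = max(4, n_starts // 4)
        for b_p in (False, True):
            starts = lhs_starts(n_single, [1e-5, 1e-6, 1e-4], [max(Gin, 1e-4), 10.0, Bmax])
            candidates += _candidate_roots_family(
                u, producer, cleaner, "producer", (b_p, False), starts
            )
        if cleaner is not None:
            for b_c in (False, True):
                starts = lhs_starts(
                    n_single, [1e-5, 1e-6, 1e-4], [max(Gin, 1e-4), 10.0, Bmax]
                )
                candidates += _candidate_roots_family(
                    u, producer, cleaner, "cleaner", (False, b_c), starts
                )
            for b_p in (False, True):
                for b_c in (False, True):
                    starts = lhs_starts(
                        n_starts,
                        [1e-5, 1e-6, 1e-4, 1e-4],
                        [max(Gin, 1e-4), 10.0, Bmax, Bmax],
                    )
                    candidates += _candidate_roots_family(
                        u, producer, cleaner, "interior", (b_p, b_c), starts
                    )

    # dedupe and screen
    kept: list[np.ndarray] = []
    for x in candidates:
        if np.max(np.abs(consortium_rhs(x, u, producer, cleaner))) > residual_tol:
            continue
        if any(
            np.linalg.norm(x - y) <= dedup_tol * (1.0 + np.linalg.norm(y)) for y in kept
        ):
            continue
        kept.append(x)
    if not kept:
        raise RuntimeError("root enumeration returned no valid equilibrium")
    results = [
        _make_result(x, u, producer, cleaner, True, "rootfinding", presence_threshold)
        for x in kept
    ]
    results.sort(key=lambda r: (not r.stable, -r.B_totP))
    return results


# ---------------------------------------------------------------------------
# phase diagrams


@dataclass
class PhaseDiagram:
    """Per-cell stable steady states over a (D, G_in) grid."""

    D_grid: np.ndarray
    Gin_grid: np.ndarray
    results: list  # results[i][j] for D_grid[i], Gin_grid[j]
    flagged_cells: list = field(default_factory=list)  # multistability suspicions

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, D in enumerate(self.D_grid):
            for j, Gin in enumerate(self.Gin_grid):
                r = self.results[i][j]
                rows.append(
                    dict(
                        D=D,
                        G_in=Gin,
                        regime=r.regime,
                        G=r.G,
                        A=r.A,
                        B_P=r.B_P,
                        H=r.H,
                        B_C=r.B_C,
                        residual=r.residual,
                        converged=r.converged,
                    )
                )
        return pd.DataFrame(rows)


def _solve_cell(D, Gin, producer, cleaner, x0, **kw):
    u = ReactorInputs(D=D, G_in=Gin, mode="chemostat")
    return steady_state_by_integration(u, producer, cleaner, x0=x0, **kw)


def scan_phase_diagram(
    producer: StrainParams,
    cleaner: StrainParams | None,
    D_grid=None,
    Gin_grid=None,
    x0: np.ndarray = DEFAULT_X0,
    n_extra_inits: int = 0,
    seed: int = 0,
    uniqueness_rtol: float = 1e-5,
    **kw,
) -> PhaseDiagram:
    """Stable steady state per (D, G_in) cell, from positive initial biomasses.

    With ``n_extra_inits`` > 0 each cell is re-solved from that many random
    positive initial conditions; cells where the endpoints disagree beyond
    ``uniqueness_rtol`` are flagged loudly (the model's monotone rate laws
    predict a unique stable steady state).
    """
    D_grid = np.arange(0.0, 0.7 + 1e-12, 0.005) if D_grid is None else np.asarray(D_grid)
    Gin_grid = np.arange(0.0, 20.0 + 1e-12, 0.5) if Gin_grid is None else np.asarray(Gin_grid)
    rng = np.random.default_rng(seed)
    results, flagged = [], []
    for D in D_grid:
        row = []
        for Gin in Gin_grid:
            r = _solve_cell(D, Gin, producer, cleaner, x0, **kw)
            row.append(r)
            for _ in range(n_extra_inits):
                alt0 = np.array(
                    [
                        rng.uniform(0, max(Gin, 1e-3)),
                        rng.uniform(0, 1.0),
                        10 ** rng.uniform(-3, 0),
                        0.0,
                        10 ** rng.uniform(-3, 0) if cleaner is not None else 0.0,
                    ]
                )
                alt = _solve_cell(D, Gin, producer, cleaner, alt0, **kw)
                if not np.allclose(
                    alt.state, r.state, rtol=uniqueness_rtol, atol=1e-5
                ):
                    flagged.append((float(D), float(Gin), r.state.copy(), alt.state.copy()))
        results.append(row)
    if flagged:
        warnings.warn(
            f"possible multistability in {len(flagged)} cell(s): {[(c[0], c[1]) for c in flagged]}",
            stacklevel=2,
        )
    return PhaseDiagram(D_grid, Gin_grid, results, flagged)


def sweep_dilution(
    producer: StrainParams,
    cleaner: StrainParams | None,
    G_in: float,
    D_grid,
    x0: np.ndarray = DEFAULT_X0,
    **kw,
) -> list[SteadyStateResult]:
    """Stable steady states along a dilution-rate sweep at fixed G_in."""
    return [_solve_cell(D, G_in, producer, cleaner, x0, **kw) for D in np.asarray(D_grid)]


def refine_transition(
    producer: StrainParams,
    cleaner: StrainParams | None,
    G_in: float,
    D_lo: float,
    D_hi: float,
    predicate,
    tol: float = 1e-3,
    x0: np.ndarray = DEFAULT_X0,
    **kw,
) -> float:
    """Bisect a regime transition in D to ``tol``.

    ``predicate(result)`` must be True at ``D_lo`` and False at ``D_hi``;
    returns the midpoint of the final bracket.
    """
    while D_hi - D_lo > tol:
        mid = 0.5 * (D_lo + D_hi)
        if predicate(_solve_cell(mid, G_in, producer, cleaner, x0, **kw)):
            D_lo = mid
        else:
            D_hi = mid
    return 0.5 * (D_lo + D_hi)


def coexistence_boundaries(
    producer: StrainParams,
    cleaner: StrainParams,
    G_in: float = 20.0,
    D_grid=None,
    refine_tol: float = 1e-3,
    presence_threshold: float = PRESENCE_THRESHOLD,
    **kw,
) -> dict[str, float]:
    """Regime-boundary dilution rates along D at fixed G_in.

    Returns the coexistence band edges (``coexistence_lo``/``coexistence_hi``,
    i.e. cleaner invasion and cleaner washout), the onset of full washout
    (``washout_lo``), and the steady-state overflow onset
    (``overflow_onset`` from the closed-form yield relation), each refined by
    bisection to ``refine_tol``. Absent transitions are reported as nan.
    """
    from .rates import overflow_onset_dilution

    D_grid = np.arange(0.0, 0.7 + 1e-12, 0.005) if D_grid is None else np.asarray(D_grid)
    sweep = sweep_dilution(producer, cleaner, G_in, D_grid, **kw)
    has_cleaner = np.array([r.B_C > presence_threshold for r in sweep])
    washed = np.array([r.regime == "washout" for r in sweep])

    out = {
        "coexistence_lo": float("nan"),
        "coexistence_hi": float("nan"),
        "washout_lo": float("nan"),
        "overflow_onset": overflow_onset_dilution(producer),
    }
    idx = np.flatnonzero(has_cleaner)
    if idx.size:
        i0, i1 = idx[0], idx[-1]
        if i0 > 0:
            out["coexistence_lo"] = refine_transition(
                producer, cleaner, G_in, D_grid[i0 - 1], D_grid[i0],
                lambda r: not r.B_C > presence_threshold, tol=refine_tol, **kw,
            )
        else:
            out["coexistence_lo"] = float(D_grid[0])
        if i1 < len(D_grid) - 1:
            out["coexistence_hi"] = refine_transition(
                producer, cleaner, G_in, D_grid[i1], D_grid[i1 + 1],
                lambda r: r.B_C > presence_threshold, tol=refine_tol, **kw,
            )
        else:
            out["coexistence_hi"] = float(D_grid[-1])
    widx = np.flatnonzero(washed & (D_grid > 0))
    if widx.size:
        w0 = widx[0]
        out["washout_lo"] = refine_transition(
            producer, cleaner, G_in, D_grid[w0 - 1], D_grid[w0],
            lambda r: not r.regime == "washout", tol=refine_tol, **kw,
        )
    return out
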