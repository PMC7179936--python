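"""Two-step kinetic parameter estimation from exponential-growth rate data.

The calibration data are rate measurements taken during exponential growth in
batch of a wild-type strain (D = 0, Y_h = 0): the growth rate mu+, the
glucose uptake rate r_up_g+, and the net acetate exchange rate
(r_up_a - r_over_a)+ (negative = net secretion), under three condition
classes — glucose only, acetate only, and a glucose + acetate gradient.

Step 1 inverts the steady-exponential balance closed-form on the single-
substrate conditions to fix k_a, Y_a (acetate only: no overflow, CCR factor
one) and k_g, k_over, Y_g (glucose only: no acetate uptake, overflow
present). Step 2 estimates the regulatory constants (Theta_a, n, Theta_g, m)
on the mixed conditions by bound-constrained derivative-free least squares
pooled over the three observables. Identifiability is assessed by stratified
case-resampling bootstrap of step 2 with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .params import StrainParams
from .rates import strain_rates

__all__ = [
    "RateDataset",
    "FitResult",
    "predict_exponential_rates",
    "closed_form_estimates",
    "fit_inhibition_params",
    "goodness_of_fit",
    "bootstrap_identifiability",
    "kdeg_from_maintenance",
    "apply_uptake_mutation",
]

CONDITION_CLASSES = ("glucose_only", "acetate_only", "glucose_plus_acetate")
CSV_COLUMNS = ("condition", "G", "A", "mu_plus", "rupg_plus", "net_acetate_plus")
OBSERVABLES = ("mu_plus", "rupg_plus", "net_acetate_plus")

DEFAULT_BOUNDS = {
    "Theta_a": (1e-3, 10.0),
    "n": (0.5, 4.0),
    "Theta_g": (1e-3, 5.0),
    "m": (0.5, 4.0),
}


@dataclass
class RateDataset:
    """Tabular exponential-growth rate measurements for calibration."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"rate dataset missing columns: {missing}")
        bad = ~self.table["condition"].isin(CONDITION_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown condition class in rows {list(self.table.index[bad])}"
            )
        if (self.table[["G", "A"]] < 0).any().any():
            raise ValueError("concentrations must be >= 0")
        ac = self.table["condition"] == "acetate_only"
        if (self.table.loc[ac, "G"] != 0).any():
            raise ValueError("acetate_only records must have G = 0")
        gl = self.table["condition"] == "glucose_only"
        if (self.table.loc[gl, "A"] > 1e-6).any():
            raise ValueError("glucose_only records must have A ~ 0")

    def subset(self, condition: str) -> pd.DataFrame:
        return self.table[self.table["condition"] == condition]

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table[list(CSV_COLUMNS)].to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


def predict_exponential_rates(p: StrainParams, G, A):
    """Noise-free observables at ambient (G, A) during exponential batch growth.

    Returns (mu_plus, r_up_g_plus, net_acetate_plus) with
    mu+ = Y_g r_up_g + Y_a (r_up_a - r_over_a) - k_deg (wild type: no product,
    no dilution). Vectorized over G and A.
    """
    r = strain_rates(G, A, p)
    mu = p.Y_g * r.r_up_g + p.Y_a * (r.r_up_a - r.r_over_a) - p.k_deg
    return mu, r.r_up_g, r.r_up_a - r.r_over_a


@dataclass
class FitResult:
    """Estimated parameters with fit diagnostics."""

    params: StrainParams
    estimates: dict[str, float]
    fixed: dict[str, float]
    rss: float
    r2: dict[str, float]
    n_obs: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "fixed": self.fixed,
            "rss": self.rss,
            "r2": self.r2,
            "n_obs": self.n_obs,
            "flags": self.flags,
        }


def closed_form_estimates(
    data: RateDataset, fixed: dict[str, float]
) -> dict[str, float]:
    """Step 1: analytic inversion of the single-substrate exponential balances.

    ``fixed`` must provide K_g, K_a, l, k_deg (literature constants). From
    acetate-only records (G = 0, so no glucose uptake, no overflow, CCR
    factor = 1):

        k_a = r_up_a+ (A + K_a) / A,    Y_a = (mu+ + k_deg) / r_up_a+.

    From glucose-only records (A ~ 0, so no acetate inhibition or uptake;
    overflow must be present, r_up_g+ > l):

        k_g    = r_up_g+ (G + K_g) / G,
        k_over = -net_acetate+ / (r_up_g+ - l),
        Y_g    = (mu+ + k_deg - Y_a net_acetate+) / r_up_g+.

    Multiple records are averaged after per-record inversion.
    """
    for key in ("K_g", "K_a", "l", "k_deg"):
        if key not in fixed:
            raise ValueError(f"fixed parameter {key} is required")
    ace = data.subset("acetate_only")
    glc = data.subset("glucose_only")
    if len(ace) == 0:
        raise ValueError("no acetate_only records: k_a, Y_a not estimable")
    if len(glc) == 0:
        raise ValueError("no glucose_only records: k_g, k_over, Y_g not estimable")

    k_a_vals, Y_a_vals = [], []
    for idx, row in ace.iterrows():
        if row["A"] <= 0 or row["net_acetate_plus"] <= 0:
            raise ValueError(f"acetate_only record {idx}: needs A > 0 and net uptake > 0")
        rupa = row["net_acetate_plus"]  # no overflow at G = 0
        k_a_vals.append(rupa * (row["A"] + fixed["K_a"]) / row["A"])
        Y_a_vals.append((row["mu_plus"] + fixed["k_deg"]) / rupa)
    Y_a = float(np.mean(Y_a_vals))

    k_g_vals, k_over_vals, Y_g_vals = [], [], []
    for idx, row in glc.iterrows():
        if row["G"] <= 0:
            raise ValueError(f"glucose_only record {idx}: needs G > 0")
        rupg = row["rupg_plus"]
        if rupg <= fixed["l"]:
            raise ValueError(
                f"glucose_only record {idx}: r_up_g+ = {rupg} <= l = {fixed['l']}, "
                "overflow absent, k_over not estimable"
            )
        k_g_vals.append(rupg * (row["G"] + fixed["K_g"]) / row["G"])
        k_over_vals.append(-row["net_acetate_plus"] / (rupg - fixed["l"]))
        Y_g_vals.append(
            (row["mu_plus"] + fixed["k_deg"] - Y_a * row["net_acetate_plus"]) / rupg
        )
    return {
        "k_a": float(np.mean(k_a_vals)),
        "Y_a": Y_a,
        "k_g": float(np.mean(k_g_vals)),
        "k_over": float(np.mean(k_over_vals)),
        "Y_g": float(np.mean(Y_g_vals)),
    }


def _pooled_sse(theta: np.ndarray, base: StrainParams, G, A, observed: np.ndarray) -> float:
    p = base.replace(Theta_a=theta[0], n=theta[1], Theta_g=theta[2], m=theta[3])
    pred = np.column_stack(predict_exponential_rates(p, G, A))
    return float(np.sum((pred - observed) ** 2))


def fit_inhibition_params(
    data: RateDataset,
    base: StrainParams,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    xatol: float = 1e-10,
) -> FitResult:
    """Step 2: estimate (Theta_a, n, Theta_g, m) on the mixed-condition records.

    Minimizes the unweighted pooled sum of squared errors of the three
    observables with multi-start bound-constrained Nelder-Mead. Estimates
    pinned at a bound and optimizer non-convergence are flagged; a dataset
    whose mixed records all have A = 0 leaves the acetate-inhibition
    parameters structurally unidentifiable and is flagged as such.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    names = list(DEFAULT_BOUNDS)
    mix = data.subset("glucose_plus_acetate")
    if len(mix) == 0:
        raise ValueError("no glucose_plus_acetate records: step 2 has no data")
    flags = []
    if (mix["A"] <= 0).all():
        flags.append("unidentifiable: all mixed records have A = 0 (Theta_a, n free)")
    G = mix["G"].to_numpy(float)
    A = mix["A"].to_numpy(float)
    observed = mix[list(OBSERVABLES)].to_numpy(float)

    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    starts = [np.array([init[k] for k in names])] if init is not None else []
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    needed = max(0, n_starts - len(starts))
    starts += list(lo + sampler.random(needed) * (hi - lo))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            _pooled_sse,
            np.clip(x0, lo, hi),
            args=(base, G, A, observed),
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": xatol, "fatol": 1e-14, "maxiter": 4000},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        flags.append("optimizer did not report convergence from any start")
    theta = best.x
    for k, v, (a, b) in zip(names, theta, zip(lo, hi)):
        if min(v - a, b - v) < 1e-6 * (b - a):
            flags.append(f"estimate {k} = {v:.6g} pinned at bound [{a}, {b}]")

    fitted = base.replace(Theta_a=theta[0], n=theta[1], Theta_g=theta[2], m=theta[3])
    pred = np.column_stack(predict_exponential_rates(fitted, G, A))
    r2 = goodness_of_fit(
        {k: pred[:, i] for i, k in enumerate(OBSERVABLES)},
        {k: observed[:, i] for i, k in enumerate(OBSERVABLES)},
    )
    return FitResult(
        params=fitted,
        estimates=dict(zip(names, map(float, theta))),
        fixed={k: getattr(base, k) for k in ("k_g", "k_over", "k_a", "Y_g", "Y_a",
                                             "K_g", "K_a", "l", "k_deg")},
        rss=float(best.fun),
        r2=r2,
        n_obs=observed.size,
        flags=flags,
    )


def goodness_of_fit(predicted: dict, observed: dict) -> dict[str, float]:
    """Per-observable coefficient of determination R^2 = 1 - SS_res/SS_tot.

    SS_tot is taken about the observable's mean; an observable with zero
    variance has an undefined R^2, reported as nan.
    """
    out = {}
    for key, obs in observed.items():
        obs = np.asarray(obs, dtype=float)
        pred = np.asarray(predicted[key], dtype=float)
        if obs.shape != pred.shape:
            raise ValueError(f"observable {key}: prediction/observation shape mismatch")
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        if ss_tot == 0.0:
            out[key] = float("nan")
            continue
        out[key] = 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    return out


def bootstrap_identifiability(
    data: RateDataset,
    base: StrainParams,
    fit: FitResult,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    max_failure_fraction: float = 0.2,
) -> dict:
    """Percentile bootstrap confidence intervals for the step-2 estimates.

    Records are case-resampled with replacement, stratified by condition
    class, and the full two-step estimation is rerun per replicate: the
    closed-form step-1 inversion on the resampled single-substrate records
    (so step-1 estimation error propagates into the intervals), then step 2
    initialized at the point estimate. Deterministic under a fixed seed.
    Replicate fit failures are counted; more than ``max_failure_fraction``
    of failures raises.
    """
    rng = np.random.default_rng(seed)
    names = list(fit.estimates)
    fixed = {k: getattr(base, k) for k in ("K_g", "K_a", "l", "k_deg")}
    samples = []
    failures = 0
    for _ in range(n_boot):
        parts = []
        for cond in CONDITION_CLASSES:
            sub = data.subset(cond)
            if len(sub) == 0:
                continue
            parts.append(sub.sample(n=len(sub), replace=True,
                                    random_state=rng.integers(2**31)))
        boot = RateDataset(pd.concat(parts, ignore_index=True))
        try:
            step1 = closed_form_estimates(boot, fixed)
            res = fit_inhibition_params(
                boot, base.replace(**step1), init=fit.estimates, n_starts=1,
                seed=int(rng.integers(2**31)),
            )
            samples.append([res.estimates[k] for k in names])
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"bootstrap failed in {failures}/{n_boot} replicates"
        )
    samples = np.asarray(samples)
    alpha = 0.5 * (1.0 - level)
    ci = {
        k: (
            float(np.quantile(samples[:, i], alpha)),
            float(np.quantile(samples[:, i], 1.0 - alpha)),
        )
        for i, k in enumerate(names)
    }
    return {"ci": ci, "level": level, "n_boot": n_boot, "n_failures": failures,
            "samples": samples}


def kdeg_from_maintenance(C_m: float, Y_g: float) -> float:
    """Biomass degradation rate from the maintenance coefficient: k_deg = C_m Y_g."""
    if C_m < 0 or Y_g < 0:
        raise ValueError("C_m and Y_g must be >= 0")
    return C_m * Y_g


def apply_uptake_mutation(p: StrainParams, uptake_fraction: float) -> StrainParams:
    """Scale the maximal glucose uptake rate k_g by the mutant's uptake fraction.

    A glucose-uptake-system deletion reduces the uptake capacity; the
    observed relative decrease of uptake maps to the same proportional
    decrease of k_g (all other parameters unchanged).
    """
    if not 0.0 <= uptake_fraction <= 1.0:
        raise ValueError("uptake_fraction must lie in [0, 1]")
    return p.replace(k_g=p.k_g * uptake_fraction)
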