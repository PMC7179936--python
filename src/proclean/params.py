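"""Kinetic parameter sets and bioreactor control inputs.

Units are fixed package-wide: time in h, substrate and biomass concentrations
in g L^-1 and gDW L^-1, specific rates in g gDW^-1 h^-1. There is no unit
conversion layer.

The packaged default parameter file ``data/default_params.toml`` holds the calibrated
constants of the wild-type-derived producer strain together with the three
extra constants of the acetate-cleaner strain (reduced PTS-independent glucose
uptake ``k_dPTS``, overexpressed acetyl-CoA synthetase uptake ``k_Acs`` with
half-saturation ``K_Acs``).
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "StrainParams",
    "ReactorInputs",
    "load_config",
    "save_config",
    "default_config",
    "producer_params",
    "cleaner_params",
]

#: keys of the flat parameter config, in canonical order
CONFIG_KEYS = (
    "k_g", "K_g", "Theta_a", "n", "k_over", "l", "k_a", "K_a",
    "Theta_g", "m", "Y_g", "Y_a", "Y_h", "k_deg", "k_dPTS", "k_Acs", "K_Acs",
)


@dataclass(frozen=True)
class StrainParams:
    """Kinetic and yield constants of one strain (producer or cleaner variant).

    The cleaner variant (``is_cleaner=True``) replaces the maximal glucose
    uptake rate ``k_g`` by the residual rate ``k_dPTS`` in the glucose Monod
    term and adds an Acs-mediated acetate uptake term with constants
    ``k_Acs`` and ``K_Acs``; it carries no product (``Y_h = 0``).
    """

    k_g: float       # max glucose uptake rate [g gDW^-1 h^-1]
    K_g: float       # glucose half-saturation [g L^-1]
    Theta_a: float   # acetate growth-inhibition constant [g L^-1]
    n: float         # acetate-inhibition exponent [-]
    k_over: float    # overflow proportionality constant [-]
    l: float         # overflow threshold on glucose uptake [g gDW^-1 h^-1]
    k_a: float       # max acetate uptake rate [g gDW^-1 h^-1]
    K_a: float       # acetate half-saturation [g L^-1]
    Theta_g: float   # carbon-catabolite-repression constant [g gDW^-1 h^-1]
    m: float         # CCR exponent [-]
    Y_g: float       # glucose biomass yield [gDW g^-1]
    Y_a: float       # acetate biomass yield [gDW g^-1]
    Y_h: float       # product yield fraction [-]
    k_deg: float     # biomass degradation rate [h^-1]
    k_dPTS: float = 0.0   # residual glucose uptake rate (cleaner) [g gDW^-1 h^-1]
    k_Acs: float = 0.0    # Acs-mediated acetate uptake rate (cleaner) [g gDW^-1 h^-1]
    K_Acs: float = 1.0    # Acs half-saturation (cleaner) [g L^-1]
    is_cleaner: bool = False

    def __post_init__(self) -> None:
        for name in CONFIG_KEYS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.Y_h < 1.0:
            raise ValueError(f"Y_h must lie in [0, 1), got {self.Y_h}")
        if self.is_cleaner and self.Y_h != 0.0:
            raise ValueError("cleaner strain carries no heterologous product (Y_h must be 0)")

    @property
    def glucose_uptake_vmax(self) -> float:
        """Maximal glucose uptake rate of this variant (``k_dPTS`` for cleaner)."""
        return self.k_dPTS if self.is_cleaner else self.k_g

    def replace(self, **changes) -> "StrainParams":
        return dataclasses.replace(self, **changes)

    def as_config_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in CONFIG_KEYS}


@dataclass(frozen=True)
class ReactorInputs:
    """Bioreactor control inputs.

    Modes: ``batch`` (D = 0, no feed), ``chemostat`` (constant dilution D and
    inflow glucose G_in), ``fedbatch`` (no outflow, D = 0; the reactor glucose
    level is structurally held at ``G_held`` by an implied time-varying feed).
    """

    D: float = 0.0
    G_in: float = 0.0
    mode: str = "batch"
    G_held: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "chemostat", "fedbatch"):
            raise ValueError(f"unknown reactor mode {self.mode!r}")
        if self.D < 0 or self.G_in < 0:
            raise ValueError("D and G_in must be >= 0")
        if self.mode == "batch" and self.D != 0.0:
            raise ValueError("batch mode requires D = 0")
        if self.mode == "fedbatch":
            if self.D != 0.0:
                raise ValueError("fed-batch mode requires D = 0")
            if not self.G_held > 0.0:
                raise ValueError("fed-batch mode requires G_held > 0")


def load_config(path: str | Path) -> dict[str, float]:
    """Read a flat TOML parameter file into a key -> value dict."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    missing = [k for k in CONFIG_KEYS if k not in raw]
    if missing:
        raise ValueError(f"parameter file {path} is missing keys: {missing}")
    return {k: float(raw[k]) for k in CONFIG_KEYS}


def save_config(config: dict[str, float], path: str | Path) -> None:
    """Write a flat key = value TOML parameter file."""
    lines = [f"{k} = {float(config[k])!r}" for k in CONFIG_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def default_config() -> dict[str, float]:
    """The packaged default (calibrated) parameter set."""
    src = resources.files("proclean").joinpath("data/default_params.toml")
    raw = tomllib.loads(src.read_text())
    return {k: float(raw[k]) for k in CONFIG_KEYS}


def producer_params(config: dict[str, float] | None = None, Y_h: float | None = None) -> StrainParams:
    """Producer-strain parameters from a config dict (default: packaged set).

    ``Y_h`` overrides the product yield fraction; the wild type corresponds
    to ``Y_h = 0``.
    """
    cfg = dict(default_config() if config is None else config)
    if Y_h is not None:
        cfg["Y_h"] = Y_h
    cfg["k_dPTS"] = 0.0
    cfg["k_Acs"] = 0.0
    cfg.setdefault("K_Acs", 1.0)
    return StrainParams(**cfg, is_cleaner=False)


def cleaner_params(config: dict[str, float] | None = None) -> StrainParams:
    cfg = dict(default_config() if config is None else config)
    cfg["Y_h"] = 0.0
    p = StrainParams(**cfg, is_cleaner=True)
    # sanity of the engineered design: weakened glucose uptake, boosted acetate uptake
    if not (p.k_dPTS < p.k_g and p.k_Acs > p.k_a):
        raise ValueError("cleaner design requires k_dPTS < k_g and k_Acs > k_a")
    return p
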