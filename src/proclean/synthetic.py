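"""Synthetic calibration datasets with the structure of the batch rate data.

The generator emulates exponential-growth rate measurements in the three
condition classes used for calibration — glucose only, acetate only, and a
fixed-glucose acetate gradient — by evaluating the noise-free rate laws and
applying independent multiplicative lognormal noise of a given coefficient
of variation. Noise factors are mean-one and sign-preserving (applied to the
magnitude of the observable, so a net-secretion value stays a secretion).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CSV_COLUMNS, RateDataset, predict_exponential_rates
from .params import StrainParams

__all__ = ["DataDesign", "generate_rate_dataset", "default_calibration_design"]


@dataclass
class DataDesign:
    """Experimental design of a synthetic rate dataset.

    Condition classes: ``glucose_only_levels`` [g/L] with no acetate,
    ``acetate_only_levels`` [g/L] with no glucose, and a mixed gradient of
    ``mixed_acetate_levels`` at fixed ``mixed_G``. ``noise_cv`` is the
    multiplicative coefficient of variation of every observable.
    """

    glucose_only_levels: tuple = (2.7,)
    acetate_only_levels: tuple = (0.5, 1.0, 2.0, 4.0)
    mixed_G: float = 2.7
    mixed_acetate_levels: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = (
            list(self.glucose_only_levels)
            + list(self.acetate_only_levels)
            + [self.mixed_G]
            + list(self.mixed_acetate_levels)
        )
        if any(v < 0 for v in levels):
            raise ValueError("all concentration levels must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def conditions(self):
        for G in self.glucose_only_levels:
            yield "glucose_only", float(G), 0.0
        for A in self.acetate_only_levels:
            yield "acetate_only", 0.0, float(A)
        for A in self.mixed_acetate_levels:
            yield "glucose_plus_acetate", float(self.mixed_G), float(A)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def generate_rate_dataset(true_params: StrainParams, design: DataDesign) -> RateDataset:
    """Simulate a rate dataset from known parameters under the given design.

    With ``noise_cv = 0`` the observables equal the model predictions
    exactly; otherwise each observable is multiplied by an independent
    mean-one lognormal factor with the design's CV (single RNG stream seeded
    by ``design.seed``, so the dataset is reproducible).
    """
    rng = np.random.default_rng(design.seed)
    cv = design.noise_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    rows = []
    for cond, G, A in design.conditions():
        mu, rupg, net = predict_exponential_rates(true_params, G, A)
        for _ in range(design.replicates):
            obs = np.array([mu, rupg, net], dtype=float)
            if cv > 0:
                factors = np.exp(sigma * rng.standard_normal(3) - 0.5 * sigma * sigma)
                obs = np.sign(obs) * np.abs(obs) * factors
            rows.append(dict(zip(CSV_COLUMNS, (cond, G, A, *obs))))
    return RateDataset(pd.DataFrame(rows))


def default_calibration_design(
    replicates: int = 3, noise_cv: float = 0.05, seed: int = 0
) -> DataDesign:
    """The stable default design mirroring the calibration data's structure.

    One saturating glucose-only condition (overflow present), an acetate
    gradient as sole carbon source, and an acetate gradient added to fixed
    glucose. The 5% noise CV is a modelling choice for typical relative
    measurement error of physiological rate data.
    """
    return DataDesign(replicates=replicates, noise_cv=noise_cv, seed=seed)
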