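"""Synthetic steady-state measurement generator with known ground truth.

The raw per-concentration oligomer measurements exist only as published
figures, so end-to-end validation of the fitting pipeline uses
simulated datasets: the model curve is evaluated on the experimental
concentration grid (1–250 nM, nine log-ish spaced points, three
replicates per point) and perturbed with multiplicative lognormal noise.
Relative error dominates at these oligomer concentrations and the noise
must never produce negative concentrations, which is why the lognormal
is the default; the sample-to-sample coefficient of variation defaults
to 0.35, consistent with the large error bars of the single-molecule
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cooligomer import MixedSystemParams
from .datasets import MeasurementDataset
from .exceptions import InvalidParameterError
from .inference import model_curve
from .observation import CROSS, SELF_MIXED, LabelScheme
from .thermo import SelfSystemParams, ThermoContext

__all__ = [
    "NoiseModel",
    "DEFAULT_GRID",
    "generate_self_dataset",
    "generate_mixed_dataset",
]

NM = 1e-9
# the experimental range 1-250 nM, 9 roughly log-spaced points
DEFAULT_GRID = tuple(c * NM for c in (1, 5, 10, 25, 50, 100, 150, 200, 250))


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise with a detection floor."""

    kind: str = "lognormal"
    cv: float = 0.35
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "lognormal":
            raise InvalidParameterError(f"unsupported noise kind {self.kind!r}")
        if self.cv < 0:
            raise InvalidParameterError("cv must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb with unit-mean lognormal factors of the configured CV."""
        if self.cv == 0:
            noisy = np.asarray(values, float).copy()
        else:
            sigma2 = math.log1p(self.cv**2)
            factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=values.shape)
            noisy = values * factors
        return np.maximum(noisy, self.floor)


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid > 1e-6):
        raise InvalidParameterError("grid must lie within (0, 1 uM]")
    return grid


def _generate(system, truth, ctx, grid, n_rep, noise, scheme) -> MeasurementDataset:
    grid = _check_grid(grid)
    if n_rep < 1:
        raise InvalidParameterError("n_rep must be >= 1")
    curve = model_curve(truth, grid, scheme, ctx)
    rng = np.random.default_rng(noise.seed)
    totals, observed, replicates = [], [], []
    for rep in range(1, n_rep + 1):
        totals.append(grid)
        observed.append(noise.apply(curve, rng))
        replicates.extend([f"rep{rep}"] * len(grid))
    return MeasurementDataset.from_arrays(
        system=system,
        total_conc=np.concatenate(totals),
        oligomer_conc=np.concatenate(observed),
        replicate=replicates,
        label_scheme=scheme,
    )


def generate_self_dataset(
    truth: SelfSystemParams,
    ctx: ThermoContext | None = None,
    grid=DEFAULT_GRID,
    n_rep: int = 3,
    noise: NoiseModel | None = None,
    scheme: LabelScheme | None = None,
    system: str = "self_A",
) -> MeasurementDataset:
    """Simulate one isoform's replicated oligomer-vs-total curve."""
    ctx = ctx or ThermoContext()
    noise = noise or NoiseModel()
    scheme = scheme or LabelScheme(mode=SELF_MIXED)
    if scheme.mode != SELF_MIXED:
        raise InvalidParameterError("self datasets use the self_mixed_colours scheme")
    return _generate(system, truth, ctx, grid, n_rep, noise, scheme)


def generate_mixed_dataset(
    truth: MixedSystemParams,
    ctx: ThermoContext | None = None,
    grid=DEFAULT_GRID,
    n_rep: int = 3,
    noise: NoiseModel | None = None,
    scheme: LabelScheme | None = None,
) -> MeasurementDataset:
    """Simulate the 1:1 mixed experiment (heterodimer observations only)."""
    ctx = ctx or ThermoContext()
    noise = noise or NoiseModel()
    scheme = scheme or LabelScheme(mode=CROSS)
    if scheme.mode != CROSS:
        raise InvalidParameterError("mixed datasets use the cross_colour scheme")
    return _generate("mixed", truth, ctx, grid, n_rep, noise, scheme)
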