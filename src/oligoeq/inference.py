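"""Fitting the equilibrium model to steady-state oligomer measurements.

Two estimators, written to the scikit-learn contract (``fit`` /
``predict``, ``get_params`` / ``set_params``, trailing-underscore fitted
attributes), cover the two experiment types:

- :class:`SelfOligomerFit` — one isoform, mixed-colour labelling; fits
  the oligomer free energy ΔG°(oligo) and the fibril CAC to the
  grow-then-plateau curve of observed oligomer concentration vs total
  peptide concentration.
- :class:`MixedDimerFit` — 1:1 two-isoform mixture, cross-colour
  labelling (only the heterodimer is detected); fits the single
  heterodimer bond free energy ΔG°(AB) with both self free energies held
  fixed.

X is the total initial monomer concentration (molar, shape ``(n,)`` or
``(n, 1)``), y the observed (coincidence-detected) oligomer
concentration in molar.  Objectives are unweighted least squares on
nanomolar concentrations; a 1/SD² weighting over replicates is
available.  Optimisation is deterministic, derivative-free and
multi-start, so results are reproducible bit-for-bit.

Uncertainties come from a case-resampling bootstrap over replicates
within each concentration (the experiments have N = 3 samples per
concentration), reported as percentile intervals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .cooligomer import MixedSystemParams, solve_two_species
from .datasets import MeasurementDataset
from .exceptions import FitError, InvalidParameterError
from .observation import (
    CROSS,
    SELF_MIXED,
    LabelScheme,
    observed_oligomer_concentration,
)
from .thermo import (
    SelfSystemParams,
    ThermoContext,
    equilibrium_constant,
    solve_free_monomer,
)

__all__ = [
    "FitResult",
    "SelfOligomerFit",
    "MixedDimerFit",
    "model_curve",
    "fit_self_system",
    "fit_mixed_dG",
    "bootstrap_ci",
    "estimate_plateau_onset",
    "NO_PLATEAU",
]

NM = 1e-9
NO_PLATEAU = math.inf  # sentinel: no plateau detectable within the grid


@dataclass
class FitResult:
    """Point estimates, intervals and provenance of one model fit."""

    system: str
    params: dict[str, float]
    residual_summary: float
    confidence_intervals: dict[str, tuple[float, float]] | None = None
    ci_level: float | None = None
    n_boot: int = 0
    seed: int | None = None
    flags: list[str] = dc_field(default_factory=list)
    settings: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "system": self.system,
            "params": self.params,
            "residual_summary": self.residual_summary,
            "confidence_intervals": self.confidence_intervals,
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "flags": self.flags,
            "settings": self.settings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def model_curve(
    params: SelfSystemParams | MixedSystemParams,
    total_conc_grid,
    scheme: LabelScheme | None = None,
    ctx: ThermoContext | None = None,
    *,
    observed_space: str = "coincident",
    mix_fraction_B: float = 0.5,
) -> np.ndarray:
    """Predicted observed oligomer concentration over a total-conc grid.

    Pure composition of the equilibrium solvers and the observation
    filter — no additional physics.  ``observed_space`` selects whether
    the curve is passed through the coincidence filter (``"coincident"``,
    what TCCD reports) or left as the true particle concentration
    (``"true"``).  For mixed systems the two spaces coincide because the
    heterodimer always carries both colours.
    """
    ctx = ctx or ThermoContext()
    grid = np.atleast_1d(np.asarray(total_conc_grid, dtype=float))
    if np.any(grid < 0):
        raise InvalidParameterError("total concentrations must be non-negative")
    if observed_space not in ("coincident", "true"):
        raise InvalidParameterError(f"unknown observed_space {observed_space!r}")
    out = np.empty_like(grid)
    if isinstance(params, SelfSystemParams):
        scheme = scheme or LabelScheme(mode=SELF_MIXED)
        # vectorised closed forms (identical algebra to solve_self_equilibrium
        # + observed_oligomer_concentration, which the tests cross-check)
        K = equilibrium_constant(params.dG_oligo, ctx)
        t_eff = grid if params.cac_fib is None else np.minimum(grid, params.cac_fib)
        m = solve_free_monomer(t_eff, params.dG_oligo, ctx)
        x = K * m
        if observed_space == "true":
            out = K * m * m / (1.0 - x)
        else:
            p = scheme.blue_fraction
            out = (
                x * x / (1.0 - x)
                - (p * x) ** 2 / (1.0 - p * x)
                - ((1.0 - p) * x) ** 2 / (1.0 - (1.0 - p) * x)
            ) / K
    elif isinstance(params, MixedSystemParams):
        scheme = scheme or LabelScheme(mode=CROSS)
        if scheme.mode != CROSS:
            raise InvalidParameterError("mixed curves require the cross_colour scheme")
        for i, total in enumerate(grid):
            state = solve_two_species(
                total * (1.0 - mix_fraction_B), total * mix_fraction_B, params, ctx
            )
            out[i] = observed_oligomer_concentration(state, scheme)
    else:
        raise InvalidParameterError(f"unsupported params type {type(params).__name__}")
    return out


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise InvalidParameterError("X must have a single concentration column")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    if X.shape != y.shape or X.ndim != 1:
        raise InvalidParameterError("X and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("X and y must be finite")
    if np.any(X < 0) or np.any(y < 0):
        raise InvalidParameterError("concentrations must be non-negative")
    if len(np.unique(X)) < 3:
        raise InvalidParameterError("need >= 3 distinct total concentrations")
    return X, y


class SelfOligomerFit(BaseEstimator, RegressorMixin):
    """Least-squares fit of (ΔG°(oligo), fibril CAC) to one isoform's curve.

    Parameters
    ----------
    temperature : float
        Kelvin; enters through ΔG° = RT ln(CAC/c0).
    observed_space : {"coincident", "true"}
        Whether y is the raw TCCD (two-colour-coincident) concentration
        or an already-corrected true particle concentration.
    blue_fraction : float
        Blue-label probability of the mixed-colour scheme (0.5 for 1:1).
    dG_bounds, cac_fib_bounds_nM : tuple
        Search box; the CAC is optimised on a log scale.
    n_starts : int
        Starting grid is ``n_starts x n_starts`` over the box; the best
        converged optimum is kept (ties broken by lower ΔG°).

    Attributes
    ----------
    dG_oligo_ : float
        Fitted oligomer free energy, kJ/mol.
    cac_fib_ : float
        Fitted fibril critical aggregation concentration, molar.
    residual_ : float
        Sum of squared residuals in nM².
    result_ : FitResult
    """

    def __init__(
        self,
        temperature: float = 310.15,
        observed_space: str = "coincident",
        blue_fraction: float = 0.5,
        dG_bounds: tuple = (-45.0, -25.0),
        cac_fib_bounds_nM: tuple = (10.0, 1000.0),
        n_starts: int = 5,
        label: str = "self_A",
    ):
        self.temperature = temperature
        self.observed_space = observed_space
        self.blue_fraction = blue_fraction
        self.dG_bounds = dG_bounds
        self.cac_fib_bounds_nM = cac_fib_bounds_nM
        self.n_starts = n_starts
        self.label = label

    def _ctx(self) -> ThermoContext:
        return ThermoContext(temperature=self.temperature)

    def _scheme(self) -> LabelScheme:
        return LabelScheme(mode=SELF_MIXED, blue_fraction=self.blue_fraction)

    def _objective(self, theta, X, y_nM, w):
        dG, log_cac = theta
        params = SelfSystemParams(
            label=self.label, dG_oligo=dG, cac_fib=10.0**log_cac * NM
        )
        pred = model_curve(
            params, X, self._scheme(), self._ctx(), observed_space=self.observed_space
        )
        r = pred / NM - y_nM
        return float(np.sum(w * r * r))

    def fit(self, X, y, sample_weight=None):
        X, y = _validate_xy(X, y)
        if np.all(y == 0):
            raise FitError("all observed oligomer concentrations are zero")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        if w.shape != y.shape or np.any(w < 0):
            raise InvalidParameterError("sample_weight must be non-negative, same length as y")
        y_nM = y / NM

        dG_lo, dG_hi = self.dG_bounds
        lc_lo, lc_hi = (math.log10(b) for b in self.cac_fib_bounds_nM)
        bounds = [(dG_lo, dG_hi), (lc_lo, lc_hi)]
        starts = [
            (dg, lc)
            for dg in np.linspace(dG_lo, dG_hi, self.n_starts)
            for lc in np.linspace(lc_lo, lc_hi, self.n_starts)
        ]
        # a data-driven start from the plateau-onset changepoint, when available
        onset = _plateau_onset_from_arrays(X, y)
        if np.isfinite(onset):
            starts.append(((dG_lo + dG_hi) / 2, np.clip(math.log10(onset / NM), lc_lo, lc_hi)))

        best = None
        for x0 in starts:
            res = optimize.minimize(
                self._objective,
                x0=np.asarray(x0),
                args=(X, y_nM, w),
                method="Powell",
                bounds=bounds,
                options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 2000},
            )
            key = (res.fun, res.x[0])  # ties broken by lowest dG
            if best is None or key < (best.fun, best.x[0]):
                best = res

        self.dG_oligo_ = float(best.x[0])
        self.cac_fib_ = float(10.0 ** best.x[1] * NM)
        self.residual_ = float(best.fun)
        self.n_features_in_ = 1
        flags = []
        for val, (lo, hi), name in [
            (best.x[0], bounds[0], "dG_oligo"),
            (best.x[1], bounds[1], "log10_cac_fib_nM"),
        ]:
            if abs(val - lo) < 1e-6 * (hi - lo) or abs(val - hi) < 1e-6 * (hi - lo):
                flags.append(f"{name}_at_bound")
        if not np.isfinite(onset):
            flags.append("no_plateau_in_range")
        self.flags_ = flags
        self.result_ = FitResult(
            system=self.label,
            params={"dG_oligo_kJ_mol": self.dG_oligo_, "cac_fib_nM": self.cac_fib_ / NM},
            residual_summary=self.residual_,
            flags=flags,
            settings=self.get_params(),
        )
        return self

    def params_(self) -> SelfSystemParams:
        return SelfSystemParams(label=self.label, dG_oligo=self.dG_oligo_, cac_fib=self.cac_fib_)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        shape1d = X[:, 0] if X.ndim == 2 else X
        return model_curve(
            self.params_(), shape1d, self._scheme(), self._ctx(),
            observed_space=self.observed_space,
        )


class MixedDimerFit(BaseEstimator, RegressorMixin):
    """1-D least-squares fit of the heterodimer bond free energy ΔG°(AB).

    The self free energies (and optional fibril CACs) are held fixed at
    independently fitted values; X is the total peptide concentration of
    the 1:1 mixture and y the observed heterodimer concentration.
    """

    def __init__(
        self,
        dG_AA: float = -36.3,
        dG_BB: float = -36.3,
        temperature: float = 310.15,
        hetero_degeneracy: int = 2,
        mix_fraction_B: float = 0.5,
        dG_AB_bounds: tuple = (-45.0, -20.0),
        cac_fib_A: float | None = None,
        cac_fib_B: float | None = None,
    ):
        self.dG_AA = dG_AA
        self.dG_BB = dG_BB
        self.temperature = temperature
        self.hetero_degeneracy = hetero_degeneracy
        self.mix_fraction_B = mix_fraction_B
        self.dG_AB_bounds = dG_AB_bounds
        self.cac_fib_A = cac_fib_A
        self.cac_fib_B = cac_fib_B

    def _ctx(self) -> ThermoContext:
        return ThermoContext(temperature=self.temperature)

    def _params(self, dG_AB: float) -> MixedSystemParams:
        return MixedSystemParams(
            dG_AA=self.dG_AA,
            dG_BB=self.dG_BB,
            dG_AB=dG_AB,
            cac_fib_A=self.cac_fib_A,
            cac_fib_B=self.cac_fib_B,
            hetero_degeneracy=self.hetero_degeneracy,
        )

    def fit(self, X, y, sample_weight=None):
        X, y = _validate_xy(X, y)
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        y_nM = y / NM

        def objective(dG_AB):
            pred = model_curve(
                self._params(dG_AB), X, ctx=self._ctx(),
                mix_fraction_B=self.mix_fraction_B,
            )
            r = pred / NM - y_nM
            return float(np.sum(w * r * r))

        lo, hi = self.dG_AB_bounds
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        self.dG_AB_ = float(res.x)
        self.residual_ = float(res.fun)
        self.n_features_in_ = 1
        flags = []
        if abs(self.dG_AB_ - hi) < 1e-4 * (hi - lo):
            flags.append("dG_AB_at_upper_bound")
        if abs(self.dG_AB_ - lo) < 1e-4 * (hi - lo):
            flags.append("dG_AB_at_lower_bound")
        self.flags_ = flags
        self.result_ = FitResult(
            system="mixed",
            params={"dG_AB_kJ_mol": self.dG_AB_},
            residual_summary=self.residual_,
            flags=flags,
            settings=self.get_params(),
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        shape1d = X[:, 0] if X.ndim == 2 else X
        return model_curve(
            self._params(self.dG_AB_), shape1d, ctx=self._ctx(),
            mix_fraction_B=self.mix_fraction_B,
        )


# ---------------------------------------------------------------------------
# dataset-level wrappers


def _dataset_arrays(data: MeasurementDataset):
    df = data.to_frame()
    return df["total_conc"].to_numpy(), df["oligomer_conc"].to_numpy(), df["replicate"]


def _replicate_weights(data: MeasurementDataset) -> np.ndarray:
    """1/SD² weights per concentration, from replicate spread."""
    df = data.to_frame()
    sd = df.groupby("total_conc")["oligomer_conc"].transform("std").to_numpy()
    sd_nM = sd / NM
    positive = sd_nM[sd_nM > 0]
    fallback = positive.min() if len(positive) else 1.0
    sd_nM = np.where(sd_nM > 0, sd_nM, fallback)
    return 1.0 / sd_nM**2


def fit_self_system(
    data: MeasurementDataset,
    ctx: ThermoContext | None = None,
    init: SelfSystemParams | None = None,
    bounds: dict | None = None,
    *,
    observed_space: str = "coincident",
    weighted: bool = False,
    n_boot: int = 0,
    seed: int = 0,
    level: float = 0.68,
) -> FitResult:
    """Fit ΔG°(oligo) and the fibril CAC to one self-aggregation dataset."""
    if data.system not in ("self_A", "self_B"):
        raise InvalidParameterError(f"expected a self system, got {data.system!r}")
    ctx = ctx or ThermoContext()
    kwargs = dict(
        temperature=ctx.temperature,
        observed_space=observed_space,
        blue_fraction=data.label_scheme.blue_fraction,
        label=data.system,
    )
    if bounds:
        kwargs.update(bounds)
    est = SelfOligomerFit(**kwargs)
    X, y, _ = _dataset_arrays(data)
    w = _replicate_weights(data) if weighted else None
    est.fit(X, y, sample_weight=w)
    result = est.result_
    if init is not None:
        # refine from the caller-supplied start; keep whichever is better
        refined = optimize.minimize(
            est._objective,
            x0=np.array([init.dG_oligo, math.log10((init.cac_fib or 222e-9) / NM)]),
            args=(X, y / NM, np.ones_like(y) if w is None else w),
            method="Powell",
            bounds=[est.dG_bounds, tuple(math.log10(b) for b in est.cac_fib_bounds_nM)],
            options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 2000},
        )
        if refined.fun < result.residual_summary:
            result.params = {
                "dG_oligo_kJ_mol": float(refined.x[0]),
                "cac_fib_nM": float(10.0 ** refined.x[1]),
            }
            result.residual_summary = float(refined.fun)
    if n_boot:
        refit = lambda ds: fit_self_system(
            ds, ctx, observed_space=observed_space, weighted=weighted
        )
        result.confidence_intervals = bootstrap_ci(data, refit, n_boot, level, seed)
        result.ci_level = level
        result.n_boot = n_boot
        result.seed = seed
    return result


def fit_mixed_dG(
    data: MeasurementDataset,
    fixed_self: tuple[SelfSystemParams, SelfSystemParams],
    ctx: ThermoContext | None = None,
    *,
    weighted: bool = False,
    use_fibril_caps: bool = False,
    n_boot: int = 0,
    seed: int = 0,
    level: float = 0.68,
) -> FitResult:
    """Fit ΔG°(AB) to the 1:1 mixed dataset with self parameters fixed.

    Fibril caps are off by default: the mixed series shows no plateau,
    consistent with both isoforms staying below their CACs in the 1:1
    mixture; ``use_fibril_caps`` enables the per-isoform caps taken from
    ``fixed_self`` for extrapolation studies.
    """
    if data.system != "mixed":
        raise InvalidParameterError(f"expected the mixed system, got {data.system!r}")
    ctx = ctx or ThermoContext()
    self_A, self_B = fixed_self
    est = MixedDimerFit(
        dG_AA=self_A.dG_oligo,
        dG_BB=self_B.dG_oligo,
        temperature=ctx.temperature,
        cac_fib_A=self_A.cac_fib if use_fibril_caps else None,
        cac_fib_B=self_B.cac_fib if use_fibril_caps else None,
    )
    X, y, _ = _dataset_arrays(data)
    w = _replicate_weights(data) if weighted else None
    est.fit(X, y, sample_weight=w)
    result = est.result_
    if n_boot:
        refit = lambda ds: fit_mixed_dG(ds, fixed_self, ctx, weighted=weighted)
        result.confidence_intervals = bootstrap_ci(data, refit, n_boot, level, seed)
        result.ci_level = level
        result.n_boot = n_boot
        result.seed = seed
    return result


def bootstrap_ci(
    data: MeasurementDataset,
    fit,
    n_boot: int = 1000,
    level: float = 0.68,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals by case-resampling replicates.

    Within each total concentration the replicate measurements are
    resampled with replacement; ``fit`` maps a dataset to a
    :class:`FitResult`.  Reproducible given ``seed``.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    df = data.to_frame()
    groups = [sub for _, sub in df.groupby("total_conc", sort=True)]
    if any(len(g) < 2 for g in groups):
        raise InvalidParameterError(
            "each concentration needs >= 2 replicates for case resampling"
        )
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    for _ in range(n_boot):
        parts = [g.iloc[rng.integers(0, len(g), size=len(g))] for g in groups]
        resampled = pd.concat(parts, ignore_index=True)
        ds = MeasurementDataset.from_arrays(
            system=data.system,
            total_conc=resampled["total_conc"],
            oligomer_conc=resampled["oligomer_conc"],
            replicate=resampled["replicate"],
            label_scheme=data.label_scheme,
        )
        res = fit(ds)
        for k, v in res.params.items():
            draws.setdefault(k, []).append(v)
    alpha = (1.0 - level) / 2.0
    return {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
        for k, v in draws.items()
    }


def _plateau_onset_from_arrays(X: np.ndarray, y: np.ndarray) -> float:
    """Changepoint from local log-log slopes: rising limb, then plateau.

    The observed curve grows with local log-log slope ~2 in the dilute
    regime and flattens abruptly at the fibril CAC, so a plateau is a
    trailing run of inter-point slopes far below the rising reference.
    Smoothly decelerating (but still rising) growth does not qualify.
    Returns the onset total concentration (molar), the first grid point
    for flat data, or the ``NO_PLATEAU`` sentinel (inf).
    """
    totals = np.unique(X)
    means = np.array([y[X == t].mean() for t in totals])
    n = len(totals)
    if means.max() <= 0:
        return float(totals[0])
    if (means.max() - means.min()) / means.max() < 0.05:
        return float(totals[0])  # flat within 5%: plateau from the start
    with np.errstate(divide="ignore", invalid="ignore"):
        log_means = np.where(means > 0, np.log(means), np.nan)
    slopes = np.diff(log_means) / np.diff(np.log(totals))
    reference = np.nanmax(slopes)
    if not np.isfinite(reference) or reference <= 0.5:
        return float(totals[0])
    flat = slopes < 0.5 * reference  # slope collapse marks the cap
    flat[np.isnan(slopes)] = False
    if not flat[n - 2]:  # growth continues through the last interval
        return NO_PLATEAU
    j = n - 2  # first interval of the trailing flat run (spans totals[j..j+1])
    while j - 1 >= 0 and flat[j - 1]:
        j -= 1
    k = j + 1  # first certain plateau grid point
    plateau = float(means[k:].mean())
    rise_end = k
    if plateau > 0 and abs(means[k - 1] - plateau) / plateau < 0.1:
        rise_end = k - 1  # the break sits just before this grid point
    pos = means[:rise_end] > 0
    if pos.sum() < 2:
        return float(totals[k])
    b, loga = np.polyfit(np.log(totals[:rise_end][pos]), log_means[:rise_end][pos], 1)
    if b <= 0 or plateau <= 0:
        return float(totals[k])
    crossing = (plateau / math.exp(loga)) ** (1.0 / b)
    return float(np.clip(crossing, totals[max(rise_end - 1, 0)], totals[k]))


def estimate_plateau_onset(data: MeasurementDataset) -> float:
    """Model-free plateau-onset (fibril CAC) estimate from one dataset."""
    X, y, _ = _dataset_arrays(data)
    if len(np.unique(X)) < 5:
        raise InvalidParameterError("need >= 5 distinct concentrations")
    return _plateau_onset_from_arrays(X, y)
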