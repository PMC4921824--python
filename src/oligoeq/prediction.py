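"""Predictions at physiological (nanomolar) Aβ concentrations.

With the fitted free energies in hand the dimer equilibrium can be
extrapolated to the ~1 nM total Aβ concentration found in vivo, far
below what bulk experiments reach.  This module provides

- composition sweeps over the Aβ42 proportion at fixed total peptide,
- single-species oligomer size distributions (geometric; dimers
  dominate at 1 nM),
- the relative number of membrane-bound oligomers, counting dimers
  weighted by relative membrane affinities (Aβ42 self-dimers bind the
  neuronal membrane ~4x as strongly as Aβ40 dimers; heterodimers are
  assigned the intermediate factor 2), normalised to pure Aβ40 at the
  baseline concentration, and
- named disease scenarios: a 1.5x overall overproduction (trisomy-21
  gene dosage of APP) and an extreme 22:1 Aβ42:Aβ40 ratio
  (Beyreuther/Iberian APP mutation).

In the dilute regime every dimer concentration is quadratic in total
peptide, so a fold change f in total concentration multiplies oligomer
numbers by ~f²; at f = 1.5 that is the +125% prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooligomer import (
    MixedEquilibriumState,
    MixedSystemParams,
    composition_fractions,
    solve_two_species,
)
from .exceptions import InvalidParameterError
from .thermo import SelfSystemParams, ThermoContext, size_distribution, solve_self_equilibrium

__all__ = [
    "AffinityWeights",
    "ScenarioSpec",
    "PredictionReport",
    "parse_ratio",
    "sweep_ab42_fraction",
    "size_distribution_report",
    "relative_bound_oligomers",
    "scenario_report",
]


@dataclass(frozen=True)
class AffinityWeights:
    """Relative membrane affinities of the three dimer species."""

    w_AA: float = 1.0
    w_AB: float = 2.0
    w_BB: float = 4.0

    def __post_init__(self) -> None:
        if not all(w > 0 for w in (self.w_AA, self.w_AB, self.w_BB)):
            raise InvalidParameterError("affinity weights must be positive")


def parse_ratio(ratio: str) -> float:
    """Parse an ``"A:B"`` ratio string into the Aβ42 (B) fraction.

    ``"9:1"`` → 0.1; the first number is Aβ40, the second Aβ42.
    """
    try:
        a, b = (float(part) for part in ratio.split(":"))
    except ValueError as exc:
        raise InvalidParameterError(f"cannot parse ratio {ratio!r}") from exc
    if a < 0 or b < 0 or a + b == 0:
        raise InvalidParameterError(f"invalid ratio {ratio!r}")
    return b / (a + b)


@dataclass(frozen=True)
class ScenarioSpec:
    """One prediction condition relative to a baseline.

    ``ab42_fraction`` may be given directly or as a ratio string; the
    baseline (denominator of relative quantities) defaults to pure Aβ40
    at ``total_conc``.
    """

    total_conc: float = 1e-9
    ab42_fraction: float | str = 0.1
    fold_change: float = 1.0
    baseline_total_conc: float | None = None
    baseline_ab42_fraction: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.ab42_fraction, str):
            object.__setattr__(self, "ab42_fraction", parse_ratio(self.ab42_fraction))
        if not 0.0 <= self.ab42_fraction <= 1.0:
            raise InvalidParameterError("ab42_fraction must lie in [0, 1]")
        if self.fold_change <= 0:
            raise InvalidParameterError("fold_change must be > 0")
        if self.total_conc < 0:
            raise InvalidParameterError("total_conc must be non-negative")

    @property
    def baseline_total(self) -> float:
        return self.total_conc if self.baseline_total_conc is None else self.baseline_total_conc


@dataclass
class PredictionReport:
    """Tabular prediction output plus the settings that produced it."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {"metadata": self.metadata, "rows": self.table.to_dict(orient="records")}


def _solve_at(total: float, fraction_B: float, params: MixedSystemParams,
              ctx: ThermoContext) -> MixedEquilibriumState:
    return solve_two_species(total * (1.0 - fraction_B), total * fraction_B, params, ctx)


def _weighted_bound(state: MixedEquilibriumState, weights: AffinityWeights) -> float:
    return (
        weights.w_AA * state.conc_AA
        + weights.w_AB * state.conc_AB
        + weights.w_BB * state.conc_BB
    )


def sweep_ab42_fraction(
    total_conc: float,
    fractions=None,
    params: MixedSystemParams | None = None,
    ctx: ThermoContext | None = None,
    weights: AffinityWeights | None = None,
) -> PredictionReport:
    """Equilibrium composition over a grid of Aβ42 proportions.

    At each fraction the two-species dimer equilibrium is solved at
    fixed total peptide; the report carries free monomers, the three
    dimer concentrations, the total oligomer (dimer particle)
    concentration and the affinity-weighted relative bound-oligomer
    value normalised to the pure-Aβ40 endpoint.
    """
    params = params or MixedSystemParams()
    ctx = ctx or ThermoContext()
    weights = weights or AffinityWeights()
    fractions = np.linspace(0.0, 1.0, 101) if fractions is None else np.asarray(fractions, float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise InvalidParameterError("fractions must lie in [0, 1]")
    rows = []
    baseline_state = _solve_at(total_conc, 0.0, params, ctx)
    baseline_bound = _weighted_bound(baseline_state, weights)
    for f in fractions:
        st = _solve_at(total_conc, float(f), params, ctx)
        rows.append(
            {
                "ab42_fraction": float(f),
                "free_A": st.free_A,
                "free_B": st.free_B,
                "conc_AA": st.conc_AA,
                "conc_AB": st.conc_AB,
                "conc_BB": st.conc_BB,
                "total_oligomer": st.oligomer_particle_conc,
                "relative_bound": _weighted_bound(st, weights) / baseline_bound,
            }
        )
    return PredictionReport(
        table=pd.DataFrame(rows),
        metadata={
            "total_conc_M": total_conc,
            "params": params.__dict__,
            "weights": weights.__dict__,
            "temperature_K": ctx.temperature,
            "normalisation": "pure Abeta40 at the same total concentration",
        },
    )


def size_distribution_report(
    total_conc: float,
    params: SelfSystemParams | None = None,
    ctx: ThermoContext | None = None,
    n_max: int = 10,
) -> dict[int, float]:
    """Oligomer concentrations by size at the given total concentration.

    Uses the single-species free energy of monomer addition for every
    bond (the mixing ratio then does not matter); at 1 nM the dimer
    dominates and each further monomer costs a factor K·m ≈ 1.3e-3.
    """
    params = params or SelfSystemParams(label="self_A", dG_oligo=-36.3)
    ctx = ctx or ThermoContext()
    state = solve_self_equilibrium(total_conc, params, ctx)
    return size_distribution(state.free_monomer, params.dG_oligo, ctx, n_max=n_max)


def relative_bound_oligomers(
    spec: ScenarioSpec,
    params: MixedSystemParams | None = None,
    weights: AffinityWeights | None = None,
    ctx: ThermoContext | None = None,
) -> float:
    """Affinity-weighted bound oligomers relative to the baseline.

    numerator:   Σ w_s · [s] at (fold_change × total, ab42_fraction)
    denominator: Σ w_s · [s] at (baseline total, baseline fraction —
                 pure Aβ40 unless overridden)
    """
    params = params or MixedSystemParams()
    weights = weights or AffinityWeights()
    ctx = ctx or ThermoContext()
    base = _solve_at(spec.baseline_total, spec.baseline_ab42_fraction, params, ctx)
    denom = _weighted_bound(base, weights)
    if denom == 0:
        raise InvalidParameterError("baseline bound-oligomer concentration is zero")
    scen = _solve_at(spec.total_conc * spec.fold_change, spec.ab42_fraction, params, ctx)
    return _weighted_bound(scen, weights) / denom


def scenario_report(
    spec: ScenarioSpec,
    params: MixedSystemParams | None = None,
    weights: AffinityWeights | None = None,
    ctx: ThermoContext | None = None,
) -> dict:
    """Bundle the scenario arithmetic for one named condition.

    Reports the percentage change in total oligomer (dimer particle)
    concentration relative to the un-scaled condition, the composition
    fractions, and the relative bound-oligomer factor under both
    heterodimer degeneracy conventions (g = 2 and g = 1), because the
    convention behind published heterodimer free energies is not always
    stated.
    """
    params = params or MixedSystemParams()
    weights = weights or AffinityWeights()
    ctx = ctx or ThermoContext()
    before = _solve_at(spec.total_conc, spec.ab42_fraction, params, ctx)
    after = _solve_at(spec.total_conc * spec.fold_change, spec.ab42_fraction, params, ctx)
    frac_AA, frac_AB, frac_BB = composition_fractions(after)
    out = {
        "total_conc_M": spec.total_conc,
        "ab42_fraction": spec.ab42_fraction,
        "fold_change": spec.fold_change,
        "oligomer_conc_before_M": before.oligomer_particle_conc,
        "oligomer_conc_after_M": after.oligomer_particle_conc,
        "oligomer_increase_percent": 100.0
        * (after.oligomer_particle_conc / before.oligomer_particle_conc - 1.0),
        "composition": {"frac_AA": frac_AA, "frac_AB": frac_AB, "frac_BB": frac_BB},
    }
    for g in (params.hetero_degeneracy, 3 - params.hetero_degeneracy):
        p_g = MixedSystemParams(
            dG_AA=params.dG_AA, dG_BB=params.dG_BB, dG_AB=params.dG_AB,
            cac_fib_A=params.cac_fib_A, cac_fib_B=params.cac_fib_B,
            hetero_degeneracy=g,
        )
        out[f"relative_bound_g{g}"] = relative_bound_oligomers(spec, p_g, weights, ctx)
    out["relative_bound"] = out[f"relative_bound_g{params.hetero_degeneracy}"]
    return out
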