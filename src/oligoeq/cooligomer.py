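"""Two-species (Aβ40 = A, Aβ42 = B) dimer equilibrium.

At nanomolar concentrations the single-species analysis predicts that
oligomers are overwhelmingly dimeric, so the mixed system is truncated at
dimers: free monomers a, b in equilibrium with homodimers AA, BB and the
heterodimer AB.  Mass-action laws:

    [AA] = K_AA a²,   [BB] = K_BB b²,   [AB] = g K_AB a b

where g is the heterodimer degeneracy (statistical) factor: an AB pair
has two distinguishable arrangements where AA and BB have one, so g = 2
by default; g = 1 (degeneracy absorbed into K_AB) is supported because
published free energies do not always state the convention.

The coupled mass balances

    a + 2 K_AA a² + g K_AB a b = total_A
    b + 2 K_BB b² + g K_AB a b = total_B

are solved by damped alternating substitution: holding b, the balance
for a is a quadratic with a unique positive root (and vice versa); each
sweep relaxes halfway toward the new root.  The map is monotone, so the
fixed point is unique on the positive orthant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import (
    ConvergenceError,
    InvalidParameterError,
    UndefinedCompositionError,
)
from .thermo import ThermoContext, equilibrium_constant, solve_free_monomer

__all__ = [
    "MixedSystemParams",
    "MixedEquilibriumState",
    "solve_two_species",
    "composition_fractions",
]

# fitted oligomerization free energies, kJ/mol
DEFAULT_DG_AA = -36.3
DEFAULT_DG_BB = -36.3
DEFAULT_DG_AB = -32.6


@dataclass(frozen=True)
class MixedSystemParams:
    """Bond free energies (kJ/mol) for the AA, BB and AB dimer contacts.

    Optional per-isoform fibril CACs cap the free monomers for
    extrapolation above the solubility limits; they are off by default
    because the mixed-system measurements sit below both CACs.
    """

    dG_AA: float = DEFAULT_DG_AA
    dG_BB: float = DEFAULT_DG_BB
    dG_AB: float = DEFAULT_DG_AB
    cac_fib_A: float | None = None
    cac_fib_B: float | None = None
    hetero_degeneracy: int = 2

    def __post_init__(self) -> None:
        for name in ("dG_AA", "dG_BB", "dG_AB"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v}")
        if self.hetero_degeneracy not in (1, 2):
            raise InvalidParameterError(
                f"hetero_degeneracy must be 1 or 2, got {self.hetero_degeneracy}"
            )
        for name in ("cac_fib_A", "cac_fib_B"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be > 0 M, got {v}")

    def swapped(self) -> "MixedSystemParams":
        """Parameters with the A and B labels exchanged."""
        return MixedSystemParams(
            dG_AA=self.dG_BB,
            dG_BB=self.dG_AA,
            dG_AB=self.dG_AB,
            cac_fib_A=self.cac_fib_B,
            cac_fib_B=self.cac_fib_A,
            hetero_degeneracy=self.hetero_degeneracy,
        )


@dataclass
class MixedEquilibriumState:
    free_A: float
    free_B: float
    conc_AA: float
    conc_AB: float
    conc_BB: float
    total_A: float
    total_B: float
    fibril_mass_A: float = 0.0
    fibril_mass_B: float = 0.0

    @property
    def oligomer_particle_conc(self) -> float:
        """Total dimer (particle) concentration, AA + AB + BB."""
        return self.conc_AA + self.conc_AB + self.conc_BB

    def mass_balance_error(self) -> float:
        """Max relative defect of the two species mass balances."""
        errs = []
        for free, homo, total, fib in (
            (self.free_A, self.conc_AA, self.total_A, self.fibril_mass_A),
            (self.free_B, self.conc_BB, self.total_B, self.fibril_mass_B),
        ):
            lhs = free + 2.0 * homo + self.conc_AB + fib
            errs.append(abs(lhs - total) / total if total > 0 else abs(lhs))
        return max(errs)


def _positive_root(total: float, coupling: float, K_homo: float) -> float:
    """Unique positive root of 2*K*x² + (1+coupling)*x - total = 0."""
    c = 1.0 + coupling
    # rationalised quadratic formula, stable for small K*total
    return 2.0 * total / (c + math.sqrt(c * c + 8.0 * K_homo * total))


def solve_two_species(
    total_A: float,
    total_B: float,
    params: MixedSystemParams,
    ctx: ThermoContext | None = None,
    *,
    rtol: float = 1e-12,
    max_iter: int = 500,
    relaxation: float = 0.5,
) -> MixedEquilibriumState:
    """Solve the coupled two-species dimer mass balance.

    Deterministic damped substitution; raises :class:`ConvergenceError`
    with diagnostics if the relative mass-balance residuals do not fall
    below ``rtol`` within ``max_iter`` sweeps.
    """
    ctx = ctx or ThermoContext()
    if total_A < 0 or total_B < 0:
        raise InvalidParameterError("totals must be non-negative")
    K_AA = equilibrium_constant(params.dG_AA, ctx)
    K_BB = equilibrium_constant(params.dG_BB, ctx)
    K_AB = equilibrium_constant(params.dG_AB, ctx)
    g = float(params.hetero_degeneracy)

    # optional solubility caps on the free monomers
    a_cap = params.cac_fib_A
    b_cap = params.cac_fib_B
    if a_cap is not None:
        a_cap = solve_free_monomer(a_cap, params.dG_AA, ctx)
    if b_cap is not None:
        b_cap = solve_free_monomer(b_cap, params.dG_BB, ctx)

    a = min(total_A, a_cap) if a_cap is not None else total_A
    b = min(total_B, b_cap) if b_cap is not None else total_B
    for iteration in range(1, max_iter + 1):
        a_new = _positive_root(total_A, g * K_AB * b, K_AA)
        if a_cap is not None:
            a_new = min(a_new, a_cap)
        a = (1.0 - relaxation) * a + relaxation * a_new
        b_new = _positive_root(total_B, g * K_AB * a, K_BB)
        if b_cap is not None:
            b_new = min(b_new, b_cap)
        b = (1.0 - relaxation) * b + relaxation * b_new

        conc_AB = g * K_AB * a * b
        res_a = a + 2.0 * K_AA * a * a + conc_AB - total_A
        res_b = b + 2.0 * K_BB * b * b + conc_AB - total_B
        rel_a = abs(res_a) / total_A if total_A > 0 else abs(res_a)
        rel_b = abs(res_b) / total_B if total_B > 0 else abs(res_b)
        capped_a = a_cap is not None and a >= a_cap * (1.0 - 1e-12)
        capped_b = b_cap is not None and b >= b_cap * (1.0 - 1e-12)
        if (rel_a < rtol or capped_a) and (rel_b < rtol or capped_b):
            state = MixedEquilibriumState(
                free_A=a,
                free_B=b,
                conc_AA=K_AA * a * a,
                conc_AB=conc_AB,
                conc_BB=K_BB * b * b,
                total_A=float(total_A),
                total_B=float(total_B),
            )
            if capped_a:
                state.fibril_mass_A = total_A - (a + 2.0 * state.conc_AA + conc_AB)
            if capped_b:
                state.fibril_mass_B = total_B - (b + 2.0 * state.conc_BB + conc_AB)
            return state

    raise ConvergenceError(
        "two-species solver did not converge",
        details={
            "iterations": max_iter,
            "residual_A": rel_a,
            "residual_B": rel_b,
            "free_A": a,
            "free_B": b,
        },
    )


def composition_fractions(state: MixedEquilibriumState) -> tuple[float, float, float]:
    """Fractions (frac_AA, frac_AB, frac_BB) of the dimer population."""
    total = state.conc_AA + state.conc_AB + state.conc_BB
    if total <= 0:
        raise UndefinedCompositionError("no dimers present; composition undefined")
    return state.conc_AA / total, state.conc_AB / total, state.conc_BB / total
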