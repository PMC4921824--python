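"""Single-species isodesmic (linear-aggregation) equilibrium thermodynamics.

The model treats an oligomer as a one-dimensional chain of monomers held
together by nearest-neighbour contacts, each contributing the same Gibbs
free energy of monomer addition, ΔG° (kJ/mol, negative = favourable).
This single parameter fixes the association constant

    K = exp(-ΔG°/RT) / c0          [1/M]

for a standard concentration c0 (1 M by default), and therefore the
critical aggregation concentration CAC = 1/K = c0·exp(ΔG°/RT).  At free
monomer concentration m the oligomer size distribution is geometric,

    [A_n] = K**(n-1) * m**n,       n = 1, 2, ...

convergent for K·m < 1.  Oligomeric and fibrillar states are assigned
separate free energies; the fibrillar state manifests as a plateau: once
the total peptide concentration exceeds the fibril CAC, all additional
material is sequestered into fibrils and the solution phase (monomer +
oligomers) is pinned at the state it had at that CAC.

All concentrations in this module are molar; free energies are kJ/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, SupersaturationError

GAS_CONSTANT = 8.314  # J / (mol K)
DEFAULT_TEMPERATURE = 310.15  # K, the 37 degC incubation temperature
DEFAULT_STANDARD_CONC = 1.0  # M

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_STANDARD_CONC",
    "ThermoContext",
    "SelfSystemParams",
    "SelfEquilibriumState",
    "equilibrium_constant",
    "cac_from_free_energy",
    "free_energy_from_cac",
    "solve_free_monomer",
    "apply_fibril_cap",
    "size_distribution",
    "oligomer_totals",
    "solve_self_equilibrium",
]


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and reference state defining the ΔG° ↔ K ↔ CAC mapping.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 310.15 K (37 degC, the
        incubation temperature of the steady-state experiments).
    standard_concentration : float
        Reference concentration c0 in molar, default 1.0.
    gas_constant : float
        R in J/(mol K); a physical constant, exposed only for unit clarity.
    """

    temperature: float = DEFAULT_TEMPERATURE
    standard_concentration: float = DEFAULT_STANDARD_CONC
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise InvalidParameterError(f"temperature must be > 0 K, got {self.temperature}")
        if not (np.isfinite(self.standard_concentration) and self.standard_concentration > 0):
            raise InvalidParameterError(
                f"standard_concentration must be > 0 M, got {self.standard_concentration}"
            )

    @property
    def rt_kj(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature / 1000.0


def _check_free_energy(dG: float) -> float:
    dG = float(dG)
    if not math.isfinite(dG):
        raise InvalidParameterError(f"free energy must be finite, got {dG}")
    return dG


def equilibrium_constant(dG: float, ctx: ThermoContext | None = None) -> float:
    """Association constant K = exp(-ΔG°/RT)/c0 in 1/M.

    ``dG`` is the free energy of monomer addition in kJ/mol; negative
    values (favourable binding) give K > 1/c0.
    """
    ctx = ctx or ThermoContext()
    dG = _check_free_energy(dG)
    return math.exp(-dG / ctx.rt_kj) / ctx.standard_concentration


def cac_from_free_energy(dG: float, ctx: ThermoContext | None = None) -> float:
    """Critical aggregation concentration c = c0·exp(ΔG°/RT) in molar."""
    ctx = ctx or ThermoContext()
    dG = _check_free_energy(dG)
    return ctx.standard_concentration * math.exp(dG / ctx.rt_kj)


def free_energy_from_cac(cac: float, ctx: ThermoContext | None = None) -> float:
    """Inverse map ΔG° = RT·ln(cac/c0) in kJ/mol.

    Warns (does not raise) if cac >= c0, where the implied free energy is
    non-negative and aggregation is nominally unfavourable.
    """
    ctx = ctx or ThermoContext()
    cac = float(cac)
    if not (math.isfinite(cac) and cac > 0):
        raise InvalidParameterError(f"cac must be a positive concentration, got {cac}")
    if cac >= ctx.standard_concentration:
        warnings.warn(
            f"cac = {cac} M >= standard concentration {ctx.standard_concentration} M; "
            "implied free energy is non-negative",
            stacklevel=2,
        )
    return ctx.rt_kj * math.log(cac / ctx.standard_concentration)


@dataclass(frozen=True)
class SelfSystemParams:
    """One isoform's oligomer free energy and fibril solubility threshold.

    ``dG_oligo`` (kJ/mol) controls the oligomer population below the
    plateau; ``cac_fib`` (molar) is the fibril critical aggregation
    concentration above which added peptide goes into fibrils.  The two
    parametrisations of the fibril state (cac_fib or dG_fib) are
    interchangeable through :func:`cac_from_free_energy`.
    """

    label: str
    dG_oligo: float
    cac_fib: float | None = None

    def __post_init__(self) -> None:
        _check_free_energy(self.dG_oligo)
        if self.cac_fib is not None and not (
            math.isfinite(self.cac_fib) and self.cac_fib > 0
        ):
            raise InvalidParameterError(f"cac_fib must be > 0 M, got {self.cac_fib}")

    @classmethod
    def from_free_energies(
        cls, label: str, dG_oligo: float, dG_fib: float, ctx: ThermoContext | None = None
    ) -> "SelfSystemParams":
        return cls(label=label, dG_oligo=dG_oligo, cac_fib=cac_from_free_energy(dG_fib, ctx))

    def dG_fib(self, ctx: ThermoContext | None = None) -> float:
        if self.cac_fib is None:
            raise InvalidParameterError("no fibril CAC set for this system")
        return free_energy_from_cac(self.cac_fib, ctx)


def solve_free_monomer(
    total_conc: float, dG_oligo: float, ctx: ThermoContext | None = None
) -> float:
    """Free monomer m at total (monomer-equivalent) concentration ``total_conc``.

    Mass balance of the isodesmic series, total = Σ n·K**(n-1)·m**n
    = m/(1-Km)², is a quadratic in x = K·m:

        τ x² - (2τ+1) x + τ = 0,   τ = K·total

    whose root in (0, 1) is x = 2τ / (2τ + 1 + sqrt(4τ + 1)), written in
    the cancellation-free form.  Accepts scalars or arrays.
    """
    ctx = ctx or ThermoContext()
    K = equilibrium_constant(dG_oligo, ctx)
    total = np.asarray(total_conc, dtype=float)
    if np.any(total < 0):
        raise InvalidParameterError("total_conc must be non-negative")
    tau = K * total
    x = 2.0 * tau / (2.0 * tau + 1.0 + np.sqrt(4.0 * tau + 1.0))
    m = x / K
    return float(m) if np.isscalar(total_conc) else m


def apply_fibril_cap(
    m_oligo_only: float,
    total_conc: float,
    params: SelfSystemParams,
    ctx: ThermoContext | None = None,
) -> tuple[float, float]:
    """Partition total peptide between the solution phase and fibrils.

    Below the fibril CAC nothing changes.  Once ``total_conc`` exceeds
    ``params.cac_fib``, the solution phase (free monomer + oligomers) is
    frozen at its state at the CAC and all excess mass is fibrillar, so
    the oligomer concentration plateaus exactly.  Returns
    ``(m, fibril_mass)`` with fibril_mass in monomer equivalents.
    """
    ctx = ctx or ThermoContext()
    if m_oligo_only < 0 or total_conc < 0:
        raise InvalidParameterError("concentrations must be non-negative")
    cac = params.cac_fib
    if cac is None or total_conc <= cac:
        return float(m_oligo_only), 0.0
    m_cap = solve_free_monomer(cac, params.dG_oligo, ctx)
    return m_cap, float(total_conc - cac)


def size_distribution(
    m: float, dG_oligo: float, ctx: ThermoContext | None = None, n_max: int = 1000
) -> dict[int, float]:
    """Geometric size distribution [A_n] = K**(n-1)·m**n for n = 1..n_max."""
    ctx = ctx or ThermoContext()
    if n_max < 2:
        raise InvalidParameterError(f"n_max must be >= 2, got {n_max}")
    K = equilibrium_constant(dG_oligo, ctx)
    x = K * m
    if x >= 1.0:
        raise SupersaturationError(f"K*m = {x:.6g} >= 1: isodesmic series diverges")
    n = np.arange(1, n_max + 1)
    with np.errstate(under="ignore"):
        conc = (m / x) * np.power(x, n) if x > 0 else np.where(n == 1, m, 0.0)
    return dict(zip(n.tolist(), conc.tolist()))


def oligomer_totals(
    m: float, dG_oligo: float, ctx: ThermoContext | None = None
) -> tuple[float, float]:
    """Closed-form oligomer totals at free monomer m.

    Returns ``(particle_conc, mass_conc)``: the concentration of
    assemblies with n >= 2, Σ [A_n] = K m²/(1-Km), and their mass in
    monomer equivalents, Σ n[A_n] = m/(1-Km)² - m.
    """
    ctx = ctx or ThermoContext()
    K = equilibrium_constant(dG_oligo, ctx)
    x = K * m
    if x >= 1.0:
        raise SupersaturationError(f"K*m = {x:.6g} >= 1: isodesmic series diverges")
    particle = K * m * m / (1.0 - x)
    mass = m / (1.0 - x) ** 2 - m
    return particle, mass


@dataclass
class SelfEquilibriumState:
    """Full single-species equilibrium state at a given total concentration.

    ``size_distribution`` maps oligomer size n (>= 1) to molar
    concentration; ``oligomer_particle_conc`` counts assemblies with
    n >= 2 (what a single-molecule counting experiment sees as events);
    ``oligomer_mass_conc`` and ``fibril_mass_conc`` are monomer
    equivalents so that mass is conserved:

        m + oligomer_mass + fibril_mass = total.
    """

    free_monomer: float
    oligomer_particle_conc: float
    oligomer_mass_conc: float
    fibril_mass_conc: float
    total_conc: float
    params: SelfSystemParams
    ctx: ThermoContext = field(default_factory=ThermoContext)
    n_max: int = 1000

    @property
    def size_distribution(self) -> dict[int, float]:
        return size_distribution(self.free_monomer, self.params.dG_oligo, self.ctx, self.n_max)

    def mass_balance_error(self) -> float:
        """Relative mass-conservation defect (0 for a consistent state)."""
        lhs = self.free_monomer + self.oligomer_mass_conc + self.fibril_mass_conc
        if self.total_conc == 0:
            return abs(lhs)
        return abs(lhs - self.total_conc) / self.total_conc


def solve_self_equilibrium(
    total_conc: float,
    params: SelfSystemParams,
    ctx: ThermoContext | None = None,
    n_max: int = 1000,
) -> SelfEquilibriumState:
    """Solve the single-species equilibrium including the fibril plateau."""
    ctx = ctx or ThermoContext()
    m0 = solve_free_monomer(total_conc, params.dG_oligo, ctx)
    m, fibril_mass = apply_fibril_cap(m0, total_conc, params, ctx)
    particle, mass = oligomer_totals(m, params.dG_oligo, ctx)
    return SelfEquilibriumState(
        free_monomer=m,
        oligomer_particle_conc=particle,
        oligomer_mass_conc=mass,
        fibril_mass_conc=fibril_mass,
        total_conc=float(total_conc),
        params=params,
        ctx=ctx,
        n_max=n_max,
    )
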