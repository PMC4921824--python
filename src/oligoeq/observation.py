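"""Two-colour coincidence detection (TCCD) observation model.

TCCD distinguishes oligomers from monomers by temporal coincidence of
blue- and red-fluorophore bursts: only assemblies carrying at least one
monomer of each colour register as oligomers.  With monomers labelled
blue with probability p (1:1 mixing gives p = 0.5) and colours assigned
independently, the coincident fraction of n-mers is

    f(n, p) = 1 - p**n - (1-p)**n.

Two labelling schemes are used:

- ``self_mixed_colours``: one isoform, half blue / half red.  Every
  oligomer size contributes with weight f(n, p).
- ``cross_colour``: Aβ40 blue, Aβ42 red.  Only the AB heterodimer is
  two-coloured; AA and BB are invisible to the coincidence criterion.

Burst-rate-to-concentration calibration is assumed applied upstream;
this module works entirely at the concentration level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cooligomer import MixedEquilibriumState
from .exceptions import InvalidParameterError, SchemeMismatchError
from .thermo import SelfEquilibriumState, equilibrium_constant

__all__ = [
    "LabelScheme",
    "coincident_fraction",
    "observed_oligomer_concentration",
    "correct_observed_to_true",
]

SELF_MIXED = "self_mixed_colours"
CROSS = "cross_colour"


@dataclass(frozen=True)
class LabelScheme:
    mode: str = SELF_MIXED
    blue_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in (SELF_MIXED, CROSS):
            raise InvalidParameterError(f"unknown labelling mode {self.mode!r}")
        if not 0.0 < self.blue_fraction < 1.0:
            raise InvalidParameterError(
                f"blue_fraction must be in (0, 1), got {self.blue_fraction}"
            )


def coincident_fraction(n: int, blue_fraction: float = 0.5) -> float:
    """Probability that a random n-mer carries both colours."""
    if n < 1 or int(n) != n:
        raise InvalidParameterError(f"n must be an integer >= 1, got {n}")
    p = blue_fraction
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"blue_fraction must be in (0, 1), got {p}")
    return 1.0 - p ** int(n) - (1.0 - p) ** int(n)


def observed_oligomer_concentration(
    state: SelfEquilibriumState | MixedEquilibriumState,
    scheme: LabelScheme,
) -> float:
    """Concentration of coincidence-detectable oligomers for a state.

    For a self system the geometric size distribution admits a closed
    form:  Σ_{n>=2} K**(n-1) m**n f(n, p)
    = [x²/(1-x) - x_p²/(1-x_p) - x_q²/(1-x_q)] / K
    with x = Km, x_p = pKm, x_q = (1-p)Km.  For the cross-colour mixed
    experiment only the heterodimer is counted.
    """
    if isinstance(state, SelfEquilibriumState):
        if scheme.mode != SELF_MIXED:
            raise SchemeMismatchError(
                "single-species state requires the self_mixed_colours scheme"
            )
        K = equilibrium_constant(state.params.dG_oligo, state.ctx)
        m = state.free_monomer
        p = scheme.blue_fraction
        total = 0.0
        for frac in (1.0, p, 1.0 - p):
            x = frac * K * m
            sign = 1.0 if frac == 1.0 else -1.0
            total += sign * x * x / (1.0 - x)
        return total / K
    if isinstance(state, MixedEquilibriumState):
        if scheme.mode != CROSS:
            raise SchemeMismatchError(
                "two-species state requires the cross_colour scheme"
            )
        return state.conc_AB
    raise SchemeMismatchError(f"unsupported state type {type(state).__name__}")


def correct_observed_to_true(
    observed: float, mean_size_assumption: int, scheme: LabelScheme
) -> float:
    """Invert the coincidence filter under an assumed (monodisperse) size.

    A dimer-dominated population at p = 0.5 needs a factor of 2; the
    factor shrinks quickly with size (1.33 for trimers, 1.14 for
    tetramers).
    """
    if observed < 0:
        raise InvalidParameterError("observed concentration must be non-negative")
    if mean_size_assumption < 2:
        raise InvalidParameterError("mean_size_assumption must be >= 2")
    if scheme.mode == CROSS:
        return observed  # heterodimers are always two-coloured
    return observed / coincident_fraction(mean_size_assumption, scheme.blue_fraction)
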