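"""Independent oracles used to cross-check the package's solvers.

Each oracle deliberately avoids the algebraic route the implementation
takes (closed-form quadratics, damped substitution, closed-form
geometric sums) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize

C0 = 1.0  # M


def bisect_free_monomer(total: float, K: float, tol: float = 1e-18) -> float:
    """Pure-bisection solve of m/(1-Km)^2 = total on (0, 1/K)."""
    if total == 0:
        return 0.0

    def residual(m: float) -> float:
        return m / (1.0 - K * m) ** 2 - total

    lo, hi = 0.0, (1.0 - 1e-12) / K
    if residual(hi) < 0:  # total beyond representable bracket
        return hi
    while hi - lo > tol and (hi - lo) > 1e-16 * hi:
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def brute_force_oligomer_totals(m: float, K: float, n_max: int = 10_000):
    """Direct truncated summation of the geometric size distribution."""
    n = np.arange(2, n_max + 1)
    with np.errstate(under="ignore"):
        conc = np.exp((n - 1) * math.log(K) + n * math.log(m))  # avoids overflow
    return float(conc.sum()), float((n * conc).sum())


def enumerate_coincident_fraction(n: int, p: float) -> float:
    """Exhaustive enumeration over all 2^n colourings of an n-mer."""
    total = 0.0
    for colours in itertools.product((0, 1), repeat=n):
        k = sum(colours)
        weight = p**k * (1.0 - p) ** (n - k)
        if 0 < k < n:
            total += weight
    return total


def nested_brentq_two_species(
    total_A: float, total_B: float, K_AA: float, K_BB: float, K_AB: float, g: float
):
    """Solve the coupled dimer mass balance by nested Brent root-finding."""

    def b_given_a(a: float) -> float:
        if total_B == 0:
            return 0.0
        f = lambda b: b + 2.0 * K_BB * b * b + g * K_AB * a * b - total_B
        return optimize.brentq(f, 0.0, total_B, xtol=1e-30, rtol=1e-15)

    if total_A == 0:
        b = b_given_a(0.0)
        return 0.0, b

    def f_a(a: float) -> float:
        b = b_given_a(a)
        return a + 2.0 * K_AA * a * a + g * K_AB * a * b - total_A

    a = optimize.brentq(f_a, 0.0, total_A, xtol=1e-30, rtol=1e-15)
    return a, b_given_a(a)


def free_energy_minimisation_two_species(
    total_A: float,
    total_B: float,
    dG_AA: float,
    dG_BB: float,
    dG_AB: float,
    g: int,
    rt_kj: float,
):
    """Minimise the ideal-solution Gibbs free energy over the dimer concs.

    Works in concentrations scaled by the total mass and in extended
    precision, grid-scanning log-space then polishing with Nelder-Mead.
    Returns (free_A, free_B, conc_AA, conc_AB, conc_BB) in molar.
    """
    T = total_A + total_B
    ld = np.longdouble

    def gibbs(z):
        cAA, cAB, cBB = (ld(10.0) ** ld(v) for v in z)  # in units of T
        a = ld(total_A) / ld(T) - 2 * cAA - cAB
        b = ld(total_B) / ld(T) - 2 * cBB - cAB
        if a <= 0 or b <= 0:
            return np.inf
        scale = ld(T) / ld(C0)
        G = a * (np.log(a * scale) - 1) + b * (np.log(b * scale) - 1)
        G += cAA * (np.log(cAA * scale) - 1 + ld(dG_AA / rt_kj))
        G += cBB * (np.log(cBB * scale) - 1 + ld(dG_BB / rt_kj))
        G += cAB * (np.log(cAB * scale / ld(g)) - 1 + ld(dG_AB / rt_kj))
        return float(G)

    grid = np.linspace(-14, math.log10(0.499), 16)
    best_z, best_g = None, np.inf
    for z in itertools.product(grid, repeat=3):
        val = gibbs(z)
        if val < best_g:
            best_g, best_z = val, z
    z = np.asarray(best_z)
    for _ in range(2):  # restart once: Nelder-Mead gains precision on re-seed
        res = optimize.minimize(
            gibbs,
            z,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": np.inf, "maxiter": 20000, "maxfev": 20000},
        )
        z = res.x
    cAA, cAB, cBB = (10.0**v * T for v in z)
    a = total_A - 2 * cAA - cAB
    b = total_B - 2 * cBB - cAB
    return a, b, cAA, cAB, cBB
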