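"""Irreversible mass-action model of mating encounters.

Mating-pair formation in a stirred suspension is modelled as the
bimolecular reaction a + α → pair with rate constant k: the density of
pairs x(t) obeys dx/dt = k·(a0 − x)(α0 − x) from x(0) = 0, where a0 and α0
are the initial MATa and MATα densities.  Pairing is strictly 1:1 and
irreversible (higher-order aggregates are excluded).  The observable is
the fraction of MATa cells that found a partner, x(t)/a0, which at long
times exhausts the minority type and tends to min(1, θ_α/(1−θ_α)) — at
high total density the encounter probability is set by the sex ratio
alone, mirroring what the mating-pathway response reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "EncounterParams",
    "pair_fraction_analytic",
    "pair_fraction_ode",
    "pair_fraction_limit",
    "encounter_grid",
]

# relative density difference below which the equal-density branch is used
_EQUAL_TOL = 1e-9


@dataclass(frozen=True)
class EncounterParams:
    """Collision-rate constant and reaction horizon (dimensionless units)."""

    k: float = 1.0
    t_horizon: float = 100.0

    def __post_init__(self):
        if self.k <= 0 or self.t_horizon <= 0:
            raise ValueError("k and t_horizon must be positive")


def _check_inputs(rho_a0, rho_alpha0, k, t):
    if rho_a0 <= 0:
        raise ValueError("rho_a0 must be positive")
    if rho_alpha0 < 0 or k < 0 or t < 0:
        raise ValueError("rho_alpha0, k and t must be non-negative")


def pair_fraction_analytic(rho_a0: float, rho_alpha0: float, k: float, t: float) -> float:
    """Closed-form fraction of MATa cells paired by time t.

    For unequal densities, with d = α0 − a0,

        x(t) = a0·α0·(e^{dkt} − 1) / (α0·e^{dkt} − a0),

    evaluated with the exponential of a negative argument on both branches
    so the expression stays stable as d·k·t → ±∞; for a0 = α0 the
    degenerate form x(t) = a0²kt/(1 + a0·k·t) applies (used whenever
    |d| < 1e-9·max(a0, α0) to avoid catastrophic cancellation).
    """
    _check_inputs(rho_a0, rho_alpha0, k, t)
    a0, b0 = float(rho_a0), float(rho_alpha0)
    if b0 == 0.0 or k == 0.0 or t == 0.0:
        return 0.0
    d = b0 - a0
    if abs(d) < _EQUAL_TOL * max(a0, b0):
        x = a0 * a0 * k * t / (1.0 + a0 * k * t)
    elif d > 0:
        e = math.exp(-d * k * t)
        x = a0 * b0 * (1.0 - e) / (b0 - a0 * e)
    else:
        e = math.exp(d * k * t)  # d < 0 so the argument is negative
        x = a0 * b0 * (1.0 - e) / (a0 - b0 * e)
    frac = x / a0
    return float(min(max(frac, 0.0), min(1.0, b0 / a0)))


def pair_fraction_ode(
    rho_a0: float, rho_alpha0: float, k: float, t: float,
    rtol: float = 1e-12, atol: float = 1e-14,
) -> float:
    """Numerical integration of dx/dt = k(a0−x)(α0−x); oracle for the closed form."""
    _check_inputs(rho_a0, rho_alpha0, k, t)
    if t == 0.0 or rho_alpha0 == 0.0 or k == 0.0:
        return 0.0
    sol = solve_ivp(
        lambda _t, x: [k * (rho_a0 - x[0]) * (rho_alpha0 - x[0])],
        (0.0, t), [0.0], method="Radau", rtol=rtol, atol=atol,
        jac=lambda _t, x: [[-k * ((rho_a0 - x[0]) + (rho_alpha0 - x[0]))]],
    )
    if not sol.success:
        raise RuntimeError(f"encounter ODE integration failed: {sol.message}")
    frac = float(sol.y[0, -1]) / rho_a0
    return min(max(frac, 0.0), min(1.0, rho_alpha0 / rho_a0))


def pair_fraction_limit(theta_alpha: float) -> float:
    """Long-time encounter fraction min(1, θ_α/(1−θ_α)).

    The minority type is exhausted: at θ_α ≥ 1/2 every MATa cell eventually
    pairs, below that the fraction is the partner-to-receiver ratio.
    """
    if not 0.0 <= theta_alpha < 1.0:
        raise ValueError("theta_alpha must lie in [0, 1) (some receivers required)")
    return min(1.0, theta_alpha / (1.0 - theta_alpha))


def encounter_grid(
    theta_values, rho_T_values, k: float = 1.0, t: float = 100.0
) -> pd.DataFrame:
    """Paired fraction over a (θ_α, ρ_T) grid, long format.

    Each cell evaluates the closed form at a0 = (1−θ)ρ_T, α0 = θρ_T.
    """
    theta_values = np.asarray(theta_values, dtype=float)
    rho_T_values = np.asarray(rho_T_values, dtype=float)
    if theta_values.size == 0 or rho_T_values.size == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for theta in theta_values:
        for rho_T in rho_T_values:
            frac = pair_fraction_analytic(
                (1.0 - theta) * rho_T, theta * rho_T, k, t
            )
            rows.append((theta, rho_T, k, t, frac))
    return pd.DataFrame(
        rows, columns=["theta_alpha", "rho_T", "k", "t", "fraction_paired"]
    )
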