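"""Well-mixed secrete-and-degrade pheromone communication model.

MATα cells emit α-factor at a constant per-cell rate while MATa cells emit
the protease Bar1, which degrades α-factor.  In a well-mixed culture with
constitutive secretion and sub-saturation (first-order) degradation the
extracellular concentrations obey

    dB/dt = β·ρ_a                      (Bar1 accumulates linearly)
    dP/dt = α_s·ρ_α − κ·B·P            (secretion minus degradation)

with ρ_a, ρ_α the receiver (MATa) and emitter (MATα) densities in OD600
units.  The pheromone transient has the closed form

    P(t) = (α_s·ρ_α / sqrt(κ·β·ρ_a)) · g(t·sqrt(κ·β·ρ_a)),
    g(τ) = exp(−τ²/2)·∫₀^τ exp(u²/2) du = sqrt(2)·D(τ/sqrt(2)),

where D is the Dawson function.  g attains its single maximum
g_max ≈ 0.765152 at τ* ≈ 1.306930, so the peak pheromone level scales as
ρ_α/√ρ_a — the emitted signal is attenuated by the square root of the
receiver density, which is what converts partner-density sensing into
sex-ratio sensing.  A Hill-type dose-response curve converts pheromone
level into P_FUS1-driven reporter output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import dawsn

__all__ = [
    "PopulationComposition",
    "CommunicationParams",
    "PheromoneTrajectory",
    "DoseResponseCurve",
    "FitResult",
    "G_MAX",
    "TAU_STAR",
    "SaturationWarning",
    "IdentifiabilityError",
    "simulate_pheromone",
    "peak_pheromone_analytic",
    "pheromone_bar1delta",
    "pheromone_closed_form",
    "dose_response",
    "predict_reporter",
    "fit_model",
]


def _g(tau):
    """Dimensionless pheromone transient g(τ) = √2·D(τ/√2)."""
    return math.sqrt(2.0) * dawsn(np.asarray(tau, dtype=float) / math.sqrt(2.0))


def _solve_g_max() -> tuple[float, float]:
    res = minimize_scalar(
        lambda t: -_g(t), bounds=(0.5, 3.0), method="bounded",
        options={"xatol": 1e-13},
    )
    return float(-res.fun), float(res.x)


#: Maximum of the dimensionless transient g and its location τ*.
G_MAX, TAU_STAR = _solve_g_max()


class SaturationWarning(UserWarning):
    """Pheromone exceeded 0.1·K_M: the linear-degradation assumption is strained."""


class IdentifiabilityError(ValueError):
    """The condition design cannot constrain the requested parameters."""


@dataclass(frozen=True)
class PopulationComposition:
    """Densities of the two mating types, in OD600 units.

    ``theta_alpha`` (fraction of emitters, the population sex ratio) and
    ``rho_T`` (total density) are derived.
    """

    rho_a: float
    rho_alpha: float

    def __post_init__(self):
        if not (np.isfinite(self.rho_a) and np.isfinite(self.rho_alpha)):
            raise ValueError("densities must be finite")
        if self.rho_a < 0 or self.rho_alpha < 0:
            raise ValueError("densities must be non-negative")
        if self.rho_a + self.rho_alpha <= 0:
            raise ValueError("total density must be positive")

    @property
    def theta_alpha(self) -> float:
        return self.rho_alpha / (self.rho_alpha + self.rho_a)

    @property
    def rho_T(self) -> float:
        return self.rho_alpha + self.rho_a

    @classmethod
    def from_ratio(cls, theta_alpha: float, rho_T: float) -> "PopulationComposition":
        """Build a composition from sex ratio and total density."""
        if not 0.0 <= theta_alpha <= 1.0:
            raise ValueError("theta_alpha must lie in [0, 1]")
        if rho_T <= 0:
            raise ValueError("rho_T must be positive")
        return cls(rho_a=(1.0 - theta_alpha) * rho_T, rho_alpha=theta_alpha * rho_T)


@dataclass(frozen=True)
class CommunicationParams:
    """Rates of the secrete-and-degrade model.

    alpha_secretion_rate
        α-factor concentration produced per unit emitter density per minute.
    bar1_secretion_rate
        Bar1 concentration produced per unit receiver density per minute.
    bar1_specific_activity
        First-order degradation constant per unit Bar1 concentration
        (lumped k_cat/K_M).
    K_M
        Michaelis constant of Bar1, μM; only used for the sub-saturation
        guard (the default model never saturates by construction).
    """

    alpha_secretion_rate: float = 1.0
    bar1_secretion_rate: float = 1.0
    bar1_specific_activity: float = 1.0
    K_M: float = 30.0
    P0: float = 0.0
    B0: float = 0.0

    def __post_init__(self):
        vals = (
            self.alpha_secretion_rate,
            self.bar1_secretion_rate,
            self.bar1_specific_activity,
            self.K_M,
            self.P0,
            self.B0,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite communication parameter")
        if any(v < 0 for v in vals[:3]) or self.P0 < 0 or self.B0 < 0:
            raise ValueError("rates and initial concentrations must be >= 0")
        if self.K_M <= 0:
            raise ValueError("K_M must be positive")

    @property
    def decay(self) -> float:
        """Lumped degradation rate κ·β (per density per minute²)."""
        return self.bar1_specific_activity * self.bar1_secretion_rate


@dataclass
class PheromoneTrajectory:
    """Time courses of extracellular α-factor (P) and Bar1 (B), minutes."""

    time: np.ndarray
    P: np.ndarray
    B: np.ndarray
    saturation_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time, "P": self.P, "B": self.B})

    @property
    def peak(self) -> tuple[float, float]:
        """(level, time) of the maximum pheromone concentration on the grid."""
        i = int(np.argmax(self.P))
        return float(self.P[i]), float(self.time[i])


@dataclass(frozen=True)
class DoseResponseCurve:
    """Saturating (Hill) conversion of α-factor level to reporter output."""

    r_max: float
    ec50: float
    hill_n: float = 1.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.r_max <= 0 or self.ec50 <= 0 or self.hill_n <= 0:
            raise ValueError("r_max, ec50 and hill_n must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")

    def __call__(self, P):
        return dose_response(P, self)


def pheromone_closed_form(comp: PopulationComposition, params: CommunicationParams, t):
    """Exact solution P(t) of the default (linear degradation) model.

    Vectorized over ``t``.  With no degradation (κ·β·ρ_a = 0) this reduces to
    the linear accumulation α_s·ρ_α·t + P0.  A nonzero P0 decays with the
    Gaussian factor exp(−κβρ_a t²/2).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    a = params.decay * comp.rho_a  # κ·β·ρ_a, the attenuation scale
    src = params.alpha_secretion_rate * comp.rho_alpha
    if a == 0.0:
        return params.P0 + src * t
    s = np.sqrt(a)
    return params.P0 * np.exp(-a * t * t / 2.0) + src / s * _g(t * s)


def simulate_pheromone(
    comp: PopulationComposition,
    params: CommunicationParams,
    t_end: float,
    n_points: int = 500,
    method: str = "adaptive",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> PheromoneTrajectory:
    """Integrate the communication ODEs on a uniform grid of ``n_points``.

    ``method="adaptive"`` uses a stiff-capable adaptive integrator;
    ``method="rk4"`` is a fixed-step validation mode whose step is the grid
    spacing (halve it by doubling ``n_points`` for convergence checks).
    Emits :class:`SaturationWarning` (and sets the trajectory flag) when the
    pheromone transient exceeds 0.1·K_M, where first-order degradation is no
    longer a good description of Bar1 kinetics.
    """
    if not (np.isfinite(t_end) and t_end > 0):
        raise ValueError("t_end must be positive and finite")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    t = np.linspace(0.0, float(t_end), int(n_points))
    src = params.alpha_secretion_rate * comp.rho_alpha
    beta_rho = params.bar1_secretion_rate * comp.rho_a
    kappa = params.bar1_specific_activity

    def rhs(ti, y):
        P, B = y
        return (src - kappa * B * P, beta_rho)

    y0 = (params.P0, params.B0)
    if method == "adaptive":
        sol = solve_ivp(rhs, (0.0, t[-1]), y0, method="LSODA", t_eval=t,
                        rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover - LSODA is robust on this system
            raise RuntimeError(f"integration failed: {sol.message}")
        P, B = sol.y
    elif method == "rk4":
        P, B = _rk4(rhs, y0, t)
    else:
        raise ValueError(f"unknown method {method!r}")

    P = np.maximum(P, 0.0)
    traj = PheromoneTrajectory(time=t, P=P, B=B)
    if P.max(initial=0.0) > 0.1 * params.K_M:
        traj.saturation_warning = True
        warnings.warn(
            "peak pheromone exceeds 0.1*K_M; sub-saturation assumption violated",
            SaturationWarning,
            stacklevel=2,
        )
    return traj


def _rk4(rhs, y0, t):
    y = np.empty((len(t), 2))
    y[0] = y0
    for i in range(len(t) - 1):
        h = t[i + 1] - t[i]
        yi = y[i]
        k1 = np.asarray(rhs(t[i], yi))
        k2 = np.asarray(rhs(t[i] + h / 2, yi + h / 2 * k1))
        k3 = np.asarray(rhs(t[i] + h / 2, yi + h / 2 * k2))
        k4 = np.asarray(rhs(t[i] + h, yi + h * k3))
        y[i + 1] = yi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y[:, 0], y[:, 1]


def peak_pheromone_analytic(
    comp: PopulationComposition, params: CommunicationParams
) -> tuple[float, float]:
    """Analytic peak of the pheromone transient: (level, time).

    peak level = g_max · α_s·ρ_α / sqrt(κ·β·ρ_a)  at  t* = τ*/sqrt(κ·β·ρ_a):
    proportional to the emitter density and inversely proportional to the
    square root of the receiver density.  Requires active degradation; for a
    bar1Δ population (no Bar1 source) the transient has no interior maximum
    and :func:`pheromone_bar1delta` applies instead.
    """
    a = params.decay * comp.rho_a
    if a <= 0.0:
        raise ValueError(
            "no interior peak without degradation (rho_a = 0 or Bar1 rate = 0); "
            "use pheromone_bar1delta"
        )
    if params.alpha_secretion_rate <= 0:
        raise ValueError("alpha_secretion_rate must be positive for a peak")
    s = math.sqrt(a)
    level = G_MAX * params.alpha_secretion_rate * comp.rho_alpha / s
    return level, TAU_STAR / s


def pheromone_bar1delta(comp: PopulationComposition, params: CommunicationParams, t):
    """Pheromone level without Bar1: linear accumulation α_s·ρ_α·t + P0.

    Independent of the receiver density ρ_a — a bar1Δ population reads the
    absolute emitter density, not the sex ratio.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = params.P0 + params.alpha_secretion_rate * comp.rho_alpha * t
    return float(out) if out.ndim == 0 else out


def dose_response(P, curve: DoseResponseCurve):
    """Hill conversion: baseline + r_max·Pⁿ/(ec50ⁿ + Pⁿ).  Vectorized."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("pheromone level must be non-negative")
    x = (P / curve.ec50) ** curve.hill_n
    out = curve.baseline + curve.r_max * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def predict_reporter(
    comp: PopulationComposition,
    params: CommunicationParams,
    curve: DoseResponseCurve,
    t_meas: float = 135.0,
    strain: str = "WT",
    mode: str = "peak",
) -> float:
    """Deterministic forward map from population composition to reporter level.

    For the wild type in ``peak`` mode the dose-response is applied to the
    maximum pheromone level reached by ``t_meas`` (the transient is unimodal,
    so this is P at min(t*, t_meas)); ``instantaneous`` mode uses P(t_meas).
    A bar1Δ strain accumulates pheromone linearly and both modes coincide
    with the level at ``t_meas``.
    """
    if t_meas <= 0:
        raise ValueError("t_meas must be positive")
    if strain not in ("WT", "bar1d"):
        raise ValueError(f"unknown strain {strain!r}: expected 'WT' or 'bar1d'")
    if mode not in ("peak", "instantaneous"):
        raise ValueError(f"unknown mode {mode!r}: expected 'peak' or 'instantaneous'")
    if strain == "bar1d" or params.decay * comp.rho_a == 0.0:
        P = pheromone_bar1delta(comp, params, t_meas)
    elif mode == "instantaneous":
        P = float(pheromone_closed_form(comp, params, t_meas))
    else:
        _, t_star = peak_pheromone_analytic(comp, params)
        P = float(pheromone_closed_form(comp, params, min(t_star, t_meas)))
    return float(dose_response(P, curve))


@dataclass
class FitResult:
    """Lumped-parameter least-squares fit of the communication model."""

    gain: float
    decay: float | None
    gain_se: float
    decay_se: float | None
    rss: float
    converged: bool
    n_obs: int = 0
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "gain": self.gain,
            "decay": self.decay,
            "gain_se": self.gain_se,
            "decay_se": self.decay_se,
            "rss": self.rss,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def fit_model(
    dataset: pd.DataFrame,
    strain: str,
    curve: DoseResponseCurve,
    t_meas: float = 135.0,
    initial: tuple[float, float] = (1.0, 1.0),
    bounds: tuple[float, float] = (1e-8, 1e8),
) -> FitResult:
    """Fit the identifiable lumped parameters to a reporter dataset.

    Only two combinations of the secretion/degradation rates are identifiable
    from end-point reporter data: the gain α_s (pheromone produced per unit
    emitter density per minute, as seen through the fixed dose-response) and,
    for the wild type, the decay κ·β.  The fit is ordinary least squares on
    the reporter scale, parameterized in log space to enforce positivity.

    The dataset needs columns ``rho_a``, ``rho_alpha``, ``reporter``.  A
    design with fewer than two distinct compositions (or, for the wild type,
    no variation in the peak's two natural coordinates ρ_α and ρ_α/√ρ_a)
    raises :class:`IdentifiabilityError`.  Non-convergence is reported via
    the ``converged`` flag rather than an exception.

    Note that if every condition has already peaked by ``t_meas`` the data
    constrain only the ratio gain/√decay (the peak law contains the rates in
    that combination alone): the fit then sits on a flat ridge and the
    reported standard errors blow up accordingly.  Designs measured early
    enough that some conditions are still rising identify both parameters.
    """
    if strain not in ("WT", "bar1d"):
        raise ValueError(f"unknown strain {strain!r}")
    df = dataset
    comps = df[["rho_a", "rho_alpha"]].drop_duplicates()
    if len(comps) < 2:
        raise IdentifiabilityError(
            f"need >= 2 distinct compositions, got {len(comps)}"
        )
    y = df["reporter"].to_numpy(dtype=float)
    rho_a = df["rho_a"].to_numpy(dtype=float)
    rho_alpha = df["rho_alpha"].to_numpy(dtype=float)

    if strain == "bar1d":
        x0 = np.log([initial[0]])
    else:
        # decay only identifiable if rho_alpha/sqrt(rho_a) varies independently
        with np.errstate(divide="ignore"):
            ratio = np.where(rho_a > 0, rho_alpha / np.sqrt(np.maximum(rho_a, 1e-300)), np.inf)
        if np.ptp(ratio[np.isfinite(ratio)]) == 0 and np.ptp(rho_a) == 0:
            raise IdentifiabilityError("design cannot separate gain and decay")
        x0 = np.log([initial[0], initial[1]])

    def predict(theta_log):
        # vectorized forward map: peak (or end-point) pheromone -> reporter
        alpha_s = math.exp(theta_log[0])
        if strain == "bar1d":
            P = alpha_s * rho_alpha * t_meas
        else:
            decay = math.exp(theta_log[1])
            a = decay * rho_a
            s = np.sqrt(np.maximum(a, 1e-300))
            t_eff = np.minimum(TAU_STAR / s, t_meas)
            P = np.where(
                a > 0, alpha_s * rho_alpha / s * _g(t_eff * s),
                alpha_s * rho_alpha * t_meas,
            )
        return dose_response(P, curve)

    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    res = least_squares(
        lambda th: predict(th) - y, x0,
        bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    rss = float(res.fun @ res.fun)
    n, p = len(y), len(res.x)
    sigma2 = rss / max(n - p, 1)
    try:
        cov_log = sigma2 * np.linalg.inv(res.jac.T @ res.jac)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(p, np.nan)
    est = np.exp(res.x)
    se = est * se_log  # delta method back from log scale
    return FitResult(
        gain=float(est[0]),
        decay=float(est[1]) if strain == "WT" else None,
        gain_se=float(se[0]),
        decay_se=float(se[1]) if strain == "WT" else None,
        rss=rss,
        converged=bool(res.status > 0),
        n_obs=n,
        message=res.message,
    )
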