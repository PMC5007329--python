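"""Seeded synthetic datasets with the structure of the flow-cytometry assays.

Four generators emulate the measurement processes the statistics pipeline
consumes, so every analysis stage can run — and be validated against known
ground truth — without external data:

* :func:`generate_reporter_dataset` — per-condition P_FUS1-GFP reporter
  values over a (ρ_a, ρ_α) design grid with replicates, built on the
  communication model's forward map plus additive Gaussian replicate noise
  (truncated at zero; a lognormal option is available).
* :func:`generate_event_table` — two-colour per-event tables (forward
  scatter, green, red) with ground-truth classes a_only / alpha_only / pair
  for aggregation gating.
* :func:`generate_aggregation_dataset` / :func:`generate_growth_dataset` —
  linear ground-truth tables for the regression stages (fraction aggregated
  or mated vs sex ratio; relative growth vs pathway induction).

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import (
    CommunicationParams,
    DoseResponseCurve,
    PopulationComposition,
    pheromone_bar1delta,
    pheromone_closed_form,
    peak_pheromone_analytic,
    predict_reporter,
)

__all__ = [
    "DEFAULT_PARAMS",
    "DEFAULT_CURVE",
    "DEFAULT_THETA_GRID",
    "DEFAULT_RHO_T_GRID",
    "default_design",
    "generate_reporter_dataset",
    "generate_event_table",
    "generate_aggregation_dataset",
    "generate_growth_dataset",
]

#: Communication-model parameters used as the generator's study conditions.
#: Concentrations are in units of the dose-response EC50 scale (a.u.);
#: densities in OD600, time in minutes.  With these rates the wild-type peak
#: pheromone stays below the shmooing threshold across the design grid while
#: a bar1Δ strain saturates the reporter and shmoos already at low emitter
#: densities, mirroring the measured phenotypes.
DEFAULT_PARAMS = CommunicationParams(
    alpha_secretion_rate=1.0,
    bar1_secretion_rate=1.0,
    bar1_specific_activity=1.0,
)

#: Hill dose-response of the reporter, EC50 = 1 concentration unit.
DEFAULT_CURVE = DoseResponseCurve(r_max=1000.0, ec50=1.0, hill_n=1.0, baseline=0.0)

#: Sex-ratio grid: eight interior levels, endpoints trimmed.
DEFAULT_THETA_GRID = tuple(i / 9.0 for i in range(1, 9))
#: Total densities, OD600.
DEFAULT_RHO_T_GRID = (0.1, 0.3, 0.9)

#: Replicate noise, a.u. of reporter fluorescence (≈2% of the reporter span,
#: consistent with the small replicate s.e.m. of averaged flow-cytometry
#: reporter values).
DEFAULT_NOISE_SD = 20.0

DEFAULT_T_MEAS = 135.0


def default_design(
    theta_grid=DEFAULT_THETA_GRID, rho_T_grid=DEFAULT_RHO_T_GRID
) -> pd.DataFrame:
    """Condition design mirroring the mixed-culture grid: 8 sex ratios ×
    3 total densities (72 observations with 3 replicates)."""
    rows = [
        ((1.0 - th) * rt, th * rt)
        for th in theta_grid
        for rt in rho_T_grid
    ]
    return pd.DataFrame(rows, columns=["rho_a", "rho_alpha"])


def generate_reporter_dataset(
    design: pd.DataFrame | None = None,
    params: CommunicationParams = DEFAULT_PARAMS,
    curve: DoseResponseCurve = DEFAULT_CURVE,
    strain: str = "WT",
    noise_sd: float = DEFAULT_NOISE_SD,
    n_rep: int = 3,
    seed: int | None = 0,
    shmoo_threshold: float | None = None,
    t_meas: float = DEFAULT_T_MEAS,
    noise: str = "gaussian",
) -> pd.DataFrame:
    """Long-format reporter table over the design grid.

    Each replicate draws reporter = forward model + noise (Gaussian with
    s.d. ``noise_sd``, truncated at zero; ``noise="lognormal"`` multiplies
    instead by a lognormal factor of matched relative spread).  The shmoo
    flag marks conditions whose peak pheromone level exceeds
    ``shmoo_threshold`` (default 10× the dose-response EC50).
    """
    if design is None:
        design = default_design()
    if len(design) == 0:
        raise ValueError("design grid is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_rep < 1:
        raise ValueError("n_rep must be at least 1")
    if noise not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown noise model {noise!r}")
    if shmoo_threshold is None:
        shmoo_threshold = 10.0 * curve.ec50
    rng = np.random.default_rng(seed)
    rows = []
    for rho_a, rho_alpha in design[["rho_a", "rho_alpha"]].itertuples(index=False):
        comp = PopulationComposition(rho_a=float(rho_a), rho_alpha=float(rho_alpha))
        mean = predict_reporter(comp, params, curve, t_meas=t_meas, strain=strain)
        if strain == "bar1d" or params.decay * comp.rho_a == 0.0:
            p_level = pheromone_bar1delta(comp, params, t_meas)
        else:
            _, t_star = peak_pheromone_analytic(comp, params)
            p_level = float(
                pheromone_closed_form(comp, params, min(t_star, t_meas))
            )
        shmoo = bool(p_level > shmoo_threshold)
        for rep in range(1, n_rep + 1):
            if noise_sd == 0.0:
                value = mean
            elif noise == "gaussian":
                value = max(0.0, mean + rng.normal(0.0, noise_sd))
            else:
                cv = noise_sd / max(mean, 1e-12)
                s = np.sqrt(np.log1p(cv * cv))
                value = mean * rng.lognormal(-0.5 * s * s, s)
            rows.append(
                (
                    comp.rho_a,
                    comp.rho_alpha,
                    comp.theta_alpha,
                    comp.rho_T,
                    strain,
                    rep,
                    t_meas,
                    value,
                    shmoo,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rho_a",
            "rho_alpha",
            "theta_alpha",
            "rho_T",
            "strain",
            "replicate",
            "time_min",
            "reporter",
            "shmoo",
        ],
    )


def generate_event_table(
    n_events: int = 47_000,
    theta_alpha: float = 0.5,
    pair_prob: float = 0.2,
    green_mean: float = 1000.0,
    green_sd: float = 100.0,
    red_mean: float = 1000.0,
    red_sd: float = 100.0,
    background_mean: float = 10.0,
    background_sd: float = 5.0,
    fsc_mean: float = 100.0,
    fsc_sd: float = 10.0,
    seed: int | None = 0,
    aga2_null: bool = False,
) -> pd.DataFrame:
    """Per-event two-colour table for aggregation gating.

    A fraction ``pair_prob`` of MATa cells is aggregated with a MATα partner
    (a pair is one event carrying both green and red signal); ``aga2_null``
    emulates the non-agglutinating control by forcing that fraction to zero.
    The default 47,000 events mirror the mean flow-cytometry sample size.
    Event classes are drawn multinomially; channel values are Gaussian with
    the stated means/s.d.s, truncated at zero, and pairs get a larger
    forward-scatter signal.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    if not 0.0 <= pair_prob <= 1.0:
        raise ValueError("pair_prob must lie in [0, 1]")
    if not 0.0 <= theta_alpha <= 1.0:
        raise ValueError("theta_alpha must lie in [0, 1]")
    if min(green_sd, red_sd, background_sd, fsc_sd) < 0:
        raise ValueError("channel standard deviations must be non-negative")
    if aga2_null:
        pair_prob = 0.0
    rng = np.random.default_rng(seed)
    frac_a, frac_alpha = 1.0 - theta_alpha, theta_alpha
    # a cells that pair consume one alpha cell each; cap at the available alphas
    paired = min(pair_prob * frac_a, frac_alpha)
    probs = np.array([frac_a - paired, frac_alpha - paired, paired])
    probs = probs / probs.sum()
    classes = rng.choice(3, size=n_events, p=probs)
    labels = np.array(["a_only", "alpha_only", "pair"])[classes]

    green = rng.normal(background_mean, background_sd, n_events)
    red = rng.normal(background_mean, background_sd, n_events)
    is_a = classes != 1
    is_alpha = classes != 0
    green[is_a] = rng.normal(green_mean, green_sd, int(is_a.sum()))
    red[is_alpha] = rng.normal(red_mean, red_sd, int(is_alpha.sum()))
    fsc = rng.normal(fsc_mean, fsc_sd, n_events)
    fsc[classes == 2] = rng.normal(2.0 * fsc_mean, fsc_sd, int((classes == 2).sum()))
    return pd.DataFrame(
        {
            "fsc": np.maximum(fsc, 1e-6),
            "green": np.maximum(green, 0.0),
            "red": np.maximum(red, 0.0),
            "true_class": labels,
        }
    )


def generate_aggregation_dataset(
    theta_grid=DEFAULT_THETA_GRID,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.08,
    n_rep: int = 3,
    seed: int | None = 0,
    time_min: float = 259.0,
) -> pd.DataFrame:
    """Fraction of MATa cells aggregated/mated vs sex ratio.

    Ground truth is linear through the origin by default (fraction =
    slope·θ_α), as the aggregation and mating assays report, with Gaussian
    replicate noise clipped to [0, 1].
    """
    if noise_sd < 0 or n_rep < 1:
        raise ValueError("noise_sd must be >= 0 and n_rep >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for theta in theta_grid:
        mean = intercept + slope * theta
        for rep in range(1, n_rep + 1):
            val = mean if noise_sd == 0 else mean + rng.normal(0.0, noise_sd)
            rows.append((theta, time_min, rep, float(np.clip(val, 0.0, 1.0))))
    return pd.DataFrame(
        rows, columns=["theta_alpha", "time_min", "replicate", "fraction"]
    )


def generate_growth_dataset(
    levels=None,
    intercept: float = 0.897,
    slope: float = -1.51e-4,
    noise_sd: float = 0.17,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Relative growth vs reporter induction level.

    Defaults follow the measured dose-dependent growth reduction: an
    ordinary linear trend with intercept near 0.9 and a small negative slope
    per a.u. of reporter output, plus Gaussian noise, floored just above
    zero (relative growth is positive).
    """
    if levels is None:
        levels = np.linspace(0.0, 2000.0, 24)
    levels = np.asarray(levels, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    mean = intercept + slope * levels
    if noise_sd == 0:
        growth = mean
    else:
        growth = mean + rng.normal(0.0, noise_sd, size=levels.shape)
    growth = np.maximum(growth, 1e-9)
    return pd.DataFrame(
        {
            "reporter": levels,
            "replicate": np.ones(len(levels), dtype=int),
            "relative_growth": growth,
        }
    )
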