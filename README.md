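# matesense

Models and statistics of Bar1-mediated **sex-ratio sensing** in budding
yeast.

When *Saccharomyces cerevisiae* haploids mate in suspension, the first step
is a chance encounter between a MATa cell and a MATα cell. MATα cells
advertise themselves with the α-factor pheromone; MATa cells secrete the
protease Bar1, which degrades it. Because the degradation capacity grows
with the density of MATa cells, the pheromone level any one MATa cell
experiences reports not the raw partner density ρ_α but (approximately) the
population's sex ratio θ_α = ρ_α/(ρ_α + ρ_a) — exactly the quantity that
predicts its chance of finding a partner. This package implements, as
reusable and tested components, the three computational models behind that
claim and the statistical pipeline used to test it, for quantitative
biologists studying microbial communication and mating strategy:

1. **Communication model** (`matesense.core_model`) — well-mixed
   secrete-and-degrade ODEs, dB/dt = β·ρ_a, dP/dt = α_s·ρ_α − κ·B·P, with
   the exact peak solution P_max = g_max·α_s·ρ_α/√(κ·β·ρ_a)
   (g_max ≈ 0.76515): emitted signal attenuated by the **square root** of
   receiver density. A Hill dose-response converts pheromone into
   P_FUS1-GFP reporter output, and `fit_model` recovers the lumped
   gain/decay parameters from reporter data.
2. **Encounter model** (`matesense.encounter`) — irreversible mass-action
   pairing a + α → pair, with closed-form and ODE solutions; at high total
   density the fraction of receivers that find a partner collapses onto
   min(1, θ_α/(1−θ_α)), a function of the sex ratio alone.
3. **Strategy-fitness model** (`matesense.fitness`) — cost–benefit
   comparison W = λ·m + (1−m)(1−c·I) of sex-ratio sensing against
   per-environment-optimized partner-density sensing and constitutive
   induction, over populations of environments (θ_α truncated-normal,
   ρ_T log-uniform).
4. **Synthetic data + statistics** (`matesense.synthetic`,
   `matesense.stats`) — seeded generators with the structure of the
   flow-cytometry assays (72-row factorial reporter designs, two-colour
   event tables, linear aggregation/growth tables), and the matching
   pipeline: factorial GLM with per-term F-tests, through-origin and
   ordinary regression, one-tailed t and Mann–Whitney U tests with
   Bonferroni correction, FSC normalization and threshold gating.

See `docs/methods.md` for model assumptions, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
from matesense import (
    PopulationComposition, CommunicationParams, DoseResponseCurve,
    peak_pheromone_analytic, predict_reporter, pair_fraction_analytic,
    generate_reporter_dataset, fit_glm,
)

params = CommunicationParams()            # alpha_s = beta = kappa = 1
curve = DoseResponseCurve(r_max=1000, ec50=1.0)

for theta in (0.25, 0.50, 0.75):
    comp = PopulationComposition.from_ratio(theta, rho_T=0.3)
    peak, t_star = peak_pheromone_analytic(comp, params)
    r = predict_reporter(comp, params, curve)          # 135 min end point
    enc = pair_fraction_analytic(comp.rho_a, comp.rho_alpha, k=1.0, t=100.0)
    print(f"theta={theta:.2f}  peak P={peak:.3f} at t*={t_star:.1f} min  "
          f"reporter={r:.0f} a.u.  encounter fraction={enc:.3f}")

table = generate_reporter_dataset(strain="WT", seed=0)  # 72-row synthetic set
res = fit_glm(table, ["theta_alpha", "rho_T"])
print(f"GLM (n={res.n_obs}, df_resid={res.df_resid}): "
      f"F_theta={res.fvalues['theta_alpha']:.0f}")
```

prints

```
theta=0.25  peak P=0.121 at t*=2.8 min  reporter=108 a.u.  encounter fraction=0.333
theta=0.50  peak P=0.296 at t*=3.4 min  reporter=229 a.u.  encounter fraction=0.938
theta=0.75  peak P=0.629 at t*=4.8 min  reporter=386 a.u.  encounter fraction=1.000
GLM (n=72, df_resid=69): F_theta=867
```

Reading this: at fixed total density the peak pheromone — and hence the
reporter — rises steeply with the sex ratio (θ_α enters as θ_α/√(1−θ_α)
before Hill compression), tracking the encounter fraction a MATa cell can
expect; the factorial GLM on a replicate-noise synthetic dataset finds the
sex-ratio term overwhelmingly significant with 69 residual degrees of
freedom, the design scale of the original analyses.

## Command line

```sh
matesense simulate --rho-a 0.5 --rho-alpha 0.5 --t-end 135 --out out/
matesense encounters --out out/            # (theta, rho_T) pairing grid
matesense fitness-map --out out/           # W_WT / W_opt-density ratio map
matesense fitness-lambda --out out/        # averaged ratio vs lambda
matesense synth --strain WT --seed 1 --out out/
matesense stats --dataset out/reporter_WT.csv --out out/
matesense reproduce fig4de_fitness --out out/
```

All commands accept `--config` (YAML/TOML), `--seed` and `--out`; every
run writes its outputs as CSV plus a `provenance.yaml` recording config,
seed and package version. `reproduce` regenerates the figure-analog data
bundles (`fig2ab_model`, `fig2gh_encounters`, `fig4de_fitness`,
`stats_report`) end to end.

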