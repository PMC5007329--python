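# Methods

`matesense` implements three small quantitative models of pheromone-based
mate sensing in budding yeast, a synthetic-data generator that emulates the
flow-cytometry experiments used to probe them, and the statistical pipeline
that connects the two. This note records the models, their assumptions, the
default parameter choices and why they were made, and what the synthetic
data do and do not establish.

## 1. Secrete-and-degrade communication model

A well-mixed co-culture contains emitters (MATα, density ρ_α in OD600
units) secreting the α-factor pheromone and receivers (MATa, density ρ_a)
secreting the protease Bar1, which degrades α-factor. The default model is
the minimal constitutive form

    dB/dt = β·ρ_a,
    dP/dt = α_s·ρ_α − κ·B·P,

with B the extracellular Bar1 concentration, P the α-factor concentration,
β and α_s per-density secretion rates (min⁻¹) and κ the Bar1 specific
activity (the lumped k_cat/K_M). Assumptions, each with its biological
justification:

* **constitutive Bar1** — basal Bar1 secretion suffices for the sex-ratio
  response; pheromone-dependent Bar1 induction occurs above the reporter's
  sensitive range and is omitted;
* **sub-saturation degradation** — Bar1's Michaelis constant (≈30 μM) is
  orders of magnitude above signalling-relevant pheromone levels, so
  degradation is first order in P. `simulate_pheromone` sets a warning flag
  whenever max P exceeds 0.1·K_M (a conservative guard; violation is
  expected and harmless for protease-null scenarios, where no Bar1 acts);
* **isotropic, shared Bar1** — no cell-wall-bound pool, no spatial
  gradients; the model is a pair of well-mixed ODEs;
* **constitutive pheromone production** — no mutual induction of
  pheromone secretion.

With B(0)=P(0)=0 the pheromone transient has the exact solution
P(t) = (α_s ρ_α/√(κβρ_a))·g(t√(κβρ_a)) with
g(τ) = e^(−τ²/2)∫₀^τ e^(u²/2)du = √2·D(τ/√2) (D the Dawson function).
g has a single interior maximum g_max = 0.7651520803 at τ* = 1.3069297388
(solved once at import by bounded minimization of −g), so

    P_max = g_max · α_s·ρ_α / √(κ·β·ρ_a).

The peak is linear in the emitter density and attenuated by the **square
root** of the receiver density: after the saturating reporter conversion
this makes the response depend mostly on the sex ratio
θ_α = ρ_α/(ρ_α+ρ_a) and only weakly on total density. Without Bar1
(bar1Δ), P = α_s·ρ_α·t: the receiver reads absolute partner density.

Numerics. `simulate_pheromone` integrates with LSODA at rtol 1e-9 /
atol 1e-12 on a uniform output grid; a fixed-step RK4 mode exists for
step-halving convergence checks. `predict_reporter` and `fit_model` use
the closed form directly (it is the exact solution of the default model).
Alternative model variants (Bar1 at steady state, Michaelis–Menten
degradation) were deliberately left out of the default path: the minimal
form reproduces the square-root law exactly and adding unidentifiable
terms would only blur the fits.

Reporter conversion is a Hill function
R = baseline + r_max·Pⁿ/(ec50ⁿ+Pⁿ), defaults n = 1, baseline = 0.
The *peak* pheromone level reached by the measurement time (default
t_meas = 135 min, the end-point of the mixed-culture reporter assay) is
converted; an `instantaneous` mode exists for sensitivity analysis.

`fit_model` estimates the two identifiable lumped parameters — gain α_s
and decay κβ — by least squares in log space. Identifiability caveat: once
every condition in a design has passed its pheromone peak, the data
constrain only α_s/√(κβ); designs that include still-rising conditions
(early measurement times) identify both parameters, and the recovery tests
use such a design. Standard errors come from the Gauss–Newton Jacobian
with the delta method back from the log scale.

## 2. Mass-action encounter model

Pair formation in suspension is the irreversible bimolecular reaction
a + α → pair, dx/dt = k(a₀−x)(α₀−x), pairs strictly 1:1 (higher-order
aggregation excluded, as in the experiments, which held total density low
to prevent it). The closed form is evaluated with negative-argument
exponentials on both branches for stability, and densities within 1e-9
relative switch to the equal-density branch x = a₀²kt/(1+a₀kt) to avoid
catastrophic cancellation. The observable is the fraction of receivers
paired, x/a₀, with long-time limit min(1, θ_α/(1−θ_α)): at high total
density (k·ρ_T·t ≳ 100) encounter probability is a function of the sex
ratio alone, the quantity the communication model lets a cell estimate
*before* committing. The rate constant k is not experimentally determined;
the default k = 1 with horizon t = 100 is the dimensionless convention of
the simulation the package mirrors, and the CLI exposes k for sweeps.

## 3. Strategy-fitness model

A cell chooses induction I ∈ [0,1]; mating efficiency is m = min(I, θ_α)
(induction pays only up to the available-partner fraction); fitness is

    W = λ·m + (1−m)·(1−c·I),

with λ the benefit of the diploid state and c the growth cost of full
induction borne by cells that stay haploid. Strategies:
sex-ratio sensor I = θ_α·min(1, ρ_T/ρ_ref); density sensor
I = min(1, s·θ_α·ρ_T); constitutive I = i0. Environments are drawn with
θ_α ~ Normal(μ_θ, σ_θ) truncated to [0,1] (renormalized density, so
quadrature is deterministic) and ρ_T log-uniform on [e^−γ, e^γ].
Mean fitness uses 64×64 Gauss–Legendre quadrature with weights normalized
to unit mass (exact for constants, robust to the kinks the min rules
introduce); a seeded Monte Carlo mode cross-validates it. The opposing
strategies are optimized per environment distribution (log-grid bracketing
plus bounded golden-section refinement), so the sex-ratio sensor's
advantage is never an artifact of a handicapped opponent.

Parameter defaults and their rationale:

* λ = 2.1 — the reference benefit-of-diploidy value of the comparison.
* μ_θ = 0.5, ρ_ref = 1 (the centre of the log-density support).
* c = 0.9. The cost coefficient is not experimentally pinned down; it
  controls where the advantage window sits on the λ axis. With the
  functional forms above, c = 0.9 places λ = 2.1 inside the window in
  which the sex-ratio sensor beats both the per-distribution-optimized
  density sensor and the best constitutive level (the window is roughly
  λ ∈ [1.5, 2.6] against the density sensor); at substantially lower cost
  (e.g. c = 0.5) the window closes below 2.1, i.e. moderate costs are part
  of the regime the model describes. c is a first-class parameter
  everywhere.
* ratio-vs-λ curves average the per-cell ratio over
  σ_θ ∈ {0.1, 0.2, 0.3} × γ ∈ {1, 2, 3}, the moderate-to-high-variance
  region of the map — environmental variance is the resource the sex-ratio
  sensor exploits, and with a mostly zero-variance averaging set the
  comparison degenerates towards 1 by construction.

Behaviour worth knowing: at zero environmental variance the optimized
density sensor can mimic any fixed induction level, so the fitness ratio
is exactly 1 (never above — this is a built-in sanity check); the
advantage grows along the variance diagonal and collapses below 1 for
large λ, where unconditional investment wins.

## 4. Synthetic data generator

The generator emulates the *structure* of the flow-cytometry experiments:
per-condition reporter means from the communication model's forward map
over an 8 × 3 design grid (θ_α = 1/9 … 8/9 with endpoints trimmed,
ρ_T ∈ {0.1, 0.3, 0.9} OD600, 3 replicates → 72 observations, matching the
residual degrees of freedom 68/69 of the printed factorial analyses), plus
additive Gaussian replicate noise truncated at zero (lognormal optional).
Default communication parameters are the dimensionless reference set
α_s = β = κ = 1 with a Hill curve r_max = 1000 a.u., ec50 = 1; in these
units the wild-type peak stays below the shmooing threshold (10·ec50)
across the grid while the protease-null strain overshoots it at moderate
emitter densities — the two qualitative phenotypes of the assay. The
replicate noise default (s.d. 20 a.u., 2% of the reporter ceiling) is a
stand-in — replicate scatter was never published numerically — calibrated
so the generator reproduces the assay's statistical fingerprint: much
smaller noise lets the factorial GLM read the Hill curvature as a spurious
interaction, much larger noise drowns the (saturating) emitter-density
dependence of the protease-null response.

Event tables draw a_only/alpha_only/pair classes multinomially
(default 47,000 events, the assays' mean sample size), give pairs both
fluorophores and doubled forward scatter, and separate signal from
background by ≥ 6 s.d. so that threshold gating is error-free in practice
and gating tests are deterministic.

What passing on synthetic data does **not** show: the generator assumes
the forward model is the truth, noise is homoscedastic and independent,
and gating populations are cleanly separable. Real flow-cytometry data
have autofluorescence tails, doublet artifacts and condition-dependent
noise; conclusions about the pipeline's behaviour on real data are limited
accordingly.

## 5. Statistical pipeline

* GLM: normal family, identity link — ordinary least squares on an
  explicit design matrix. Per-term tests are coefficient Wald tests,
  F = t² on (1, df_resid) degrees of freedom, matching the F_{1,68} /
  F_{1,69} pattern of a 72-row design; sequential (Type I) sums of squares
  are not used. Rank-deficient designs raise an error naming the collinear
  terms.
* Through-origin regression: slope = Σxy/Σx²; R² uses the uncentered
  total sum of squares Σy² (conventions differ for no-intercept models;
  this choice is stated explicitly and matches the convention of the
  original analyses).
* t-tests: two-sample, one-tailed, pooled variance by default (Welch
  behind a flag); both samples constant and equal yields the p = 0.5
  convention with a degeneracy flag. Bonferroni correction multiplies by
  the number of comparisons and caps at 1.
* Mann–Whitney U: exact by full enumeration of rank assignments for
  n1+n2 ≤ 16 (valid under ties; ~12,870 arrangements at worst), normal
  approximation with tie and continuity correction above that.
* Gating: pair gate = both channels above threshold; aggregated fraction
  = pairs/(pairs + free MATa). Thresholds below background trigger a
  degenerate-gate warning.

## 6. Problem sizes

Default sizes were chosen so the full pipeline re-runs comfortably on a
single CPU: 200-seed studies for the GLM fingerprint and slope-recovery
rates, 100 random instances for the encounter oracle comparison, 64-node
quadrature per axis for mean fitness, 47,000-event gating tables, and
13-point three-decade grids for the scaling law.

## 7. Known limitations

* The communication model is deliberately minimal; dilution, basal
  pheromone decay and induced Bar1 expression are absent, and the
  constant prefactor of the peak law is the g_max of this minimal model.
* The encounter model is deterministic mass action; no stochastic
  (agent-level) variant is provided.
* The fitness model is schematic: linear benefit/cost combination, no
  evolutionary dynamics, and λ intentionally unmodelled mechanistically.
* The exact functional forms of induction, the min-rule mating efficiency
  and the fitness combination are reconstructions of a schematic model
  from its narrative description; each is a single, replaceable function.
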