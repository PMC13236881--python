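# Methods

## The measurement problem

`arsbind` analyses binding experiments in which a receptor protein is
covalently immobilized on micron-scale biosilica spheres and the sphere
suspension is used as a solid-phase adsorbent for a dissolved ligand
(arsenite, As(III), in the motivating system).  After incubation the spheres
are pelleted and the ligand on the pellet is quantified, so the primary
observable is the *bound* amount; the free concentration is obtained by
difference from the known total.  Treating each sphere as a molecule turns
particle counts into molarities and lets per-particle binding-site numbers
(order 10⁷) and association constants be estimated on a single micromolar
scale.

## Particle accounting

A suspension at mass concentration *c* (g/L) with *N* counted particles per
gram has particle molarity *cN/N_A* and particle molar mass *N_A/N*, with
Avogadro's constant fixed at its exact SI value 6.02214076 × 10²³ mol⁻¹.
All concentrations are carried internally in μM; reports rescale to the
field's display conventions (K_A in 10⁶ M⁻¹, site numbers in 10⁷ per
particle) only at the edges.  The default ligand is arsenic at 74.92 g/mol,
overridable per `LigandSpec`.

## Equilibrium model and Scatchard estimator

Binding is modelled as 1:1 on *n* independent, identical sites per particle.
With total site concentration *C = n[S]* (μM) and association constant *K_A*
(μM⁻¹), the bound ligand at equilibrium satisfies the Langmuir relation
*b = C K_A f/(1 + K_A f)* together with conservation *f + b = T*.  The
per-particle occupancy μ = b/[S] linearizes this to the Scatchard form

    f/μ = K_D/n + f/n .

Occupancy is carried in units of 10⁷ sites (μ_scaled = μ/10⁷), so the
regression of *y = f/μ_scaled* on *x = f* has order-one slope and

    n = 10⁷/slope,   K_A = slope/intercept  (μM⁻¹ ≡ 10⁶ M⁻¹).

This scale convention makes the regression coefficients directly comparable
with conventionally tabulated Scatchard equations.  Standard errors of K_A
and n are propagated from the OLS parameter covariance by the delta method.
Replicate points are averaged per concentration before the transform.
Zero-bound points are skipped (logged); a non-positive fitted intercept makes
K_A undefined and raises an error that still carries the raw line fit.

The full estimator (`affinity_from_isotherm`) runs transform → linear-segment
selection → regression.  The segment selector exhaustively scores every
contiguous window of at least `min_len` points (default 4) and returns the
longest one with OLS R² ≥ `r2_min` (default 0.99, consistent with the fit
quality this assay class reports); ties go to higher R², then to the earlier
window.  Perfectly flat windows are never candidates — a saturation plateau
is "linear" in the trivial sense but carries no information about the rising
regime.  No blank (bare-particle) subtraction is applied by default, since
control preparations are normally fitted separately; an optional
blank-corrected mode subtracts a control's bound amounts matched on total
ligand.

For noiseless Langmuir data the Scatchard plot is exactly linear, so the
linearization introduces no bias and generative parameters are recovered to
numerical precision; this is asserted in tests, alongside an independent
nonlinear Langmuir fit (scipy `curve_fit`) that must agree within 0.5%.

## Adsorption kinetics

Uptake time courses Q_t (μg adsorbate per g adsorbent) are fitted with the
two standard empirical rate laws via their linearizations:

* pseudo-first-order: ln(Q_e − Q_t) = ln Q_e − k t; OLS on t gives
  k = −slope (h⁻¹) and Q_e = e^intercept;
* pseudo-second-order: t/Q_t = 1/(k Q_e²) + t/Q_e; OLS on t gives
  Q_e = 1/slope and k = slope²/intercept (g·μg⁻¹·h⁻¹).

The Q_e entering the first-order log transform is the supplied plateau when
available, otherwise the maximum observed Q_t.  Points outside a model's
domain (Q_t ≥ Q_e; t ≤ 0 or Q_t = 0) are excluded and counted, never
perturbed.  Model selection keeps the higher R²; an exact tie prefers the
pseudo-second-order model, whose superiority is conventionally read as
chemisorption control — consistent with thiol-coordination binding chemistry.
Linearized least squares is the primary estimator because it is what this
assay literature tabulates; a nonlinear refit is provided purely as a
diagnostic.

## Competitive immobilized-vs-free inference

To test whether immobilization changes affinity, the immobilized receptor R
(site pool n[S], constant K_D1) competes with a free protein P (K_D2) for
the same ligand.  At equilibrium

    [R]_f/[R]_b = ([P]_f/[P]_b) · (K_D1/K_D2),

a zero-intercept line whose slope is the affinity ratio.  Mass balances are
closed from the single observable [R]_b by neglecting free ligand
([P]_b = total − [R]_b), valid when both binders are strong and ligand is
not in excess.  The package applies this closure exactly as stated and
quantifies its cost with the exact two-receptor solver: the fitted ratio
agrees with truth within 2% whenever equilibrium free ligand stays below 1%
of total, and `free_ligand_fraction` flags levels that violate this.  The
regression keeps a free intercept as a diagnostic of closure failure rather
than forcing the origin.  Points with any non-positive pool are excluded
with a logged reason, never imputed.  The free protein's affinity follows as
K_A,free = ratio × K_A,immobilized.

## Loading, stability and selectivity

* **Loading capacity**: OLS slope of bound protein (μM) on sphere molarity
  (μM) over the linear regime (shared segment selector; saturated tails
  excluded), read directly as molecules per sphere.
* **Release**: percent of initially bound protein lost by a time horizon,
  with a pass threshold (default 4%); increasing series report negative
  release with a warning.
* **Retention**: ligand adsorption with a competing metal over the
  metal-free control, ×100.  Classified retained at ≥ 95% — inclusive at the
  boundary so classification is deterministic.  The metric is a ratio, so
  the adsorption unit (μg/g, % removal, μM) cancels.

## Synthetic data generator

The simulators solve the equilibria exactly — closed-form stable quadratic
for the single receptor, bracketed Brent root finding on [0, total] with a
10⁻¹⁰-relative residual check for the competitive system — and therefore
double as brute-force oracles for the linearized estimators.  Measurement
noise is multiplicative Gaussian on bound amounts only (default cv 0.03,
matching the 1–3% triplicate scatter typical of atomic-fluorescence
quantification of this assay class), with free recomputed by difference so
mass balances stay closed and negative draws clamped to zero with a warning.
Seeds are mandatory for any stochastic mode and there is no global RNG
state; equal seeds give bit-identical datasets.

The default isotherm design is 10 total-ligand levels geometrically spaced
over 0.5–3× the site capacity — a standard titration through saturation.
The generator emulates equilibrium 1:1 binding with independent multiplicative
measurement error; it does not emulate non-specific background adsorption,
site heterogeneity, ligand oxidation, or correlated instrument drift, so
passing recovery tests demonstrate estimator correctness under the stated
model, not robustness to those real-data effects.

### An identifiability limit worth knowing

When capacity/K_D is very large (≈ 235 for the flagship high-affinity
parameters: K_A ≈ 30 μM⁻¹, capacity ≈ 7.7 μM), sub-saturation free
concentrations are a tiny difference of two large noisy numbers and fall
below any realistic noise floor; no titration design rescues K_A precision
under bound-side noise in that regime.  Noise-recovery calibration is
therefore run at a moderate-affinity parameter point (K_A = 0.812 μM⁻¹,
n = 0.83 × 10⁷ — the weak-ligand system of the motivating study), where the
default design resolves both slope and intercept.  Under those conditions
(cv 0.03, triplicates averaged per level, 100 seeded replicate experiments)
the median relative error of K_A is below 5%; the acceptance suite computes
this Monte-Carlo afresh.

## Numerical choices

* OLS with closed-form normal equations and exact 2×2 parameter covariance;
  R² defined as 1 − SS_res/SS_tot, clipped to [0, 1]; a zero-variance
  response is a perfect fit only when residuals vanish.
* Single-receptor quadratic solved in the numerically stable branch
  (rationalized form when the linear coefficient is positive) and clamped to
  [0, total].
* Segment search is exhaustive O(n³); datasets here are tens of points, so
  robustness beats asymptotics.
* Pipeline runs derive one sub-seed per stage deterministically from the
  top-level seed; identical configurations reproduce outputs byte for byte.
* Every exclusion (zero-bound points, out-of-domain kinetic points, flagged
  competition points, saturated loading tails) is counted and logged; silent
  dropping is forbidden.

## Problem sizes

Tests and the acceptance script run at desk scale: isotherms of 8–10
concentration levels (×3 replicates when noisy), kinetic series of ~24 time
points, competition series of 8 levels, and a 100-replicate Monte-Carlo for
noise calibration — matching the scale of the experiments the package
models.

## Known limitations

* Free ligand by difference limits high-affinity K_A precision (above).
* One binding-site class only: curved (heterogeneous-site) Scatchard plots
  and Hill cooperativity are out of scope; the segment selector will fit the
  dominant linear region of a curved plot, which is a convention, not a
  multi-class decomposition.
* Kinetic models are the two empirical rate laws; diffusion-limited
  (Weber–Morris) and Elovich kinetics are not implemented.
* The competitive module supports exactly two competing binders.
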