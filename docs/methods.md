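# Methods

## Scope and model

`sccosol` models the equilibrium mole-fraction solubility y₂ of a solid
solute (here: anti-cancer drugs) in supercritical CO₂ as a closed-form
function of temperature T (K), pressure P (MPa) and pure-CO₂ density ρ
(kg/m³).  No equation of state is involved: ρ is an *input*, taken from
measurements, property libraries or (for synthetic data) a documented
surrogate.

The central correlation combines an Arrhenius-shaped term with a
departure function,

    y₂ = (a₁·T + a₂·ρ + a₃)·exp(−a₄/P) + a₅·ln(ρ/T) + a₆ ,

motivated by the observed near-linear dependence of y₂ on T and ρ, its
exponential dependence on inverse pressure, and the residual structure
being well captured by ln(ρ/T).  The relevancy analysis (Pearson and
Spearman factors of y₂ against each input over the pooled datasets)
supports this reading: all three dependencies are positive, pressure is
the strongest and the most non-linear (Spearman ≈ Pearson for T and ρ,
|Spearman| relatively larger for P).

Ten classical density-based correlations are implemented for
benchmarking.  Unit conventions: all forms take T in K, P in MPa and ρ in
kg/m³; the Kumar–Johnston form internally converts ρ to kmol/m³ using
M(CO₂) = 44.01 kg/kmol; Bartle uses P_ref = 0.1 MPa and ρ_ref = 700 kg/m³.
Chrastil natively predicts c₂ (kg solute per m³ solvent); exact
conversions c₂ ↔ y₂ are provided and require the drug molar mass
(kg/kmol).  When no molar mass is supplied, Chrastil cannot be scored
against mole-fraction data and is excluded from comparisons with a
warning rather than silently misfitted.

### Reference coefficient scale

The packaged reference coefficients for the modified Arrhenius form are
stored in natural units.  The published table prints a₁, a₂, a₃, a₅ and a₆
in units of 10⁻⁶ (so the stored value is the printed value × 10⁻⁶), while
a₄ is unscaled and carries MPa units.  This is the only reading that
makes the predicted mole fractions land on the 10⁻⁷–10⁻³ scale of the
documented solubility envelopes, which the test suite verifies by forward
evaluation at every drug's envelope midpoint.

## Coefficient estimation

Fitting minimizes the absolute average relative deviation

    AARD% = (100/N) Σᵢ |y₂ᵉˣᵖ − y₂ᶜᵃˡ|ᵢ / y₂ᵢᵉˣᵖ ,

a relative criterion chosen because solubilities span four orders of
magnitude across drugs; squared absolute error would let the most soluble
records dominate.

The optimizer is differential evolution, strategy DE/rand/1/bin, with
population 15 per coefficient, mutation factor F = 0.8, crossover rate
CR = 0.9, at most 2000 generations, early stopping when the best
objective improves by less than a relative 10⁻¹⁰ over 200 consecutive
generations, and 5 independent restarts (seeds seed, seed+1, …) of which
the best is kept.  These are standard robust settings for ≤ 6 parameters.
scipy's implementation is used with a vectorised objective (the whole
population is evaluated in one numpy broadcast).  Each restart ends with
a Nelder–Mead polish; the simplex method is used deliberately because the
AARD surface has |·| kinks — exactly at an interpolating optimum — where
quasi-Newton polishing is unreliable.  Polished points are clipped to the
bounds and accepted only if they improve the objective, so the reported
optimum never leaves the box and the per-generation best-objective trace
remains non-increasing.  Identical (data, config, seed) inputs give
bit-identical results.

*Totality and the penalty.*  Coefficient vectors producing non-finite or
non-positive mole fractions are not errors: each offending record
contributes a fixed 10⁶ to the averaged sum (in place of its 100·|RD|
term), so the objective is total and finite everywhere and the optimizer
is steered away from the non-physical region.  Exponent arguments are
clamped at ±700; arguments above the clamp flag the prediction
non-finite.

*Bounds and initialisation.*  The default coefficient box is
[−10⁵, 10⁵] per coefficient, with the decay coefficient a₄ of the
modified Arrhenius form restricted to [0, 10⁴] (solubility increases
with pressure, so the exponential must decay in 1/P).  Because natural
coefficient scales range from ~10⁻⁶ to ~10², half of the initial
population is drawn log-uniformly in magnitude (down to 10⁻¹⁰ of the box
half-width, random sign where the box straddles zero) and half uniformly;
a purely uniform initial population over such a box would start entirely
in the penalty region and stall.  For quantitative work the bounds should
still be scaled to the problem (the recovery studies use boxes bracketing
the generating coefficients at ±50%); a fit whose best candidate predicts
no positive solubility anywhere raises a diagnostic suggesting wider
bounds.

## Quality metrics and pooling

R² = 1 − SS_res/SS_tot on the raw y₂ values; the standard error is the
RMS residual √(Σ(y_exp−y_cal)²/n) with population (1/n) normalisation,
consistent with the population-style SD used in the residual
standardization.  Per-drug AARDs are pooled into an overall value by the
count-weighted mean Σ(AARDᵢ·nᵢ)/Σnᵢ — the value that direct AARD over the
concatenated records would give.  This rule reproduces the published
pooled row of the benchmark to two decimals for ten of the eleven
correlations (9.54 modified Arrhenius, 14.90 Bian, 17.42 Chrastil, 84.66
Gordillo, …); the Méndez-Santiago–Teja column pools to 20.10 whereas the
published row prints 20.01, an apparent digit transposition in the
source, so the recomputed 20.10 is taken as correct.  The headline
accuracy-improvement statistic is 100·(AARD_ref − AARD_new)/AARD_new;
for 14.90 vs 9.54 it rounds to 56.2%.

Ranking uses competition ranks per drug (ascending AARD, ties share the
minimum rank, failed cells rank last).  On the packaged benchmark the
modified Arrhenius form is first for 6 of 12 drugs (with two second,
three third and one fourth place) and the Bian correlation first for 3.

## Outlier diagnostics

The leverage (Williams-plot) method plots standardized residuals against
hat values.  Residuals RE = y_exp − y_cal are centered and scaled by
their population SD, SR = (RE − mean RE)/SD, so SR has mean 0 and SD 1 by
construction.  Hat values are the diagonal of X(XᵀX)⁻¹Xᵀ, computed via
thin QR for numerical safety.  Because every correlation is nonlinear in
its coefficients, the design matrix follows applicability-domain practice
and uses the input variables with an intercept, X = [1, T, P, ρ] (k = 3
explanatory columns).  A record is suspect when |SR| > 3 or hat >
H* = 3(k+1)/N.

The injection-recovery validation corrupts ~5% of a synthetic dataset's
records by a factor of 10 and checks that ≥ 80% of corrupted and ≤ 5% of
clean records are flagged.  This study standardizes the residuals of
ln y₂ rather than raw y₂: the generator's noise is multiplicative
lognormal, so log-scale residuals are homoscedastic and the SR normality
band is actually meaningful there, whereas on the raw scale a corrupted
high-solubility record inflates the pooled SD and masks corrupted
low-solubility ones (measured: 70% detection raw vs 100% log-scale, with
zero false flags either way).  The raw-scale definition remains the
implementation and its unit tests; the scale choice belongs to the
validation study, and users diagnosing real data with multiplicative
error structure should pass log-scale inputs the same way.

## Synthetic data

The generator emulates the structure of the published studies: a full
n_T × n_P grid inside a drug's operating envelope (default 4 isotherms
over 308–338 K × 8 pressures over 12–40 MPa = 32 records, the most common
published design), a density attached to each point, and multiplicative
lognormal noise y₂ = y₂ᶜˡᵉᵃⁿ·exp(ε), ε ~ N(0, σ²), with σ = 0.05 the
default (mean absolute relative error ≈ 4%, matching the scatter level of
careful solubility measurements).  Additive noise would be non-physical
at the low-solubility end of a four-decade response.

The density surface is the closed form

    ρ(T, P) = (1100 − 2·(T − 300)) · P/(P + 6)   kg/m³,

valid for T ∈ [300, 360] K, P ∈ [8, 45] MPa: smooth, strictly increasing
in P, strictly decreasing in T, ranging inside [300, 1000] kg/m³.  It is
*not* a thermodynamic equation of state — it has no critical-region
structure and is not accurate against real CO₂ data — it exists so
synthetic grids are self-contained.  Any callable ρ(T, P) (e.g. from a
property library) can be substituted wherever a density surface is
accepted.

Consequently, passing recovery tests show that the estimation machinery
recovers a known generating surface under the assumed noise model; they
do not certify accuracy on real measurements, which carry correlated
errors, density uncertainty and envelope irregularities that the
generator does not emulate.  The published per-drug benchmark AARDs, the
pooled R² = 0.98 level and the published outlier counts all derive from
the original experimental data, which are not redistributed here; this
package reproduces the aggregation, ranking and diagnostic machinery and
validates it on synthetic data instead.

## Numerical and design choices

- Exponentials: arguments clamped at ±700; overflow → non-finite flag
  (penalised in fitting), underflow → 0 (then caught by the positivity
  check).
- Dataset files print 12 significant digits, making write/read round
  trips lossless to ~5·10⁻¹².
- Degenerate inputs raise early and specifically: zero residual SD,
  zero-variance features, rank-deficient designs, datasets smaller than
  the coefficient count, non-positive T/P/ρ/y₂.
- Maximisation of y₂ over an operating box is a dense-grid argmax
  (default 201×201), finer than any published experimental grid; a
  refined-grid oracle in the tests bounds the discretisation error at
  one grid step.  For the most soluble benchmark drug (busulfan) the
  maximum lies at the envelope corner (338 K, 40 MPa), i.e. at the
  highest allowable temperature and pressure.
- Problem sizes in the validation studies (chosen as desk-scale defaults):
  32-record grids; 10 optimizer seeds for noiseless recovery and 20 noise
  realisations for the noise-floor study in the tests (5 and 10 in the
  acceptance script); 20 corruption replicates for injection-recovery in
  the tests (10 in the script); a 10⁶-point grid for the one-dimensional
  DE-vs-grid oracle.

## Known limitations

- Coefficient values are not unique: the correlations are multi-modal in
  their coefficients, and fits are judged on objective value (AARD), not
  on coefficient identity.
- The default coefficient box is deliberately generous; serious fits
  should supply problem-scaled bounds.
- Chrastil comparisons require the drug molar mass; without it the model
  is excluded rather than approximated.
- The density surrogate is structural, not thermodynamic.
- No uncertainty quantification beyond restart spread; bootstrap
  intervals are a possible extension, not implemented.
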