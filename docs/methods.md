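# Methods

`aminochol` analyses ternary aqueous solutions of an amino acid
(l-glycine, d,l-alanine or l-proline, 0.05–0.15 mol kg⁻¹) and choline
chloride (0–0.3 mol kg⁻¹) between 288.15 and 318.15 K at ambient
(≈0.087 MPa) pressure.  The raw observables are solution density *d* and
speed of sound *u*; everything else is derived.

## Apparent molar properties

For a solute of molar mass *M* at molality *m* in a solvent of density
*d₀* (here the solvent is water + amino acid, so the baseline row of the
same block at the same temperature):

- isentropic compressibility (Newton–Laplace): κ_S = 1/(d·u²)
- apparent molar volume: V_φ = M/d − (d − d₀)/(m·d·d₀)
- apparent molar isentropic compressibility:
  κ_φ = (κ_S·d₀ − d·κ_S0)/(m·d·d₀) + κ_S·M/d

κ_S and κ_S0 always enter κ_φ at full floating-point precision.  This
matters: rounding κ_S to the three significant figures a printed table
would carry shifts the first glycine κ_φ from −1.91×10⁻¹⁴ to
−2.41×10⁻¹⁴ m³ mol⁻¹ Pa⁻¹, i.e. by 25%.  The pipeline therefore never
consumes printed compressibilities.

The molar mass of choline chloride defaults to 139.62 g mol⁻¹ (C₅H₁₄ClNO)
and is overridable everywhere a molar mass is accepted.

**Taste descriptors.**  ASV = V_φ/M and ASIC = κ_φ/M are empirical
sweetness and saltiness descriptors.  The ideal-sweetness band
0.5 < ASV < 0.7 is evaluated with ASV in cm³ g⁻¹.  Every bundled state
point falls at 0.876–0.909 cm³ g⁻¹, above the band.

**Reporting scales.**  Result tables use the customary scales: V_φ in
10⁶ m³ mol⁻¹, κ_φ in 10¹⁴ m³ mol⁻¹ Pa⁻¹, ASV in cm³ g⁻¹, ASIC in
10¹¹ m³ kg⁻¹ Pa⁻¹ (the only scale on which tabulated ASIC magnitudes are
self-consistent).

## Redlich–Mayer and Hepler analysis

Per (system, T), Y(m) = Y⁰ + S·√m + B·m is fitted by unweighted ordinary
least squares (no uncertainty weighting is justified: all points share the
same instrument).  The intercept is the infinite-dilution value; the
residual SD uses n−3 degrees of freedom.  V⁰_φ(T) is then fitted with a
quadratic A + BT + CT² (computed in a centered basis for conditioning and
reported in the raw basis), giving

- expansibility E⁰_φ(T) = B + 2CT,
- apparent isobaric thermal expansion α(T) = E⁰_φ(T)/V⁰_φ(T), where the
  denominator is the *fitted* V⁰_φ(T) — the only self-consistent choice
  once the numerator is the polynomial's derivative (α computed this way
  can differ by ~1% from tabulations that divide by per-temperature
  intercepts),
- Hepler criterion (∂C_P/∂P)_T = −T·(∂²V⁰_φ/∂T²)_P = −2CT.

2C > 0 classifies the solute as a water-structure maker, 2C < 0 as a
breaker; |2C| below a configurable dead band (default 10⁻⁴ on the 10⁶
scale) is reported indeterminate.  Note that 2C is a second derivative
estimated from four points: it amplifies changes in the intercepts by a
factor ≈25, so intercepts that agree to ±0.1 can still produce visibly
different Hepler constants.  Six of the nine bundled systems classify as
makers, three as breakers.

## Electrolyte PC-SAFT

The residual Helmholtz energy per molecule is
a = a_hc + a_disp + a_assoc + a_ion.

- **Hard chain**: Boublík–Mansoori–Carnahan–Starling mixture hard-sphere
  term with the chain correction through the contact radial distribution
  function.  Temperature-dependent effective diameters
  d_i = σ_i·(1 − 0.12·e^(−3ε_i/kT)) for neutral species; ions keep their
  bare diameter (they have no soft dispersion well to shrink).
- **Dispersion**: second-order perturbation theory with the universal
  I₁/I₂ coefficient tables and the C₁ compressibility correction;
  one-fluid mixing with σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_iε_j), k_ij = 0
  (pure prediction, no binary fitting).
- **Association**: Wertheim first-order theory.  Water uses a 2-site (2B)
  scheme, amino acids 2B, i.e. one donor and one acceptor each.
  Cross-association combines ε by arithmetic mean and κ by geometric mean
  scaled with (√(σ_iσ_j)/σ_ij)³.  Site fractions are solved by damped
  successive substitution (damping 0.5, tolerance 10⁻¹², max 500
  iterations, deterministic start at X = 0.5).
- **Ion term**: Debye–Hückel Helmholtz contribution
  a_ion = −(κ e²)/(12π ε₀ ε_r k_B T) Σ_j x_j z_j² χ(κσ_j), with
  χ(u) = 3u⁻³[ln(1+u) − u + u²/2] (series-expanded below u = 10⁻³), the
  inverse Debye length κ from the ionic strength, and the static
  permittivity of pure water from an empirical polynomial in T (78.4 at
  298.15 K).  Choline chloride dissociates fully into Ch⁺ + Cl⁻.

The compressibility factor Z = 1 + ρ·∂a/∂ρ is analytic in every term; the
association part uses the stationarity of the Wertheim functional, so no
∂X/∂ρ is required.  P = Z·ρ·k_B·T.  The liquid density solver scans P(η)
over η ∈ (10⁻¹⁰, 0.7405), brackets every root, polishes with Brent's
method (xtol 10⁻¹⁴), and returns the largest-η root that is mechanically
stable (∂P/∂ρ > 0); a warm start from a neighbouring state restricts the
scan to a local bracket.  Validation: the solved root refeeds to
|P − P_target|/P_target < 10⁻⁸, the analytic Z matches central differences
of a(ρ) to better than 10⁻⁶ relative, the m = 1 hard sphere reproduces
Z ≈ 1 + 4η at low packing, and a grid-scan oracle (10⁴-point scan plus
bisection, independent of the solver) pins the golden pure-water density.

### Parameter sets and their provenance

`params_experimental.csv`: literature parameters regressed from
macroscopic data.  Water is the temperature-dependent-diameter set
σ_w(T) = 2.7927 + 10.11·e^(−0.01775T) − 1.417·e^(−0.01146T) Å with
m = 1.20465, ε/k = 353.94 K, κ = 0.04509, ε_AB/k = 2425.7 K.  This set
was regressed under a two-site association scheme, and run that way it
reproduces pure liquid water to ~0.1% across 288–318 K (997.00 vs 997.05
kg m⁻³ at 298.15 K); run with four sites it overbinds and misses by +8%.
The package therefore ships it as 2B even though four-site water is the
more common convention elsewhere — scheme and parameters are a package
deal.  Choline chloride enters as m = 1 hard-sphere ions (Ch⁺:
σ = 5.9216 Å, ε/k = 220.49 K; Cl⁻: σ = 3.0575 Å, ε/k = 47.29 K), the
convention of the electrolyte-extension literature the set derives from.
By default ions take Lorentz–Berthelot dispersion with neutral species but
none with each other (`ion_dispersion="solvent"`); `"none"` and `"full"`
are available.

`params_cosmo.csv`: geometry from continuum-solvation cavities
(σ = 3V/A, m = A/(πσ²) — see below), energies from the tabulated
quantum-chemistry-derived values; choline chloride is one neutral 2B
component here (the cavity calculation treats the intact salt).  The
association-energy column of the source tabulation is typographically
ambiguous; the default preset reads the effective volume at three
decimals (κ = 0.020–0.024, ε_AB/k = 590–8190 K, a physically plausible
range) and `params_cosmo_alt.csv` carries the other reading (κ = 0.02
with ε_AB/k = 18 190–41 260 K).  The alternative preset's association
energies are so large that the equation of state has no liquid root at
ambient pressure — itself evidence for the default reading.

### Cavity-to-parameter mapping

Matching a chain of m tangent spheres of diameter σ to a cavity of volume
V and surface A gives σ = 3V/A and m = A/(πσ²) (equivalently
m = A³/(9πV²)); for a single sphere 3V/A is exactly the radius.  The
often-quoted σ = 6V/A is the diameter-route variant and yields exactly
twice the segment diameters tabulated for these compounds, so this
package uses 3V/A (erratum note).  The dispersion and association
energies follow u₀/k = a/σ⁶ + b and ε_AB/k = c/σ⁶ + d; the (a, b, c, d)
constants are literature inputs the user must supply — no default
pretends to a provenance it lacks.

## Synthetic data generator

The generator emulates the study's measurement design: per (system, T), a
solvent baseline (d₀, u₀) plus six molalities, four temperatures, nine
systems.  Given Redlich–Mayer triples as ground truth it inverts the
property chain in closed form,

    d(m) = (M + 1/m) / (V_φ(m) + 1/(m·d₀))
    κ_S(m) = (κ_φ(m) + κ_S0/(m·d₀)) · m·d(m)/(1 + m·M)
    u(m) = 1/√(κ_S·d)

so the noise-free table round-trips exactly, then adds Gaussian noise to
the observables d and u — never to derived quantities — at the combined
standard instrument uncertainties (0.04 kg m⁻³, 0.6 m s⁻¹).  All
randomness flows through an explicit seed.  The default ground truth for
recovery studies is the fitted bundled table itself (36 groups).

What it does *not* emulate: correlated drift within a run, temperature
error (0.02 K), molality error (0.002 mol kg⁻¹), or any misfit of the
Redlich–Mayer form itself.  Passing recovery tests therefore demonstrate
the statistical behaviour of the fitting chain under observable noise,
not the adequacy of the √m expansion for real solutions.

**Recovery experiment.**  Replicates are generated in antithetic pairs
(each odd replicate negates the Gaussian draws of its even partner).  The
fitted intercept is linear in the noise to first order, so the pair mean
cancels the O(σ) Monte-Carlo fluctuation and the reported bias estimates
the estimator's true nonlinear bias (≲10⁻⁶ on the 10⁶ scale) instead of
sampling noise; coverage statistics are unaffected because each member is
a valid draw.  Standard errors for coverage are propagated analytically
from the known noise model through the OLS projection, including the
rank-one covariance induced by the shared baseline row; a residual-based
SE with n−3 = 3 degrees of freedom would make a nominal ±3 SE interval a
~94% interval and is not used here.  The per-fit intercept spread at
instrument noise is ≈4×10⁻⁶ m³ mol⁻¹ — the √m design extrapolates to
m = 0 from m ≥ 0.05, amplifying the ≈1×10⁻⁶ per-point noise at the lowest
molality by the design's leverage.

## Known limitations

- The equation of state predicts all 252 state points to ≈0.7% ARD with
  the experimental set; the proline systems are predicted best at every
  temperature, but the glycine/alanine gap (0.002–0.02 percentage points)
  is within numerical noise and their ordering flips with temperature.
- Vapor–liquid equilibrium, activity/osmotic coefficients, enthalpies and
  any dipolar contribution are out of scope; no binary k_ij fitting is
  performed.
- The Hepler classification threshold (dead band) is a package choice;
  only the sign rule itself is standard.
- Cavity-derived dispersion/association energy correlations require
  user-supplied constants; only the geometric mapping is evaluated
  end-to-end.
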