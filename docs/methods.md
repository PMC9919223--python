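# Methods

## Model

All predictions use the small-load approximation: the complex frequency
shift Δf + iΔΓ of a thickness-shear resonator equals i f₀ Z̃_load/(π Z_q),
with Z_q the shear-wave impedance of AT-cut quartz and Z̃_load the shear
impedance the sample presents at the crystal surface.  For a planar film
under a semi-infinite bulk, Z̃_load follows from the standard
transmission-line transfer

    Z̃_load = Z̃_f (Z̃_bulk + i Z̃_f tan(k̃_f d_f)) / (Z̃_f + i Z̃_bulk tan(k̃_f d_f)),

applied recursively for multilayers (outermost layer first, terminated by
the bulk impedance: 0 for vacuum, (iωρη)^½ for a Newtonian liquid,
(ρG̃)^½ for a viscoelastic half-space).  Complex square roots are taken on
the passivity branch Re(Z̃) > 0, which implies Im(k̃) < 0 (decaying wave).
`tan(k̃ d)` is evaluated as −i(1−w)/(1+w) with w = exp(−2i k̃ d); since
|w| ≤ 1 on this branch the expression saturates smoothly to −i for films
much thicker than their penetration depth instead of overflowing, and the
prediction then equals the half-space response of the film material
regardless of the terminating bulk.

Shifts are referenced to the bare resonator by default.  Adsorption data
are almost always referenced to the liquid-loaded baseline instead;
`reference="bulk"` subtracts the d_f = 0 prediction.  A film of exactly
zero compliance is treated as rigid and contributes the purely inertial
load iω m_f (the Sauerbrey limit, Δf/n = −2 f₀² m_f / Z_q ≈ −5.7 Hz per
nm of unit-density film at 5 MHz).

## Materials

A material is two values at a reference frequency plus two power-law
exponents, in one of four representations: {J′, J″}, {G′, G″}, {η′, η″},
{|G̃|, tan δ}.  Sign conventions: G̃ = G′ + iG″, J̃ = 1/G̃ = J′ − iJ″,
η̃ = G̃/(iω) = η′ − iη″.  Power laws apply to the two native values of the
chosen representation; note that a power law in one representation is not
exactly a power law in another, so the five-parameter model families differ
slightly between representations when the exponents are nonzero (they
coincide for β′ = β″ = 0).  This is why fits in different representations
are only required to agree in χ² on dispersionless data; with dispersion
they are different (equally defensible) parameterizations.  Defaults:
f_cen = 30 MHz (the middle of the n = 3–11 range of a 5 MHz crystal),
ρ_f = 1000 kg/m³, Z_q = 8.8×10⁶ kg m⁻² s⁻¹ — all overridable.

Material properties are evaluated at f = n f₀ for each overtone.

## Thin-film limits and recipes

Two Taylor forms are implemented and verified against the exact model by
thickness-halving convergence tests:

* film in air, third order in d_f:
  (Δf+iΔΓ)/n = −(m_f/m_q) f₀ [1 + (nπ)²/3 (J̃_f Z_q²/ρ_f − c)(m_f/m_q)²],
  with c = 1 in the slightly better variant (default) and c = 0 in the
  plain expansion; relative deviation O(d_f⁴);
* film in a Newtonian liquid, first order in d_f:
  (Δf+iΔΓ)/n = −(2f₀²/Z_q) ρ_f d_f [1 − Z̃_bulk²/Z̃_f²], referenced to the
  bulk baseline; relative deviation O(d_f) (absolute O(d_f²)).  Because the
  form is linear in thickness it extends to an integral over continuous
  profiles J̃(z), which the multilayer staircase reproduces in the thin
  limit.

The recipes invert these forms from the shapes of the overtone plots.  For
a film in air, Δf/n against x = n² has intercept −(m_f/m_q)f₀ (the mass),
a slope set by J′, and a curvature set by β′; J″(n) follows from ΔΓ/n and
the fitted mass, and β″ from a log-log slope.  For a stiff film in liquid
the abscissa is n, the slope carries J″ and the curvature β″, while the
dissipative channel carries J′ and β′.  Implementation detail: a plain
quadratic least-squares fit of the plot biases the intercept and slope by a
few percent when the dispersion exponent is far from zero (the correction
term varies as x^(1+β/2)); the estimators therefore refine the quadratic
fit (kept for diagnostics and standard errors) with a least-squares fit of
the recipe's own generating shape A + B·x^(1+β/2).  On noiseless data
generated by the recipe's defining equation every parameter round-trips to
numerical precision; on data from the exact model the recipe error vanishes
as d_f → 0.  All recipe outputs are labelled approximate; accurate values
come from the full fit.

The stiff-film recipe assumes J″_f ≪ J″_bulk (equivalently η′_f ≫ η_bulk);
`validate_stiffness` reports both ratios against a configurable factor-10
threshold and the estimates are flagged, not suppressed, when the
assumption fails.

### Near-Newtonian layers

For a layer that is almost the bulk liquid (the diffuse-double-layer
situation), the first-order bracket becomes Δη̃/η_bulk, and only the
products d_f·Δη′ (from Δf/n) and d_f·η″_f (from ΔΓ/n) are accessible:
no statement about thickness alone can be made.  In the {|η̃_f|, tan δ}
coordinates the thin-film acoustic ratio is

    ΔΓ/(−Δf) = r / (√(1+tan²δ) − r·tanδ),   r = η_bulk/|η̃_f|.

At |η̃_f| = η_bulk and large tan δ this grows as 2·tanδ (the viscosity
increment is then mostly imaginary, so the response is
dissipation-dominated); the small invertible quantity is the reciprocal,
(−Δf)/ΔΓ → 1/(2 tanδ), and the double-layer analysis estimates the
layer's inverse loss tangent as cot δ ≈ 2(−Δf)/ΔΓ.  A "Sauerbrey-type"
flag (mean acoustic ratio below a configurable bound, default 0.2) marks
the regime where the increment is mostly real and the d_f·Δη′ reading is
meaningful.

## Fitting and identifiability

χ² is the unnormalized weighted sum of squared residuals over both
channels and all overtones, with equal default weights σ_f = σ_Γ = 0.1 Hz
(the magnitude of per-crystal irregularities seen on real data);
reduced χ² is reported alongside.  Positivity of d_f and the stiffness
pair is enforced by optimizing log₁₀ of those parameters; the exponents
are bounded to [−3, 3].  The minimizer (trust-region reflective least
squares) restarts from a deterministic 8-point Latin hypercube of the
bounds plus a Sauerbrey-based heuristic start, because the χ² valley of
thin films is long and shallow.  Standard errors come from the Gauss–
Newton covariance in transformed coordinates, propagated to physical
units.  The fundamental (n = 1) is excluded by default throughout — it is
usually erratic on real crystals — and no artifact model for high
overtones on Newtonian liquids is included.

`chi2_landscape` fixes one parameter on a grid and refits the rest,
warm-starting each grid point from its neighbor and from the free fit, so
every profile point is bounded below by the free-fit χ².
`identifiability_report` fits offset + slope + curvature to each channel
versus n with the declared noise scales (estimated from residual scatter
and flagged when absent) and counts a curvature as robust when it exceeds
twice its standard error: six robust observables overdetermine the
five-parameter model, four leave it underdetermined.

## Synthetic experiments

The generator evaluates the exact model along a thickness trajectory
(step, saturating Langmuir — the default adsorption shape — or linear),
references to the bulk baseline, and adds (i) per-crystal constant offsets
drawn once per overtone and channel from a zero-mean uniform distribution
of half-width 0.1 Hz, held constant in time, and (ii) Gaussian white noise
per sample, default 0.02 Hz.  The offsets emulate the irregularities
(compressional-wave admixtures, crystal-to-crystal variation) that
dominate real thin-film data and that block averaging cannot reduce;
`pre_average` (non-overlapping block means, the usual 4-point averaging of
raw exports) shrinks only the white part.  A snapshot carries the combined
per-overtone scale √(white² + offset²/3) as its noise estimate.  Fixed
seeds reproduce experiments bit for bit.

What the generator does not emulate: instrument drift, temperature
transients, high-overtone artifacts on Newtonian liquids, compressional-
wave physics, particulate or laterally structured adsorbates.  Green tests
on synthetic data therefore demonstrate the correctness and the intrinsic
(noise-limited) identifiability of the analysis chain, not robustness to
those systematics.

## Study sizes and numerical choices

* Overtones n = 3, 5, 7, 9, 11 at f₀ = 5 MHz everywhere.
* The Monte-Carlo thickness-recovery study uses 100 independent 10 nm
  films with 0.05 Hz white noise, analyzed with the standard 4-point
  pre-averaging before the fit (weights 0.025 Hz); the median |relative
  error| of d_f is ≈2.5%.  Without pre-averaging the single-snapshot
  Fisher limit for d_f is ≈8% under these conditions — the soft-film
  thickness/compliance trade-off, not the optimizer, sets this floor.
* The identifiability contrast uses 2 nm vs 10 nm films of the same soft
  material with 0.1 Hz offsets: the thin film yields 4 robust observables
  (underdetermined) and a thickness profile that is shallow above the true
  value and catastrophic below it; the thick film yields 6 robust
  observables and a sharp minimum, >10× steeper at ±30% than the thin
  film's above-truth variation.  The thin-film profile is not arbitrarily
  flat, however: fixing a several-fold overestimate of the thickness
  forces the co-fitted material to a compensation point whose own
  second-order thickness terms leave ~0.2–0.3 Hz residuals on the high
  overtones, so χ² still rises severalfold between the true thickness and
  five times it.
* Round-trip tolerances in the tests: recipes 1% on values (10% on the
  curvature-derived exponent), full fits 0.1% on noiseless data;
  representation round trips are exact to ~10⁻¹² relative; the
  near-Newtonian asymptote is verified to 3% at tan δ = 50.

## Known limitations

Piecewise-constant multilayers only (no continuous-profile inversion);
local standard errors and one-dimensional profiles only (no posterior
sampling or two-parameter landscapes); vendor binary formats are not read
— export to CSV first; the equal-density simplification in the liquid
Taylor form is opt-in, exact densities are used otherwise.
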