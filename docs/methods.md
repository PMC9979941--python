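# Methods

## Model and assumptions

The package solves the scalar Helmholtz problem for a fast electron incident
on *N* non-overlapping spheres of constant potential. The wave equation is
used in Schrödinger form with the beam energy *E* as a parameter; relativity
enters only through the de Broglie wavelength
λ = h / √(2 m₀ eV (1 + eV/2m₀c²)) (CODATA constants), not through a Dirac
treatment. Conventions: optics time dependence e^(−iωt) with an e^(+ikz)
incident wave, orthonormal spherical harmonics with the Condon–Shortley
phase, outgoing waves h_l^(1) = j_l + i y_l. Potentials are real
(elastic scattering only): every exact solution must satisfy per-partial-wave
unitarity |1 + 2t_l| = 1 and the optical theorem, and both are used as
runtime diagnostics rather than assumed.

The constant-well ("soft-sphere") atom is a deliberate simplification. Its
(ka, n) pair is chosen to reproduce the scattering cross section of a real
atom, which is the figure of merit that controls the *extent of multiple
scattering* — the quantity this model is meant to estimate — not the detailed
angular shape of the form factor. The muffin-tin module refines this with
concentric constant shells averaged from the screened-Coulomb IAM potential.

## Numerical pieces and their choices

**Radial functions.** scipy's `spherical_jn` / `spherical_yn` (which are
stable in the l > x regime relevant here); Hankel as their complex
combination. No overflow occurs for the orders the truncation rule requests
(l up to ~2·l_max at arguments down to 10⁻³).

**Gaunt coefficients and the addition theorem.** Translation operators are
assembled from the Gaunt series

    A_{l'm',lm}(kd) = Σ_L 4π i^(L+l'−l) z_L(kd) conj(Y_L^{m'−m}(d̂)) G(L, m'−m; l, m; l'),

with z_L = h_L^(1) for outgoing→regular (valid for |k r_target| < |kd|) and
z_L = j_L for regular→regular; the L sum runs over the parity-allowed window
|l−l'| … l+l'. The form was derived from the plane-wave expansion and is
validated in the tests against direct evaluation of translated multipoles
(the independent oracle), not against any printed formula. Gaunt/Wigner-3j
symbols are computed by the Racah single-sum formula with log-factorials
(float, ~1e-11 accuracy, cached); sympy's exact implementation is kept as a
test oracle but is too slow to assemble general-m operators at l_max ≳ 10.
An axial fast path keeps only m = 0 when every centre lies on the beam axis
and the incidence is axial — the general solver agrees with it to 1e-10 and
its m ≠ 0 unknowns vanish to 1e-12, which is tested.

**Truncation rule.** l_max = ⌈max ka⌉ + 8 by default, user-overridable. The
margin is calibrated by the boundary-continuity diagnostic: on the standard
two-sphere fixture the surface mismatch falls monotonically with l_max and
reaches ~1e-13 at l_max = ka + 12.

**Single-sphere response.** Uniform wells: per-l 2×2 continuity solve in
closed form. Multi-shell spheres: the regular solution is propagated outward
across interfaces as a normalized (value, derivative) pair — equivalent to a
logarithmic-derivative transfer but free of the pole when j_l vanishes at an
interface — then matched to the exterior j + t·h form; interior amplitudes
are afterwards rescaled region by region so interior fields can be evaluated.
Singular 2×2 systems (machine-level resonances) raise; nothing is
regularized silently.

**Coupled solves.** Dense LAPACK solve of (I − T)A = L with a condition
estimate (warning above 1e12) and a residual guarantee (warning above 1e-10).
Forward mode requires the caller to supply spheres already sorted ascending
along the beam axis (ties broken by transverse coordinates) and refuses to
sort silently; spheres whose z differ by less than 1e-9/k share a slice, and
intra-slice coupling is dropped entirely (90° scattering neglected), which
keeps T strictly slice-lower-triangular so the successive (Neumann) expansion
terminates exactly at the slice count — asserted at 1e-12 in the tests.

**Far fields and quadrature.** Gauss–Legendre in cos θ and uniform trapezoid
in φ. The node count is 2·l_max + 16 plus the array's phase bandwidth
⌈k·(largest inter-sphere distance)⌉: the inter-sphere phase factors
e^(−ik r̂·d_p) oscillate faster than the single-sphere patterns, and a grid
sized to the harmonic bandwidth alone integrates them wrongly (this is
visible as an apparent optical-theorem violation, and is tested). The
differential cross section is dσ/dΩ = |f|² with f in Å, so σ = ∫|f|² dΩ;
any extra normalization constant is taken as unity.

**Boundary-continuity diagnostic.** The interior expansion at each surface is
compared against an exterior side composed of: the incident wave expanded
about that sphere's centre (truncated at the operating l_max, exactly like
the solution), the sphere's own outgoing expansion (analytic), and the other
spheres' outgoing fields evaluated *directly* (their radial derivative by a
5-point central difference of step 1e-3/k). The interior saw those other
fields only through the truncated translational re-expansion, so this
mismatch isolates precisely the truncation error that the l_max rule must
control; value and derivative errors are surface-L2 normalized and reported
separately. With n = 1 everywhere the error is zero to round-off.

**Scattering probabilities.** Per-order far-field amplitudes f^(n) come from
the successive expansion. The assignment of interference cross terms to
orders is ambiguous; the default telescopes cumulative intensities,
σ_n = ∫|Σ_{m≤n} f^(m)|² − ∫|Σ_{m≤n−1} f^(m)|², which sums exactly to the
retained-order total but may be negative for an individual n (reported
as-is). A pure-|f^(n)|² variant is available behind `cross_terms="pure"`.
Probabilities are P_n = σ_n/S with S the illuminated area — a required user
input (SAED aperture or simulation supercell), never defaulted. The
precondition S > σ_total is enforced by raising, not clamping. The
incoherent baseline is Poissonian in z/Λ with Λ = S·dz/σ̄ the elastic mean
free path of the chain.

## Parameters that matter

| parameter | meaning | default / typical |
|---|---|---|
| energy_kev | beam energy | 200 keV (λ = 0.02508 Å) |
| ka | normalized sphere radius | 0.5–5 (abstract fixtures); ~30 for a truncated carbon atom |
| n_ref − 1 | well strength V/2E | 10⁻⁴–10⁻² |
| kd | normalized spacing | 30 (of the order of interatomic distances) |
| l_max | truncation order | ⌈max ka⌉ + 8 |
| S | illuminated area (probabilities) | user-supplied, Å² |

The shipped IAM table covers carbon only (the light-atom case of interest),
as a 3-Lorentzian + 3-Gaussian scattering-factor fit in the standard
electron-microscopy parameterization; shell reduction uses equal radial steps
by default with a log-spaced option concentrating shells near the nucleus
(the placement rule is a free design choice — the staircase converges to the
smooth-potential Born amplitude either way, which is tested across
n_shells ∈ {4, 8, 16, 64}).

## What the fixtures emulate — and what they do not

The test fixtures are linear chains and two-body configurations of identical
soft spheres under axial plane-wave illumination: the cleanest setting in
which multiple scattering, its forward approximation and its order-by-order
expansion can be compared against an exact solve. They do not emulate
thermal motion, inelastic or incoherent scattering, bonding corrections,
aperiodic disorder, or the very large ka (~400) a fully resolved atomic
potential would need — so passing tests demonstrate the correctness of the
solver stack and the internal consistency of the approximations, not a
quantitative match to any experimental diffraction pattern.

Problem sizes used by the test suite and the acceptance script — N ≤ 16
spheres, l_max ≤ 46, 10×10 parameter grids — were chosen as the smallest
sizes at which every qualitative regime (Born, forward-dominated, strongly
coupled) is represented.

## Known limitations

* Real potentials only; no absorption (complex n) channel.
* The forward-mode error, measured with the scale-free metric
  ‖Δb‖/‖b‖ over all spheres, saturates with N (both numerator and
  denominator grow with the chain); the accumulation of forward-propagation
  error is monotone in the absolute error and in the most-downstream sphere's
  error, and the tests assert it there.
* Translation operators are dense; no fast-multipole or rotation-axial
  decomposition, so very large N or l_max is out of reach.
* The CLI geometry format is an abstract sphere table; no CIF/PDB import.

## Config schema (YAML or JSON)

```yaml
beam: {energy_kev: 200.0, direction: [0, 0, 1]}
geometry: geometry.tsv      # or an inline list of row mappings
solver: full                # full | forward | kinematic | successive
n_orders: 3                 # successive mode only
l_max: null                 # null = auto rule
outputs: [far_field, cross_sections, probabilities, continuity, coefficients]
S: 1.0e-4                   # illuminated area, required for probabilities
seed: 0                     # sweep subsampling only
```

Geometry tables are headered whitespace-delimited text with either
`x y z radius n_ref` (explicit soft spheres, Å) or
`x y z element n_shells r_max` (expanded through the muffin-tin reduction).
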