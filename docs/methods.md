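# Methods

`cyanoagg` simulates the coupled colony-size and vertical-position dynamics
of a motile, colony-forming cyanobacterium (*Microcystis aeruginosa*) in a
stratified 1D water column. This note documents the model, the numerical
choices, the synthetic forcing, and the limits of what the test suite
demonstrates.

## Model

### Size classes and colony geometry

Colonies are tracked as discrete classes k = 1 .. k_max (cells per colony,
default k_max = 101). A k-cell colony is represented by an equivalent
spherical diameter from fractal scaling,

    d_k = k^(1/Df) · d0 / φ(k),

with single-cell diameter d0 = 5 μm, fractal dimension Df = 2.5, and a
porosity φ(k) that decreases affinely from 1 (single cells) to 0.2 (the
largest class). The porosity divides outside the fractal exponent: this
placement is the one that reproduces both quoted anchor diameters
(d₁₀₁ ≈ 160 μm and d₉₅ ≈ 125 μm) simultaneously, and it is the package
default; the alternative placement `(k/φ)^(1/Df) d0` is available as the
`phi_inside` dialect. The cell-volume fraction of a class is
vfrac(k) = k^(1−3/Df) — the ratio of live-cell volume to compact fractal
volume — and is used only for colony density, not for drag.

Sticking probability (collision efficiency) follows the extracellular
polysaccharide content of field colonies, which peaks near 100–150 μm:
α(d) = 0.994·exp(−((d − 116 μm)/134 μm)²), giving α ≈ 0.5 for single cells
and α ≈ 1 near 125 μm. For a colliding pair, α(i,j) = max(α_i, α_j): the
stickier (larger) partner dominates. The multiplicative rule
α_i·α_j is available as the `product` dialect.

### Collision kernels and aggregation

The volumetric collision rate between classes i and j is the sum of three
mechanisms,

    β(i,j,z) = β_Br + β_TS + β_DS
    β_Br = 2 T k_B (d_i + d_j)² / (3 μ d_i d_j)        (Brownian)
    β_TS = (4/3) G (d_i + d_j)³                        (turbulent shear)
    β_DS = π (d_i + d_j)² |w_i − w_j|                  (differential settling)

with G = (ε/ν)^½ the turbulent shear rate. The shear and settling
coefficients are written for total diameters; the radius-convention values
(1/6 and π/4) are exposed as `shear_coeff`/`settling_coeff` for
comparison. With the defaults, the largest kernel at high-wind surface
conditions is ≈ 8.5 × 10⁻¹⁰ m³/s, consistent with the reported
β ∈ [10⁻¹³, 10⁻⁹] m³/s range.

The population balance is the discrete Smoluchowski equation truncated at
k_max: pairs whose combined cell count would exceed k_max never react
(rather than forming and fragmenting). This choice conserves total cell
mass identically — the gain of every reacting pair is matched by its two
loss terms — and avoids gelation bookkeeping. Fragmentation is not
modelled; laboratory evidence indicates disaggregation is negligible below
the ~220 μm largest-stable-colony scale that k_max = 101 stays well under.

### Buoyancy regulation

Cell density responds to light with a saturating rate,

    dρ_cell/dt = c1·I/(I + K_I) − c2,   clipped to [ρ_min, ρ_max],

the standard gas-vesicle/ballast formulation of earlier *Microcystis*
motility models. Defaults: c1 = 2.0 × 10⁻³ kg m⁻³ s⁻¹,
c2 = 6.7 × 10⁻⁴ kg m⁻³ s⁻¹ (so a 16 h photoperiod and 8 h night roughly
balance), K_I = 100 W/m², bounds [985, 1065] kg/m³. These constants are
free parameters of the package; what is pinned down is the resulting
velocity band (below). One density field is shared by all classes — light
exposure is a local function of depth and the model does not transport
per-class physiological state; per-class density fields are a documented
extension point.

Colony density mixes cell and ambient water density through the fractal
volume fraction, ρ_k = ρ_w + vfrac(k)(ρ_cell − ρ_w), while drag uses the
porosity-inflated diameter d_k in the modified Stokes velocity

    w_k = g d_k² (ρ_k/ρ_w − 1) / (18 ν),   positive = sinking.

This split (compact-fractal volume for mass, inflated envelope for drag) is
the only combination we found that reproduces all three published velocity
anchors at once: ~10⁻⁶ m/s single-cell speeds, the [−10⁻⁴, 10⁻³] m/s band
over all classes at the density bounds, and the 160 μm largest envelope.
Folding porosity into the volume fraction as well yields speeds ~100×
too small.

### Light and water column

Surface irradiance is a truncated diel sine: I₀(t) = I_max sin(π t/D_L)
during the photoperiod D_L = 16 h (I_max = 800 W/m²) and zero for the
remaining 8 h of the 24 h cycle (the sine is only defined on the
photoperiod; extending by zero keeps irradiance non-negative). Depth
attenuation is Beer–Lambert with k_I = 1.3 m⁻¹.

Water density and viscosity come from standard temperature correlations
(limnological density polynomial with the 4 °C maximum; Vogel viscosity),
since the model consumes only T(z) profiles.

Profiles of T, D_Z and ε can be read from delimited text
(`depth_m,temp_C,Dz_m2s,eps_m2s3`, linearly interpolated onto the grid) or
generated synthetically. The synthetic generator emulates a summer
dimictic lake: a tanh two-layer temperature profile (defaults 25 °C over
12 °C), and mixed-layer-maximum mixing that rolls off smoothly below
h_ML. It is anchored to the measured regime maxima — ε_max = 4 × 10⁻⁴
m²/s³ (high wind, ~8 m/s) and 3 × 10⁻⁷ m²/s³ (low wind, ~2 m/s) — which it
attains exactly by construction. Dispersion maxima are not printed in the
source; the defaults D_max = 10⁻³ m²/s (high wind) and 10⁻⁵ m²/s (low
wind) sit inside the literature range 10⁻⁶–10⁻² m²/s and keep the default
explicit scheme diffusively stable. The mixed-layer depth h_ML is likewise
a free parameter (default 3 m for a 10 m column). The synthetic profiles
match the measured maxima, not the measured shapes: scenario results run
on them reproduce orderings and scalings, not field-specific timings.

Wind-regime schedules are stepwise: constant, or alternating between two
labelled profiles with a 50/50 duty cycle at a given period (daily or
hourly in the canonical experiments).

## Numerics

Finite-volume grid, z positive downward, nodes at (i−½)Δz, faces at iΔz;
defaults Δz = 0.2 m, Δt = 10 s, 10 m column (a `refined()` helper halves
both for sensitivity checks). Fluxes at interior faces combine Fickian
dispersion with first-order upwind advection; D and w at faces are
arithmetic means of the adjacent nodes. The surface and bottom faces carry
exactly zero flux at all times, so column cell mass is conserved to
round-off (verified to ≤ 10⁻¹⁰ relative over week-long runs).

Each step is a single combined explicit update (transport + reaction at the
same time level), ordered: environment → light → cell density → velocities
→ settling-kernel rebuild → fluxes and reaction → state update. The
Brownian and shear kernel components depend only on the per-regime
environment and are precomputed per depth; the settling component is
rebuilt each step from the instantaneous velocities.

Stability is guarded three ways: the diffusion number max(D)Δt/Δz² must
not exceed 0.5 and the Courant number max|w|Δt/Δz must not exceed 1
(checked before a run, with the velocity bound evaluated at the cell-density
limits); and if the reaction would remove more than 10% of any class in one
step — possible at seeded concentrations ≳ 10⁸–10⁹ m⁻³ — the reaction term
alone is sub-stepped internally. Together with upwinding these keep the
state non-negative structurally; residual round-off negatives (relative
magnitude < 10⁻⁹) are clipped, anything larger raises an integration error.

Appearance times τ_k (first time the column cell count N_k = Σ_z k n_k Δz
reaches 1 cell/m²) are linearly interpolated between recorded outputs and
clamped to be no earlier than the first output with any recorded mass in
the class. Output cadence (default hourly) should be well below the
timescale of interest; the concentration-sweep driver exposes it.

The first-order upwind scheme is numerically dispersive. On a pure
diffusion problem the computed decay rate converges to the analytic rate
under refinement (tested). For appearance times at the scaled validation
conditions (below), halving Δz and Δt shifts τ_kmax by only a few percent,
and the shift is not sign-stable at that problem size — the full-size
configuration, where large migrating colonies make advective smearing
matter, is reported in the source to slow appearance by ~20% under
refinement. The suite therefore asserts boundedness of the refinement
shift, not its sign.

## Validation scale

Scenario tests run a reduced problem chosen to keep the full suite around
a minute: k_max = 25 classes, Δz = 0.5 m, Δt = 30 s, 4–7 day horizons, and
(for regime comparisons) a seeded concentration of 2.3 × 10⁸ m⁻³ at which
the largest reduced class appears within ~1.5 days of constant high wind.
At these conditions the canonical orderings hold: high wind drives the
population to k_max while low wind stalls below k ≈ 10; 50/50 intermittent
wind (daily or hourly) slows largest-class appearance by roughly 2×; and
appearance is day-scale above 10⁸ m⁻³ but beyond a week at ~10⁷ m⁻³.
Passing these tests demonstrates the mechanisms and their interactions,
not field-specific numbers: real profiles (shapes, h_ML, stratification
history) and the full 101-class, six-week configuration are needed for
quantitative timing claims, and real lakes add growth, grazing and
fragmentation that the model deliberately omits.

## Known limitations

- No fragmentation/disaggregation, cell growth, nutrient or toxin
  dynamics; one horizontal-uniform column.
- The cell-density response constants are calibrated only to the velocity
  band, not to physiological measurements; EPS mass is folded into the
  cell-density bounds rather than modelled.
- Synthetic profiles reproduce regime maxima, not measured shapes.
- First-order upwind advection is dispersive; use the refined preset for
  sensitivity checks on timing quantities.
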