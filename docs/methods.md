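# Methods

## Scope and model hierarchy

The package evaluates a flow-based OSA severity marker, Cp\*, on
parametric airway geometries with a reduced-order solver. The reference
workflow it stands in for reconstructs patient-specific 3D airway lumens
from CT and solves unsteady RANS on them; here the lumen is an
axisymmetric duct with a severity-controlled velopharyngeal constriction
and the flow is a quasi-1D unsteady mechanical-energy balance. The
quantities the marker consumes — area-averaged plane pressures and the
mean velocity through the narrowest cross-section — are exactly the
quantities a quasi-1D model natively produces, which is what makes the
reduction appropriate for studying the *mechanism* of the marker. It does
not reproduce 3D features (jets impinging on walls, recirculation, Coanda
attachment, turbulence spectra), so absolute magnitudes should be read as
order-of-magnitude, not patient-predictive.

## Geometry

Seven regions in fixed anatomical order (nasal inlet, nasopharynx,
velopharynx, oropharynx, hypopharynx, larynx, trachea) with default
lengths 20/30/25/30/25/30/60 mm (220 mm total), baseline equivalent
diameter 16 mm, glottic diameter 12 mm — order-of-magnitude adult
anatomy; every value is overridable. Cross-sections are circular with
equivalent diameter `sqrt(4A/π)`: only area-averaged quantities enter the
marker, so non-circularity of real lumens is immaterial to the algebra.

Region-to-region diameter changes are cosine-tapered over a half-width of
half the shorter adjacent region, so the glottic contraction/expansion is
smooth at any station count ≥ 50 and the resolved physics does not change
along a grid-refinement ladder.

Disease severity `s ∈ [0, 1]` narrows the velopharynx linearly,
`d_min = d_base (1 − 0.75 s)`, floored at 25% of baseline so the
rigid-wall solver stays well-posed at `s = 1`. The constriction ramps in
with a half-cosine over the proximal quarter of the region, holds its
minimum over the middle half, and recovers **abruptly** (a true area
step) at three-quarters of the region length. The step is deliberate: the
inspiratory jet leaving a narrowed velopharynx separates rather than
diffusing, so pressure is not recovered there. Numerically, the step
keeps the detected sudden expansion and its Borda–Carnot coefficient
independent of grid resolution — a smooth taper would dissolve into many
sub-threshold interfaces whose summed loss vanishes under refinement.

Landmarks: pressure planes at the distal ends of the nasopharynx and
oropharynx; velocity plane at the minimum-area velopharyngeal station
(ties on the plateau resolve to the station nearest the region center).
Region boundaries, the plateau center and the step location are forced
into the station grid, so landmark *positions* are exactly
resolution-independent.

## Breathing

`Q(t) = A_t sin(2πt/τ)`, `A_t = πV_t/τ` so the inhalation half-cycle
integral is exactly the tidal volume. Defaults: `V_t = 500 ml`, `τ = 5 s`,
`Δt = 10⁻³ s`, simulated duration one half-cycle (2.5 s), metrics at peak
inhalation `t* = τ/4 = 1.25 s`. The period is exposed because the
"one breath in 2.5 s vs 5 s" convention is genuinely ambiguous in the
field; choosing `τ = 2.5 s` while keeping `t* = 1.25 s` puts the sampling
instant at zero flow, and the pipeline warns when that happens instead of
silently producing an undefined Cp\*.

## Flow solver

Rigid walls + incompressible air ⇒ `u(x,t) = Q(t)/A(x)` (continuity is
exact by construction, tested to 10 significant digits). Gauge pressure
referenced to 0 at the nasal inlet:

```
P(x,t) = − ρ Q'(t) ∫₀ˣ dx'/A   − ρ/2 (u² − u₀²)   − Lf(x,t)   − Lm(x,t)
```

- `Q'(t)` analytic (no differencing error); convective term evaluated as
  `ρ/2·Δ(u²)` exactly.
- `Lf`: accumulated Darcy friction `∫ f_D/D · ρu|u|/2 dx`, with
  `f_D = 64/Re` for Re ≤ 2000 (equivalently a 32 μu/D² gradient, finite
  as Re → 0), Blasius `0.316 Re^−0.25` for Re ≥ 4000, and a linear blend
  in Re between. Trapezoidal accumulation along the station grid.
- `Lm`: Borda–Carnot losses `K ρ u_up|u_up|/2`, `K = (1 − A_up/A_down)²`,
  at every interface where area grows by more than 10% between adjacent
  stations. With the geometry above, the only such interface is the
  constriction's recovery step, at every resolution ≥ 50 stations.
- Wall shear stress `τ_w = f_D/8 · ρu²` (= `8μ|u|/D` laminar).

Fluid defaults: air at ~20 °C, ρ = 1.204 kg m⁻³, μ = 1.82 × 10⁻⁵ Pa·s.
Inlet turbulence intensity has no quasi-1D counterpart and is recorded as
not applicable. Degenerate lumens (area below a 10⁻⁷ m² floor) raise a
solver error naming the station; non-finite fields raise a numerical
error with time/station indices.

Verification oracles (all in the test suite): Hagen–Poiseuille end-to-end
drop on a uniform tube within 0.1% across Re 10–1000; inviscid total
pressure `P + ρu²/2` constant within 0.1%; mirrored-instant pressure
symmetry of the inviscid full cycle; grid-refinement changes of the
end-to-end pressure drop strictly decreasing over 50/100/200/400 stations
(for the default constricted case: 1.4% → 0.44% → 0.05% relative to the
finest grid).

## Cp\* metric

`Cp* = sqrt(|P_o − P_n|) / V_v`, sampled at `t*` with linear time
interpolation (negligible error at Δt = 1 ms). Carried with its printed
units √(kg m⁻³); the conventional dimensionless `|ΔP|/(½ρV_v²)` is
reported alongside, never substituted. `V_v = 0` raises an
undefined-metric error per patient rather than returning infinity. The
invariant triple (nonnegativity; zero iff `P_o = P_n`; `cp² V² = |ΔP|` to
10 significant digits) is enforced on every constructed result.

Mechanism: between the two pressure planes the plane areas are equal, so
the reversible convective term cancels and at peak flow (`Q' = 0`) the
unsteady term vanishes; `|ΔP|` is friction plus the jet's expansion loss
`K(s)·½ρV_v²`. Hence `Cp*² ≈ |ΔP|/V_v² → ½ρ·K(s)` as severity grows —
a monotone function of anatomical narrowing that is insensitive to the
overall flow magnitude. This is the mechanism behind the marker's strong
correlation with AHI, and it is asserted directly: `V_v`, peak WSS, the
pharyngeal pressure drop and Cp\* are all nondecreasing over
`s ∈ {0, 0.25, 0.5, 0.75, 1}` at `t* = 1.25 s`.

Known limitation: below `s ≈ 0.13` the recovery step is under the 10%
detection threshold and the flow is laminar (`|ΔP| ∝ V`), so Cp\* dips by
~3% before the jet-loss regime takes over. The marker is designed to
rank *constricted* airways; hair-splitting between two nearly healthy
airways is outside its intended resolution.

## Synthetic cohort

Each virtual patient has a latent severity `s ~ U(0,1)`. The airway gets
a noisy copy `clip(s + N(0, σ_geom²), 0, 1)` (default σ_geom = 0.05,
imaging/anatomy noise); the AHI follows

```
AHI = round(clip(110 s^1.5 e^ε − 2, 0, 120)),   ε ~ N(0, σ_ahi²)
```

with default σ_ahi = 0.2. The power law is synthetic: it spans the
clinically observed 1–98 events/h from healthy to severe with a monotone
severity link, and its parameters are configuration-exposed. All draws
derive from one seed (reproducible to the byte). Because AHI is rounded
and clipped at 0, a noise-free cohort can tie at the low end; rank
correlation with severity is exactly 1 whenever the generated AHIs are
distinct. What passing cohort tests show is *parameter recovery* — the
pipeline recovers the link the generator put in (noise-free n = 20 gives
Cp\*–AHI Pearson r ≈ 0.99; with default noise r ≈ 0.94) — not clinical
validity: real AHI is also driven by non-anatomical factors (arousal
threshold, loop gain, muscle responsiveness) that the generator does not
model, and real airway compliance can decouple Cp\* from AHI at high
severities.

Severity bands use the standard AHI cutoffs 5/15/30
(none/mild/moderate/severe).

## Statistics

A single pre-specified two-tailed Pearson correlation between Cp\* and
AHI, significant at α = 0.01; p from the exact t transform
`t = r√(n−2)/√(1−r²)` on n−2 df (matching standard statistical packages),
with an exact n!-permutation p available as a cross-check for n ≤ 8. For
reference, r = 0.91 at n = 7 gives p = 0.004. A perfect affine relation
is reported as exactly |r| = 1 with p = 0 (float rounding from the
underlying library is snapped within 10⁻¹²).

## Problem sizes

Default runs use 201-station grids (plus forced landmark stations) and
2 501 time steps; a 20-patient cohort solves in a few seconds on one
core. The refinement ladder 50–400 stations and the 1000-seed
band-coverage study are the largest test computations.
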