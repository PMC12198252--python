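# Methods

## Scope and the central substitution

`pahemo` re-implements the desk-scale layers of a patient-specific
pulmonary-artery (PA) hemodynamics analysis for percutaneous pulmonary
valve implantation (PPVI): boundary-condition construction and
calibration, pulsatile flow solution, hemodynamic index computation and
the comparison statistics. The stage it deliberately does **not**
reproduce is the 3D finite-element Navier–Stokes solve on MRI-derived
anatomies (and everything upstream of it: segmentation, lofting,
meshing, mesh-independence studies). In its place the tree is solved as
a lumped-parameter (0D) network and radial velocity structure is
reconstructed analytically. Every downstream formula — Reynolds and
Womersley numbers, vorticity, energy dissipation, regurgitation
fraction — is then computed from these reduced fields exactly as it
would be from 3D ones.

Consequences to keep in mind when reading results:

* Viscous losses are Poiseuille losses. Under severe regurgitation a 3D
  flow dissipates most of its energy in recirculation and jet breakup,
  which a 0D network cannot represent; the synthetic pre/post energy-
  dissipation contrast is therefore much smaller than clinical values,
  and no test claims otherwise.
* The vorticity index reduces to shear of the reconstructed
  axisymmetric profile; secondary and swirling flows are absent. Only
  order-of-magnitude and trend agreement with published per-patient
  values is meaningful.
* Abstract-level clinical findings (per-patient velocities, volume-index
  correlations) require the original geometries and are out of scope.

## Model

**Geometry.** A `PATree` is a two-level bifurcating network of straight,
constant-radius segments: an MPA root, RPA/LPA principal branches, and
`n` outlet branches per side. Centerline arclength is tracked so the
branch measurement sites can be placed one MPA radius distal to the
bifurcation (crossing into child segments if the principal branch is
shorter; ties broken toward the largest-radius child). The MPA site —
unspecified in the clinical protocol, which only defines branch sites —
is the root's mid-length cross-section.

**Network.** Each segment contributes a Poiseuille resistance
`R = 8μL/(πr⁴)`; junctions are pressure-continuous and loss-free; walls
are rigid, so the only compliance lives in the outlet Windkessels. With
the inflow prescribed, the Windkessel capacitor pressures are the state
vector of a linear time-invariant ODE. The resistive layer is reduced
bottom-up to an affine relation between outlet flows, capacitor
pressures and the instantaneous inflow, so the response matrices are
assembled once per configuration.

**Integration.** BDF (implicit, adaptive) with relative tolerance 1e-8,
absolute 1e-10 and the exact (constant) Jacobian, reported on a fixed
grid of `steps_per_cycle` (default 256) over six cycles, with the last
cycle extracted for analysis. States are initialized at the steady
state of the cycle-mean inflow, which makes the cycle-to-cycle
periodicity defect of outlet volumes ~1e-8 by cycle six; the defect is
recorded on every solution so non-periodic configurations are
detectable. Six cycles are retained (rather than shortcutting to the
periodic solution) to mirror the simulation protocol this pipeline
emulates.

**Velocity profiles.** Segment flow is decomposed by FFT; the mean
component carries a Poiseuille parabola and each oscillatory harmonic
the fully developed oscillatory-pipe (Womersley) profile — a complex
Bessel-function radial shape scaled so the harmonic's sectional flow
matches its Fourier coefficient. 32 harmonics are retained by default:
the canonical half-sine-lobe waveforms have slope discontinuities, so
their spectra decay like k⁻², and 32 harmonics bring the flow
reconstruction error to ≈0.3% (8 harmonics leave ≈2%). The parabolic
inlet map distributes an instantaneous flow over a non-circular section
as `1 − (d/d_max)²` along centroid-to-boundary rays, rescaled so the
discrete surface integral equals the flow exactly.

## Indices

* `Re = ρVL/μ` with `L` the site diameter and `V` the cycle-averaged
  sectional mean speed `|Q|/A` (a forward-phase-mean alternative can be
  derived from the flow decomposition).
* `Wo = r√(2π/(νT))`; healthy PAs sit around 14–21.
* Vorticity: |∇×u| on the site disc — for the axisymmetric axial field,
  |∂u/∂s| — area-weighted over the disc and time-averaged over the last
  cycle. The closed-form check: steady Poiseuille flow with sectional
  mean `V̄` in radius `R` gives exactly `8V̄/(3R)`.
* Energy dissipation: cycle-averaged total-pressure flux in at the MPA
  minus out at all outlets, `⟨(P + ½ρV²)AV⟩`, converted to mW
  (10⁴ erg/s). Two conventions are exposed for the outlet pressure:
  the default `"face"` uses the outlet boundary face (upstream of the
  Windkessel proximal resistor — what a 3D solver reports at its caps),
  `"capacitor"` uses the Windkessel storage node and therefore adds the
  proximal-resistor losses. The formula's time treatment is also
  selectable: the default averages the full instantaneous flux;
  `"mean_pressure"` applies the literal cycle-averaged-pressure reading.
  All conventions coincide for steady flow.
* PR% = 100 × (∫max(−Q,0)dt) / (∫max(Q,0)dt) per cycle, with
  phase-mean forward/backward velocities.

All cycle integrals use the trapezoid rule with periodic wrap on the
uniform half-open time grid `[0, T)`.

## Boundary conditions and calibration

Total resistance comes from mean PA pressure over mean flow (default
driving pressure 13 mmHg, the median of the study population's printed
mean MPA pressures; 1 mmHg = 1333.22 dyn/cm²). Sides split by measured
flow share (`R_side = R_total/f`, preserving the parallel total), and
outlets within a side by Murray fractions `r^2.3/Σr^2.3` computed on
effective radii `r = √(A/π)` from cap areas. The Rp:Rd split (default
0.1) and washout time constant `τ = R_d C` (default 1.0 s, a typical
pulmonary Windkessel value) are not specified clinically and are
exposed as configuration.

Calibration rescales the two side blocks multiplicatively by
`achieved/target` (and the complement), renormalizes to preserve the
total parallel resistance, and re-solves; convergence is
`|achieved − target|/target ≤ 0.10`, reading the clinical "within 10%"
flow-split criterion as a relative, per-side bound. Exhaustion of the
iteration budget returns a flagged, non-converged report instead of
raising, so cohort runs continue past a difficult patient.

## Synthetic data: what it emulates and what it does not

The generators stand in for non-shareable MRI data. Defaults are the
study conditions: pre/post regurgitation fractions drawn around
44.2%/14.5% (SD 6/4 points, clipped to physiological ranges, post
forced ≥5 points below pre), stroke volume ~75 mL, period ~0.9 s, MPA
radius ~1.3 cm, ten outlets per side with log-normal radius dispersion
0.3, and a pre-implantation RPA flow share of 0.614 (the measured
right/left flow imbalance, 73.5 vs 46.2 mL/s; post 0.594). The inflow
shape is a forward half-sine over systole (fraction 0.35 of the cycle)
and a backward half-sine over diastole, chosen because both lobes are
smooth, integrable in closed form, and make the regurgitation fraction
exactly controllable; real MRI waveforms are neither half-sines nor
noise-free, and no morphological claim rests on the shape. Outlet areas
sum to 1.5× the principal-branch area per side (distal bed widening,
keeping outlet velocities physiological); the RPA principal radius
ratio (0.76) slightly exceeds the LPA's (0.70), matching the dominant
right lung.

Passing tests on these cohorts demonstrate that the machinery is
correct (conservation, calibration, determinism, statistics), not that
real patients would show the published effect sizes — the muted ED
contrast discussed above is the clearest example.

## Statistics

The exact Wilcoxon tests enumerate the full null distribution of the
observed mid-rank multiset — all 2ⁿ sign assignments for the
signed-rank test (n ≤ 14), all group splits for the rank-sum test
(n ≤ 20) — and report two-sided p-values as exact rationals
(probability of a statistic at least as far from its center as
observed). Zero differences are dropped; ties get mid-ranks. The
tie-corrected normal approximation (no continuity correction) is
provided because clinical reports typically print its values: nine
one-signed paired differences give exact p = 2/512 ≈ 0.0039 where the
approximation prints ≈0.008. On the packaged reference table's
energy-dissipation pairs the exact test gives 1/32 = 0.031 and the
approximation 0.033; the source report prints 0.028 for that
comparison, a software-variant discrepancy recorded here rather than
reconciled. No multiple-testing correction is applied, matching the
source analysis.

Screened regression fits each covariate alone (OLS with intercept),
keeps those with two-sided p < α (default 0.05), and refits the kept
set jointly; a rank-deficient screened design raises an error naming
the collinear columns. Categorical indicators are passed as 0/1 columns
and may accompany the continuous variables they were derived from.

## Reference table

The published nine-patient pre/post index table (per-branch Re, Wo, Vo
and whole-bed ED) ships as a CSV fixture with a SHA-256 integrity
check. Its printed mean/SD rows were computed by the source from
unrounded per-patient data, so recomputation from the printed
(one-decimal) entries reproduces every cell to within one unit of the
last printed digit — and the branch Womersley SD cells, printed with a
second decimal below the resolution of their inputs, to within 0.02.

## Numerical choices and limitations

* CGS units internally; clinical units only at I/O boundaries.
* Degenerate inputs fail loudly: non-positive radii/pressures/areas,
  flow fractions outside (10⁻⁶, 1−10⁻⁶), regurgitation targets ≥ 1,
  all-backward flows, missing outlet Windkessels.
* Problem sizes in the test suite and acceptance script (128-sample
  waveforms, 128 solver steps per cycle, 20-tree calibration studies,
  n = 3 pipeline smoke runs) are chosen so the full verification cycle
  completes in minutes while staying inside the convergence plateaus
  demonstrated by the grid-refinement and harmonic-truncation tests.
* Junction pressure losses, wall compliance (FSI), wall shear stress,
  turbulence and intracardiac flow are out of scope by design.
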