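# Methods

This note documents the models, calibrations, numerical choices and
limitations of `virtuheart`.  It is the package's own account of what it
computes; every number quoted here is produced by the code (tests or the
acceptance script), not asserted.

## Fused fibrosis segmentation

LGE-CMR is an image of relative signal intensity.  The pipeline estimates
the mean and SD of the "remote" (nonfibrotic) myocardium per slice and
labels a voxel dense if its intensity exceeds `mean + T_Dense*SD`, diffuse
if it lies in `(mean + T_Diffuse*SD, mean + T_Dense*SD]`.  The
one-size-fits-all convention is (T_Diffuse, T_Dense) = (3, 5).

**Remote-region estimation.**  Clinical practice draws a manual
low-intensity ROI; as a reproducible surrogate we fit a two-component
Gaussian mixture to the masked slice intensities and take the lower-mean
component's mean/SD.  Constant slices and slices with <100 masked voxels
are rejected.

**Personalized thresholds.**  A single mid-ventricular postcontrast T1 map
is classified by relaxation-time bands: < 350 ms dense, 350–450 ms diffuse
(both boundaries inclusive to diffuse), > 450 ms normal.  Its dense and
diffuse *area fractions* are binned onto the matching LGE slice
(nearest-neighbor, grids share the field-of-view center; the slice is
matched by z coordinate, ties toward the lower index).  T_Dense is the
`(1 - f_dense)` linear-interpolation empirical quantile of the masked slice
intensities, T_Diffuse the `(1 - f_dense - f_diffuse)` quantile, both in SD
units above the remote mean.  Only area fractions are transferable through
global thresholds; the spatial correspondence is implicit in the shared
slice and the monotone relation between gadolinium retention, LGE intensity
and (inversely) T1 time.  Empty fibrotic classes yield thresholds above the
slice maximum (zero fractions, order preserved by an epsilon offset).  By
construction, re-applying the derived thresholds to the matching slice
reproduces the T1 fractions to within one voxel's area fraction; this is
enforced as an invariant over 50 seeded synthetic patients.

## Synthetic imaging data

The generator emulates the study conditions, not any particular patient:
an annular short-axis LV (truncated ellipsoid wall, ≥8 slices, 2 mm
in-plane / 8 mm slice spacing; T1 slice at 1.5 mm in-plane).  Fibrosis
texture is a thresholded Gaussian random field with a configurable
correlation length (default 8 mm): the top `dense_fraction` of the field is
dense, the next `diffuse_fraction` diffuse.  Default burdens are the cohort
means of the fused models (diffuse 40.5%, dense 3.8%).  The noiseless LGE
intensity is a strictly increasing piecewise-linear map of the field with
landmarks chosen so that, after the mixture fit, the personalized
thresholds land on the reported scales (T_Diffuse ≈ 0.5–1.5 SD, T_Dense ≈
5 SD) and the (3,5)-SD pipeline recovers roughly 9–11% diffuse burden; the
T1 map is a strictly decreasing piecewise-linear map of the same noiseless
intensity hitting 450 ms and 350 ms exactly at the class boundaries, plus
independent Gaussian noise (10 ms per unit `noise_sd`; LGE noise 4
intensity units per unit).  With `noise_sd=0` the in-mask T1 rank order is
exactly the reverse of the LGE rank order.  What passing these tests shows
is that the *algorithm* transfers fractions correctly; it says nothing
about MRI artifacts, partial-volume effects, or real HCM intensity
distributions, none of which are modeled.

## Myocyte model and its calibration

Membrane kinetics follow the 2006 ten Tusscher–Panfilov human ventricular
formulation, epicardial parameter set, with an added late sodium current
I_NaL = g_NaL·mL·hL·(V−E_Na) (activation gate sharing the fast-Na
activation time constant, inactivation time constant 200 ms; g_NaL nominal
0.0075 nS/pF).  Integration: Rush–Larsen for Hodgkin–Huxley gates, forward
Euler for V and concentrations, the quadratic rapid-buffering update for
the three calcium compartments; default dt 0.02 ms (cell), stimulus
−52 pA/pF for 1 ms.  APD90 is measured on the final beat of a steady
1 Hz × 30-beat train, from maximum dV/dt to 90% repolarization toward the
pre-stimulus potential, with linear interpolation of the crossing.

**Baseline calibration.**  The nonfibrotic target is APD90 = 280 ms.  The
base formulation's intrinsic APD90 under this protocol is 308.6 ms at
g_NaL = 0, so no non-negative late-sodium conductance can reach the target;
`calibrate_g_nal` exists and raises an informative error in this regime.
The package therefore calibrates the *repolarization reserve*: one joint
multiplier on (G_Kr, G_Ks), preserving their published ratio, bisected to
1.345865 (APD90 = 280.0 ms).  Single-conductance alternatives were
considered and rejected on the physiology they predict after remodeling:
scaling G_Kr alone yields a remodeled APD90 of ≈341 ms and G_Ks alone
≈317 ms, while the joint scale yields 333.1 ms (+19.0%), consistent with
the reported ≈330 ms (+18%).

**Remodeled (diffuse fibrosis) variant.**  Eight factors applied to the
calibrated baseline: g_NaL ×2.07, G_CaL ×1.19, G_Kr ×0.66, G_Ks ×0.73,
G_to ×0.15, G_K1 ×0.85, k_NaCa ×1.34, V_maxup (SERCA) ×0.57.  Net effect:
APD90 280 → 333 ms and a phase-1 notch depth reduced from ≈23 to ≈12 mV.
The choice of the epicardial cell type and the I_NaL formulation are
conventions; the transmural cell type of the source recordings is unknown.

## Tissue model

Monodomain reaction–diffusion on structured 2-D quadrilateral grids sampled
from tissue label maps.  Dense elements are excluded from the conducting
domain (internal no-flux boundary — numerically cleaner than
zero-conductivity elements and physiologically identical for inexcitable
tissue); diffuse elements conduct with unchanged conductivity but carry the
remodeled myocyte.  The diffusivity tensor per element is
`d_t I + (d_l − d_t) f fᵀ` with `d = sigma/(chi · Cm)`, chi = 1400 cm⁻¹,
Cm = 1 µF/cm².  Fibers come from the Laplace–Dirichlet rule-based method:
harmonic transmural field (endo 0, epi 1; 5-point stencil, sparse direct
solve), circumferential frame from the transmural gradient and the
apicobasal direction (out-of-plane for short-axis slices), helix angle
linear from +60° (endo) to −60° (epi).  Elements with vanishing gradients
fall back to the nearest well-defined frame (logged).

**Conductivity calibration.**  sigma_l = 0.202888 S/m was bisected so the
planar CV along fiber is 0.600 m/s at 350 µm spacing (the mesh-resolution
window for stable electrophysiology simulation is 300–400 µm; CV stays
within 5% of target across that window).  sigma_t = sigma_l/4, giving a CV
anisotropy ratio that converges to √4 = 2 on fine grids (2.075 at 75 µm).

**Numerics.**  First-order operator splitting: explicit conservative
finite-volume diffusion (edge conductances from flanking-element tensors;
diagonal stencil terms for the cross tensor component), then the per-node
ionic step.  Gate steady states, Rush–Larsen factors, and the
voltage-dependent current factors are pre-tabulated on a 0.05 mV grid;
Nernst potentials are refreshed every 10 steps.  Fully repolarized nodes
with negligible net current may "sleep": their state is frozen and, on
waking (neighbor depolarization or stimulus), gates are advanced by the
exact constant-voltage Rush–Larsen solution over the slept interval.  An
explicit-stability guard rejects dt above the diffusion limit; |V| >
200 mV aborts with diagnostics.  The tissue kernel is cross-checked against
the reference single-cell integrator on an isolated node.

## Desk-scale induction studies

The full-scale pacing protocol family (6 S1 at 600 ms; extrastimuli from
90% of the cycle, −10 ms steps) is provided, but the substrate studies run
a scaled-down configuration chosen once and used throughout: annular 2-D
substrates of outer/inner radius 20/11 mm at 1 mm resolution, isotropic
conduction at half the calibrated longitudinal conductivity (discrete
planar CV ≈ 0.14 m/s, so the reentrant wavelength fits the annulus),
dt 0.15 ms, and a drive train of 2 S1 at 500 ms with S2 from 63% of the
cycle, −15 ms steps to 255 ms, then one further extrastimulus (S3) starting
one decrement below the shortest fully propagated S2; observation window
2000 ms.  Loss of capture is declared when a premature beat fails to
propagate through at least half the conducting nodes (local capture with
distal block ends that stage, mirroring effective-refractory-period
determination).  Pacing stimuli are −100 pA/pF × 2 ms plugs of conducting
tissue within 2.5 mm of the endocardial site (a sector whose endocardium is
scar snaps to the nearest conducting tissue).

**Reentry detection.**  After the last stimulus, a node's first activation
is its direct response; reentry is declared iff at least 8 nodes accumulate
≥2 further reactivations and the activity persists past the window midpoint
(or the run was stopped early on accumulating upstrokes).  The descriptor
records the median inter-activation cycle length and the core sector (the
earliest re-activated region, on the 7-sector partition).  Morphologies are
considered identical when core sectors match and cycle lengths differ by
<10% — the equivalence rule is a stated stand-in, as no operational
definition exists in the clinical literature for simulated VA morphologies.

**What the desk studies show.**  On these substrates the induced reentry is
anatomical circus movement around the annulus enabled by unidirectional
block at remodeled-tissue borders or protected-isthmus mouths (cycle
lengths ≈ 450–650 ms).  The homogeneous nonfibrotic annulus is
non-inducible from all seven sites; the protected-isthmus scar substrate
with a remodeled channel is inducible from several; across matched
substrate pairs, adding a cohort-level diffuse burden (one to two
transmural remodeled arcs, ~40% of myocardium, on a fixed, verified
non-inducible baseline geometry) never reduces and on average increases the
number of inducing sites and unique morphologies.  These are directional,
mechanism-level statements: the desk substrates cannot and do not reproduce
patient-specific induction counts, 3-D intramural reentry, or the
fibrosis-texture microstructure of real HCM hearts.  The paired design
fixes the baseline geometry because inducibility of *homogeneous* rings
under aggressive double-extrastimulus pacing is itself geometry-sensitive
at this resolution; holding geometry fixed makes the diffuse burden the
only manipulated variable.

## Risk evaluation

A heart is at risk iff ≥1 of the 7 sites induces.  Confusion metrics use
the standard definitions; degenerate denominators give NaN (undefined),
never 0.  Report rounding is half-up to one decimal with an intermediate
half-up rounding at two decimals, matching the printed-table style of the
source cohort (the convention matters for exactly one cell, a sensitivity
of 7/13 → 53.85 → 53.9).  The clinical ACCF/AHA and ESC verdicts enter as
fixture booleans: the guidelines' scoring formulas are out of scope — the
contribution being evaluated is the comparison, not the scores.  Two
published table cells (an LGE-T1 PPV of 78.8 and accuracy of 80.1) are
arithmetically inconsistent with the published counts (11/14 = 78.6,
21/26 = 80.8); the package reports the count-derived values.

## Known limitations

* 2-D structured grids only; no patient anatomy, no RV, no 3-D tetrahedral
  meshing, no mechanics.
* The desk conduction regime trades CV accuracy for tractable wavelengths;
  absolute induction coupling intervals are not physiologic measurements.
* Gray-zone sub-banding, MOLLI reconstruction, DICOM handling and MRI
  artifact simulation are out of scope.
* The synthetic intensity model is a placeholder distribution, not a claim
  about real HCM LGE statistics.
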