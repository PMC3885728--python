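# Methods

`fmtomo` is a desk-scale re-creation of a preclinical optical molecular
imaging workflow: a fluorescent (tumor) source embedded in a scattering
tissue volume is probed by four-angle transillumination, the source
distribution is recovered by an L1-regularized homotopy reconstruction, and
longitudinal two-arm treatment studies are summarized with per-day ANOVA.
Because no in vivo data are available, every input is produced by the
package's own synthetic generators; this note records the models, defaults
and numerical choices, and what the synthetic setting can and cannot show.

## Photon transport

Light propagation is modeled by the steady-state diffusion approximation

    -div(D grad Phi) + mu_a Phi = q,        D = 1 / (3 (mu_a + mu_s')),

valid in highly scattering tissue (mu_s' >> mu_a). The PDE is discretized
with 7-point finite differences on the phantom's voxel grid; face diffusion
coefficients are harmonic means, so the operator is symmetric positive
definite and reciprocity (source/detector exchange symmetry) holds to solver
tolerance. On the tissue surface a Robin (partial-current) condition
`Phi + 2 A_n D dPhi/dn = 0` accounts for internal reflection at the
tissue/air interface; `A_n` is computed from the Egan–Hilgeman fit at
refractive index n = 1.37 (`A_n ≈ 3.0`), configurable. The system is
factorized once per volume (sparse LU) and reused for every excitation and
detector adjoint solve; factorizations are cached keyed by volume content.

Discretization accuracy: for a point source in a homogeneous medium the
shell-averaged fluence follows the infinite-medium Green's function
`exp(-mu_eff r) / (4 pi D r)` to within 5% for radii from 3 voxels out to
mid-domain (about a third of the domain width at the default optical
properties). Two caveats are inherent to the setup rather than bugs: within
~3 voxels of the source the discrete delta makes individual voxels deviate
by a few percent (anisotropy of the 7-point stencil), which is why the
comparison is against the radial profile; and near the boundary the Robin
condition correctly depresses the fluence relative to the *infinite-medium*
formula, so the analytic comparison is only meaningful away from the
surface.

## Phantom and acquisition geometry

The torso proxy is a capsule (finite cylinder with hemispherical caps) along
z, radius 85% of the grid half-width by default; the tumor is a homogeneous
sphere of fluorophore yield (default radius 2 mm, centered off-axis as a
liver-lobe proxy). Background optical properties default to
mu_a = 0.02 /mm, mu_s' = 1.0 /mm — typical soft-tissue values near
500–525 nm. Tumor voxels share the background optical properties (pure
emission contrast) unless an absorption contrast factor is configured.

Acquisition is transillumination at projection angles 0°, 90°, 180°, 270°
about z (right-handed, 0° = illumination from +x). Per angle one excitation
point enters at mid-height on the illuminated side (the collimated beam is
modeled as an isotropic point source one transport mean free path
1/mu_s' below the surface) and a detector grid — default 5 transverse
positions spanning ±40° of arc × 9 axial positions spanning 60% of the
torso length — samples the fluence at surface voxel centers on the opposite
side. No lens/CCD model is applied; laser power (20 mW) scales the
excitation field, and wavelengths (488/525 nm) are metadata. Measurement
noise is additive Gaussian at a configurable SNR (default 30 dB,
sigma = rms(signal) · 10^(−SNR/20)).

## Born sensitivity matrix and the inverse crime

The fluorescence measurement is linear in the yield density x:
row (s, d) of the system matrix is `G_em(r_d, r_j) · Phi_ex,s(r_j)` over
masked voxels j, with the emission Green's function obtained by one adjoint
solve per detector. On a common grid, `A x` reproduces the simulated
noise-free measurements to machine precision (an internal consistency
oracle). Reconstruction therefore *never* runs on the simulation grid:
`reconstruct` coarsens the volume by an integer factor (default 2) and
builds A there, so the forward data contain discretization error relative
to the reconstruction operator. A normalized-Born option (rows divided by
the excitation signal at the detector) exists but is off by default, since
it changes measurement units.

## Homotopy reconstruction

The solver tracks the piecewise-linear solution path of

    min_x 0.5 ||b - A x||^2 + lam ||x||_1

from lam = ||A^T b||_inf downward. Each iteration: (1) residual
correlations c = A^T(b − Ax); (2) supporting set I = {i : |c_i| ≥ lam − tol}
(ties all admitted); (3) direction from the Gram system
(A_I^T A_I) d_I = sign(c_I); (4) smallest positive entrant step gamma+ over
inactive indices ((lam∓c_i)/(1∓a_i^T A_I d_I)) and leaver step gamma− over
active indices (−x_i/d_i); (5) append or remove depending on which is
smaller; (6) x_I += gamma d_I, lam −= gamma. Because lam is driven down
adaptively along the path, no a-priori regularization parameter estimate is
needed; at every breakpoint the iterate is the exact LASSO solution at the
current lam (verified by KKT certificates and an independent
coordinate-descent oracle in the tests).

Numerical choices:

* Tie between gamma+ and gamma− (within tol, default 1e-10): the removal is
  processed first — removing before adding avoids a singular Gram matrix
  from a simultaneous add/remove.
* Rank-deficient Gram matrix: the most recent entrant is dropped once and
  the iteration retried; a second failure raises with the trace attached.
* The solver is the *signed* path; nonnegativity of fluorophore yield is
  imposed only at the reporting stage by clamping negatives to zero
  (`nonneg_clamp`, default on). Running the signed path keeps steps 4–5
  exactly as stated; in practice the recovered coefficients are almost
  entirely nonnegative for physical data.
* Columns of A are used unnormalized by default (a normalization flag would
  change the lam scale).
* Stopping: first of relative residual ≤ 0.05, active-set size reaching 5%
  of the unknowns, lam ≤ 1e-6 · lam_max, or 10 × max_active iterations; all
  recorded per-iteration in the trace. When no event remains the path runs
  linearly down to lam_min ("cap" event).
* The coordinate-descent cross-check is applied at visited lam ≥ 1e-4
  lam_max; below that the CD oracle itself fails to converge in the nearly
  flat objective (its attained objective is measurably worse than the path
  solution's), while the KKT certificate — which is checked at *every*
  breakpoint — remains the complete optimality test.

## Quantification

Reconstruction readouts: total power (sum of clamped yield × voxel volume,
arbitrary units unless an instrument calibration constant is supplied —
absolute mW-scale powers are not reproduced), half-maximum volume
(voxels above 50% of the peak, threshold configurable), yield-weighted
centroid, and centroid distance to the known truth.

Study readouts: caliper tumor volume 0.5·a·b² (a, b = longer and shorter
diameters); percent change 100·(reference − value)/reference; per-day
one-way ANOVA across the two groups (equivalent to the pooled two-sample
t-test via F = t²), significance at alpha = 0.05 with no multiple-testing
correction across days (a Holm option exists, off by default, matching
per-day usage); and `first_significant_day`, which by default requires
significance at that day *and all later measured days* (persistence rule —
sustained divergence), configurable to a single-day rule. Degenerate ANOVA
inputs are explicit: equal means with zero within-group variance give
F = 0, p = 1; differing means with zero variance give F = inf, p = 0.

## Study generator

Each animal i in group g has a log-normal baseline S0_i (mean `s0_mean`,
CV `animal_cv`) and expected intensity S0_i · exp(rate_g · day); observed
intensity is multiplied by log-normal measurement noise (CV
`measurement_cv`). Log-normal noise is the natural choice for strictly
positive intensities spanning decades. Defaults: days (0, 4, 8, 12) with
treatment and imaging clocks coinciding; n = 12 per group; animal CV 0.3;
measurement CV 0.15; treated growth rate 0.6 × control.

The control growth rate defaults to 0.13/day (doubling time ≈ 5.3 days,
realistic for an aggressive hepatoma xenograft). This value was chosen to
place the arms' statistical divergence at the *second* post-baseline imaging
day (day 8) rather than day 4: across the plausible range (≈0.08–0.18/day)
it maximizes the probability that day 8 is the first day of sustained
significance. The baseline `s0_mean = 1.6e6` photons/cm²/s then puts the
day-12 control group mean near 7.8e6 — the order of magnitude typical of
luciferase xenografts — but this is a scale convention, not a fit.

An intrinsic limitation of this design is worth stating: with a persistent
per-animal baseline (CV 0.3) shared across days, the per-day tests are
strongly positively correlated (log-scale correlation ≈ 0.8), and the day-8
effect is only twice the day-4 effect on the log scale. Consequently no
growth rate makes "first significant at day 8" happen much more than about
half the time at n = 12: whenever day-8 power is high, day 4 already
rejects in a third of studies. The Monte-Carlo tests report this fraction
honestly (~50% at the defaults; the modal first-detection day *is* 8).

Caliper diameters are generated so that 0.5·a·b² tracks the expected
intensity through a fixed monotone power law
V = 100 mm³ · (S/S0_mean)^0.5 (caliper volume responds less dramatically
than viable-cell light output; 100 mm³ is the enrollment volume), with a
fixed aspect ratio a/b = 1.3 and diameter noise at one third of the
intensity measurement CV. Body weight is ~20 g with 5% between-animal CV,
0.3 g day-to-day jitter and no group effect (a type-I control).

What the generator does *not* emulate: organ-heterogeneous optical
properties, CT-derived body surfaces, treatment-onset delays or nonlinear
growth saturation, inter-day drift in instrument calibration, and animal
dropout. Passing tests therefore demonstrate the correctness and
statistical behavior of the algorithms under the stated model, not
performance on real animal data.

## Problem sizes

Default grids are 40×40×60 voxels at 0.5 mm (simulation) and 20×20×30 at
1 mm (reconstruction, ~5,700 unknowns from 180 measurement rows); recovery
Monte-Carlos use 50 noise realizations and study Monte-Carlos 200 simulated
studies. These sizes were chosen so a full verification run completes in a
few minutes on one CPU while remaining in the regime where the diffusion
discretization is accurate and the inverse problem is genuinely
underdetermined.

## Reproducibility

Every stochastic stage consumes an explicit seed; the pipeline derives
per-stage substreams from a single seed by hashing the stage name into a
`numpy` `SeedSequence` spawn key, so stages can be rerun independently.
A pipeline run writes a manifest with SHA-256 checksums of every artifact;
identical config + seed reproduces identical checksums on one platform.
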