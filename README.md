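# fmtomo

Fluorescence molecular tomography (FMT) at desk scale: a diffusion-based
photon-transport forward model, a homotopy (LASSO-path) sparse
reconstruction of 3-D fluorophore distributions, and the longitudinal
quantification used to read anti-tumor drug response out of optical imaging
studies. Everything runs on synthetic data generated by the package itself —
a mouse-torso-like optical phantom with an embedded fluorescent "tumor", and
two-arm treatment studies with exponential tumor growth — so the whole
pipeline is reproducible, testable, and free of animal data.

Who it is for: people developing or teaching optical tomographic
reconstruction and preclinical imaging statistics who need a transparent,
verifiable reference implementation rather than an instrument vendor's
black box.

## The model

**Forward problem.** Photon transport in tissue is modeled by the
steady-state diffusion approximation
`-div(D grad Phi) + mu_a Phi = q` with `D = 1/(3(mu_a + mu_s'))`,
discretized by 7-point finite differences with a Robin boundary condition
for the tissue/air refractive mismatch. Acquisition is four-angle
transillumination (0°/90°/180°/270°): per angle, a 20 mW excitation point
source on one side, a grid of detectors on the opposite surface. The
measurement is linear in the fluorophore yield density `x`: the Born
sensitivity matrix has rows `A[(s,d), j] = G_em(r_d, r_j) Phi_ex,s(r_j)`.

**Inverse problem.** The reconstruction solves
`min_x 0.5 ||b - A x||^2 + lam ||x||_1` by the active-set homotopy method,
tracking the piecewise-linear solution path from `lam = ||A^T b||_inf`
downward: compute residual correlations `c = A^T (b - A x)`; update the
supporting set `I = {i : |c_i| >= lam}`; solve `(A_I^T A_I) d_I =
sign(c_I)` for the direction; take the smaller of the entrant step
`gamma+` and the leaver step `gamma-` (minima over positive arguments
only); add or remove that index; update `x_I += gamma d_I`,
`lam -= gamma`. Because `lam` is lowered adaptively along the path, the
result does not depend on an a-priori regularization estimate. The solver
is exposed as a scikit-learn estimator (`HomotopyLasso`) with
`fit`/`predict`, `coef_`, and a full per-iteration trace.

**Quantification.** Reconstructions are summarized by total power,
half-maximum volume and centroid; studies by caliper tumor volume
`0.5 a b^2`, percent change `100 (ref - value)/ref`, per-day one-way ANOVA
across treatment arms (alpha = 0.05) and the first day of persistent
statistically significant divergence.

## Worked example

```python
import fmtomo
from fmtomo.forward import AcquisitionGeometry, simulate_measurements
from fmtomo.homotopy import reconstruct
from fmtomo.quantify import summarize_recon

vol, truth = fmtomo.make_phantom()          # 40x40x60 @ 0.5 mm, 2 mm sphere
geom = AcquisitionGeometry.auto(vol)        # 4 angles x 1 excitation x 45 detectors
meas = simulate_measurements(vol, truth, geom, snr_db=30.0, seed=0)
recon, trace = reconstruct(vol, geom, meas)  # homotopy on a 2x coarser grid
s = summarize_recon(recon, truth=truth)
print(f"centroid error {s.localization_error_mm:.2f} mm, "
      f"half-max volume {s.volume_mm3:.1f} mm^3, "
      f"{trace.iteration} path iterations ({trace.stop_reason})")
```

prints (seed 0):

```
centroid error 0.77 mm, half-max volume 2.0 mm^3, 113 path iterations (residual_tol)
```

i.e. the reconstructed source centroid lands 0.77 mm from the true sphere
center — under one reconstruction voxel — and the path stopped when the
measurements were fit to 5% relative residual. The half-max volume
underestimates the 33.5 mm^3 sphere: an L1 reconstruction from 180
boundary measurements concentrates the recovered energy in few voxels, so
localization is reliable while absolute volume is not (see
`docs/methods.md`).

The same pipeline is scriptable end to end, with a checksummed manifest:

```sh
fmtomo run --seed 1 --out demo_run      # phantom -> forward -> recon -> report
fmtomo simulate-study --seed 1 --out study.csv
fmtomo quantify study --study study.csv
```

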