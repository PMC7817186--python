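# istomo

Label-free 3D segmentation and kinetic analysis of immune-cell conjugates
from optical-diffraction-tomography (ODT) refractive-index volumes.

When a cytotoxic effector cell (for example a CAR-T cell) engages its
target, the two cells form an **immunological synapse (IS)** — a tight
cell-cell junction where receptors and cytotoxic machinery concentrate.
ODT measures the 3D refractive index (RI) n(**r**) of the live conjugate
without any labels, but the two touching cells have no fluorescent marker
to tell them apart, so segmenting effector, target and synapse from RI
alone is the hard part.  `istomo` implements the full computational
pipeline:

1. **Reconstruction** — angle-scanned off-axis holograms are demodulated,
   converted to complex Rytov phases, mapped onto Ewald caps in the 3D
   object spectrum (Fourier diffraction theorem), and the missing cone is
   filled by non-negativity-constrained alternating projections.
2. **Annotation** — a classical 4-hyper-parameter pipeline (seed points,
   RI threshold, grain-merging size, smoothing sigma) feeds a marker-based
   3D watershed; multiple annotations are merged by STAPLE
   (expectation-maximization consensus with per-rater sensitivity p and
   specificity q).
3. **Distance regression** — a U-shaped 3D network with residual encoder
   blocks and large-kernel separable ("global convolution") skip modules
   regresses a **signed Euclidean distance map**: positive inside the
   effector, negative inside the target, zero on background.  Training
   minimizes a boundary-weighted L1 loss with Adam.  The tensor engine is
   self-contained NumPy (explicit forward/backward per layer), so training
   and inference run on a plain CPU with no framework dependency.
4. **Post-processing** — masks by thresholding the distance map at
   ±54.5 nm, the synapse as the overlap of the two masks dilated by two
   voxels (437 nm), and surface/interior shells by one-voxel erosion.
5. **Quantification** — synapse area A(t), surficial protein density
   (fg/μm²), total synapse protein (fg), density-weighted center-of-mass
   trajectories, and saturating-hyperbola fits

   y(t) = y_max · t / (t + τ½),

   plus 10-s early/late rate windows and exact small-sample Wilcoxon
   tests.  RI converts to protein concentration through the refractive-
   index increment α = dRI/dc = 0.185 mL/g: c = (n − n_m)/α.
6. **Evaluation** — volumetric mask Pearson correlation (%) and boundary
   displacement error (voxels / nm).

Every stage is exercised on synthetic two-cell phantoms generated by the
package itself (`istomo.phantom`), so the complete pipeline is testable
without any external data.

## Worked example

Simulate a noiseless conjugate time-lapse whose contact area and cell
translocation follow saturating hyperbolas, then measure and refit them:

```python
import numpy as np
from istomo import contact_area, center_of_mass, fit_hyperbola, ri_to_density
from istomo.phantom import default_timelapse_spec, make_timelapse

spec, kin = default_timelapse_spec()      # A_max=106.16 um^2, tau=39.63 s, ...
frames = make_timelapse(spec, kin)        # 51 frames, 0..300 s at 6 s

t = np.array([f.state.time_s for f in frames])
area = np.array([contact_area(f.pair) for f in frames])
fit = fit_hyperbola(t, area)
print(f"synapse area fit: A_max = {fit.y_max:.2f} um^2, "
      f"tau_1/2 = {fit.tau_half:.2f} s, rho = {fit.rho:.3f}")

coms = []
for f in frames:
    density = ri_to_density(f.tomogram, alpha_ml_per_g=0.185)
    coms.append(center_of_mass(density, f.pair.effector))
disp = np.linalg.norm(np.array(coms) - coms[0], axis=1) / 1e3
dfit = fit_hyperbola(t, disp)
print(f"effector displacement fit: dd_max = {dfit.y_max:.2f} um, "
      f"tau_1/2 = {dfit.tau_half:.2f} s, rho = {dfit.rho:.3f}")
```

Output:

```
synapse area fit: A_max = 104.86 um^2, tau_1/2 = 36.84 s, rho = 1.000
effector displacement fit: dd_max = 7.48 um, tau_1/2 = 37.85 s, rho = 1.000
```

The displacement parameters come back essentially exact; the area
parameters carry a few percent of voxelization bias at the default
218.5 nm pitch (the contact of two barely-touching spheres is ambiguous
at sub-voxel gaps; see `docs/methods.md`), and converge to the generating
values as the pitch is refined.

A command-line front end mirrors the stages:

```bash
istomo simulate --seed 1 --out phantoms/ --n-phantoms 12
istomo train --phantom-dir phantoms/ --out model.npz --epochs 60
istomo infer --model model.npz --in tomogram.h5 --out distmap.h5
istomo postprocess --in distmap.h5 --out masks.h5
istomo quantify --in timelapse.h5 --out metrics.csv
istomo evaluate --pred-dir pred/ --ref-dir ref/ --out eval.csv
```

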