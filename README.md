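# lapwsim

Image-segmentation-free electrophysiology models of the **left atrial
posterior wall (LAPW)**, built directly from electroanatomical **point-cloud
data (PCD)**. The package is for cardiac-EP modelers and mapping researchers
who have catheter-exported wall points and unipolar electrograms (EGMs) and
want patient-scale volumetric simulations plus a quantitative
recorded-vs-simulated comparison — without MRI/CT segmentation.

The pipeline:

1. **Geometry** — downsample the PCD to a minimum spacing, reconstruct the
   sheet surface (PCA-plane Delaunay), clean extrusion-hostile vertices,
   extrude by the wall thickness (2.3 mm), split into tetrahedra, refine
   uniformly.
2. **Fibers** — rule-based transmural fiber rotation, atlas-style mapping by
   translation + scaling, transversely isotropic monodomain conductivity
   σ̄ = σ_l f⊗f + σ_t(I − f⊗f) with σ = σ_iσ_e/(σ_i + σ_e) per direction,
   and iterative calibration of a common scale factor K to a measured
   conduction velocity via CV ∝ √σ.
3. **Fibrosis** (optional) — 3-D Perlin-noise patterns (compact, diffuse,
   interstitial, patchy) at exact densities, applied as percolation: tagged
   elements are simply never solved.
4. **Simulation** — monodomain χ(C_m ∂V_m/∂t + I_ion + I_stim) = ∇·σ̄∇V_m
   with the 21-variable Courtemanche human atrial ionic model, explicit P1
   FEM (Rush–Larsen gates + lumped-mass diffusion), cube-region stimuli
   (25 pA/pF, 2.5 ms).
5. **Electrograms** — infinite-volume-conductor unipolar forward model
   φ_e = 1/(4πσ_b) Σ χ I_m V/r at arbitrary virtual electrodes, band-passed
   2–220 Hz and resampled to 1 kHz.
6. **Features & comparison** — eight characteristic parameters + LAT per
   trace; Cohen's d (pooled SD), percent errors, Pearson/cross-correlation,
   wavelet→PCA→k-means morphology clustering with centroid distances, and
   LAT isochrone maps.

A `synthetic_data` module generates desk-scale stand-ins (curved sheet PCD,
electrode grids, pseudo-recorded EGM sets with known ground truth) so every
stage is testable without clinical data.

## Worked example

```python
import numpy as np
from lapwsim import (
    SheetSpec, make_sheet_pcd, build_slab_mesh, template_field,
    ConductivitySet, SimulationConfig, StimulusProtocol, simulate,
    forward_egm_set, postprocess, characterize,
)
from lapwsim.fibers import conductivity_tensor, measure_cv

mesh = build_slab_mesh(20, 20, 1.0, 2.3)        # 20×20×2.3 mm slab, mm units
field = template_field(mesh, -60, 60)            # endo→epi fiber rotation
sigma = ConductivitySet()                        # Henriquez values, K = 1
tensors = conductivity_tensor(field, sigma)

cfg = SimulationConfig(dt=0.01, duration=140.0, stimuli=[
    StimulusProtocol(box_min=(-1, -1, -1), box_max=(1.01, 21, 3.4)),
])
res = simulate(mesh, tensors, cfg)               # planar wave from the x=0 edge

v = mesh.vertices
start = np.flatnonzero(np.abs(v[:, 0] - 4) < 0.1)
end = np.flatnonzero(np.abs(v[:, 0] - 16) < 0.1)
print(f"CV = {measure_cv(v, res.lat, start, end).cv:.1f} cm/s")

trace = postprocess(forward_egm_set(res, [[10.0, 10.0, 3.3]])[0])
f = characterize(trace)
print(f"p2p = {f.peak_to_peak:.2f} mV, LAT = {f.lat:.0f} ms, "
      f"deflections = {f.deflection_count}")
```

prints

```
CV = 14.7 cm/s
p2p = 2.35 mV, LAT = 61 ms, deflections = 2
```

i.e. on this deliberately coarse 1 mm mesh the transmurally rotating fibers
carry the wave across the slab at 14.7 cm/s (coarse meshes underestimate CV
— see `docs/methods.md`; the calibration factor K absorbs this at the
operating point), and the virtual electrode 1 mm above mid-tissue sees a
clean biphasic (RS) deflection with a 2.35 mV peak-to-peak amplitude as the
wavefront passes beneath it at ~61 ms.

Command line, end to end from a YAML config:

```bash
lapwsim run --config run.yaml        # fixtures → mesh → simulate → EGMs → report
lapwsim build-mesh --pcd wall.xyz --spacing 3.5 --thickness 2.3 --refine 2 --out mesh.vtk
lapwsim fibrosis --mesh mesh.vtk --type patchy --density 0.35 --seed 7
lapwsim compare --recorded rec.csv --simulated sim.csv --out report.json
```

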