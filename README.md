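# mitolens

Cone photoreceptors aggregate tightly packed mitochondria in the ellipsoid —
the distal inner segment (IS), directly upstream of the light-detecting
outer segment (OS).  Beyond fueling phototransduction, this lipid-rich
bundle sits squarely in the light path, and simulations on reconstructed
cones show that it behaves as a microlens: it focuses incident light into a
narrow pencil at the OS position, and light entering off-axis partially
misses the (tilted) OS, reproducing the angular falloff of the
Stiles-Crawford effect (SCE).

`mitolens` is a tested Python implementation of that computational pipeline
for researchers in photoreceptor optics and subcellular biophotonics:

* **synthetic_geometry** — parametric cone envelopes (solids of revolution)
  and mitochondrial bundles: aligned "active-like" chains, disordered
  "hibernating-like" chains (70% volume), volume-matched spheres, and a
  single megamitochondrion; branch orientations follow a von Mises-Fisher
  law calibrated so ~75% (active) / ~30% (hibernating) of branches deviate
  < 15° from the cone axis.  Mesh I/O (OBJ/PLY/STL) and skeleton ground truth.
* **dielectric_grid** — point-in-polygon voxelization at double resolution,
  ε_r = n² material assignment (1.34/1.36/1.40/1.46), 10-nm membranes via
  subpixel-averaged anisotropic interface tensors, procedural cristae,
  ablation variants (`no_mitochondria`, `mitochondria_only`), base-layer
  extension, HDF5 persistence with re-skinnable material indices.
* **fdtd_engine** — Yee-lattice FDTD (2D/3D, numba kernels) with CPML
  boundaries and a CW 450-nm plane source; exports cycle-averaged
  electromagnetic energy density u = (ε|E|² + |H|²)/2.
* **focusing_metrics** — ring annotation of structure/intensity volume
  pairs, concentration-factor depth profiles (0.75-µm axial cylinder),
  focal length and peak factor, and the OSR factor (mean factor over a
  6 × 1.5 µm cylinder at the IS tip).  Works identically on simulated
  exports and microscope z-stacks (32-bit TIFF I/O).
* **directionality** — tilt series, data-measured tilt angles, and the SCE
  fit log₁₀(relative intensity) = −ρ d² with d = angle/(2.5°/mm); ρ in mm⁻².
* **alignment_morphometry** — KNOSSOS-style skeleton XML, per-0.5-µm-layer
  branch deviation-angle histograms, `fraction_below(15°)`, morphometrics.
* **cohort_stats** — hierarchical (animals-then-cones) bootstrap CIs for
  group differences in OSR concentration; two-sample t tests.

The original study's electron-microscopy reconstructions are not deposited,
so all studies run on synthetic cones whose statistical properties emulate
them; results are checked as orderings and calibrated properties (see
`docs/methods.md`).

## Worked example

Build the reference cone, propagate 450-nm light through it and through its
mitochondria-free ablation, and compare what reaches the outer-segment
region:

```python
from mitolens.pipeline import (analyze_condition, config_3d,
                               reference_cone_3d, run_condition)

model = reference_cone_3d("active", seed=1)   # 4 µm × 8 µm IS, 19 mitochondria
cfg = config_3d()                             # 6.5×6.5×20 µm lattice, 16 vox/µm
for mode in ("intact", "mitochondria_only", "no_mitochondria"):
    focus = analyze_condition(run_condition(model, mode, 0.0, cfg))["focus"]
    print(f"{mode:18s} peak={focus.peak_factor:5.2f} "
          f"focal={focus.focal_length:4.2f} um  OSR={focus.osr_factor:4.2f}")
```

```
intact             peak= 9.58 focal=4.47 um  OSR=8.68
mitochondria_only  peak= 7.70 focal=3.53 um  OSR=7.15
no_mitochondria    peak= 9.59 focal=8.03 um  OSR=5.29
```

The intact cone concentrates light ~8.7-fold (background-normalized) into
the OSR.  Mitochondria alone deliver 82% of that; stripping the
mitochondria but keeping the cell drops delivery to 61% and pushes the
focus from 4.5 µm to 8.0 µm beyond the IS tip, where coupling into an OS
would be poor — the bundle, not the cell body, is the lens.  The
hibernating-like cone (70% bundle volume, disordered chains) delivers an
OSR factor of 7.51 under the same conditions.

The numbered scripts under `analysis/` run the full study set (model
generation and morphometry, alignment histograms, 2D ablations and index
sweeps, the 3D comparisons above, tilt-series directionality, and the
cohort bootstrap), writing tables under `results/`.

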