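# tomobreast

Desk-scale simulator and reconstruction toolkit for wide-angle digital
breast tomosynthesis (DBT). Everything runs on synthetic phantoms on a
single CPU — no external data required.

What's inside:

- **geometry** — acquisition modes (fast / moderate_fast), per-view
  timing/angle schedules, and a flying-focal-spot (FFS) source model in
  which in-pulse deflection cancels the gantry motion.
- **sampling** — k-space fill analysis and the native-slice-thickness
  relation `d(f) = 1 / (2 f tan(theta/2))`.
- **spectra** — Kramers bremsstrahlung tungsten spectra, Beer–Lambert
  filtration with embedded attenuation tables (Al, Rh with its 23.22-keV
  K-edge, PMMA, breast tissues, calcium, a-Se), a 1-D quantum-noise CNR
  model, a simplified slab AGD model, and a CNR²/AGD figure-of-merit scan
  under a 5-kW tube-power constraint.
- **phantoms** — seeded compressed-breast slabs with 1/f^β anatomical
  texture, microcalcification clusters, metal clips, tilted sub-pixel
  wires, Al sheets, and 1-D layer stacks.
- **projector** — cone-beam forward model with finite/moving (or
  FFS-stabilized) focal spot, pixel-aperture integration, effective-energy
  and polychromatic modes, and Poisson counting noise.
- **reconstruction** — row-wise ramp filtering and backprojection in the
  perspective coordinate system (voxels follow the central-view rays, so
  structures keep their in-plane index across slices), optional Cartesian
  resampling, and contrast-preserving slab merging.
- **artifact_reduction** — morphological segmentation of high-contrast
  object shadows, background inpainting (rP), and mask-driven
  backprojection that suppresses dark in-plane shadows and bright
  out-of-plane traces while keeping the object visible in focus.
- **postproc** — baseline equalization, multifrequency enhancement with
  dark-overshoot clamping, physics-constrained denoising (any estimator,
  subtraction hard-bounded to ±k·sqrt(value/gain)), and a simplified
  synthetic-mammogram generator.
- **metrics** — height-resolved effective MTF from tilted-wire stacks
  (0.1-px oversampled LSF), clip artifact metrics, ROI CNR.
- **stackio / pipeline / cli** — multi-page TIFF + JSON sidecar I/O, a
  seeded end-to-end pipeline runner with a reproducibility manifest, and
  the `tomobreast` command-line interface.

## CLI

```sh
tomobreast geom --mode fast                 # geometry + schedule JSON
tomobreast sampling --theta 50 --freq 5     # native slice thickness, F_z
tomobreast spectrum-opt --thickness 60 --filters Al:0.7,Rh:0.05
tomobreast emtf --height 60 --ffs off       # simulate wire scan, print eMTF
tomobreast run --config cfg.yaml            # full pipeline with manifest
```

A demo pipeline config ships with the package
(`src/tomobreast/data/demo_pipeline.yaml`): textured slab + clip + calc,
noisy acquisition, reconstruction with artifact reduction, flavoring, and
a synthetic mammogram — it finishes in well under a minute:

```sh
python - <<'EOF'
import importlib.resources as res, yaml
from tomobreast.pipeline import run_pipeline
cfg = yaml.safe_load((res.files("tomobreast") / "data" / "demo_pipeline.yaml").read_text())
run_pipeline(cfg, out_dir="demo_out")
EOF
```

Exit codes: 0 success, 2 configuration error, 1 runtime error.

## Notes on modeling fidelity

- Attenuation tables are anchored to standard reference data at a few
  energies per element and interpolated; they support ranking-level and
  directional conclusions, not regulatory dosimetry.
- AGD uses a deliberately simplified slab-absorption model (no tabulated
  conversion factors); only directional/ranking claims are made from it.
- The in-pulse X-ray emission profile defaults to a triangular ramp
  (`pulse_profile="triangle"` in the projector); a perfect rectangular
  pulse is available but produces idealized side lobes in the motion-blur
  kernel that measured systems do not show.
- The synthetic-mammogram generator and the denoiser's default estimator
  are classical stand-ins; the mechanism of interest is the plumbing
  (perspective indexing, the physics-bound plausibility clamp), and both
  accept plug-in replacements.
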