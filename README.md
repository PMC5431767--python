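# paleoenamel

Micro-CT grey-level densitometry and paired X-ray-fluorescence (XRF)
screening to discriminate **ante-mortem enamel hypomineralisation** (MIH /
HSPM-type lesions) from **post-mortem taphonomic discoloration** in
archaeological teeth, packaged as a tested, reusable pipeline with a
synthetic-phantom generator so every stage is verifiable without external
data.

## What it does

Grey levels in a 16-bit micro-CT reconstruction (7 µm isotropic voxels by
default) serve as an uncalibrated mineral-density proxy. The pipeline
combines three strands of evidence per tooth:

1. **3D densitometry** (`densitometry`) — five ~49 µm cubes placed along a
   surface→DEJ transect (surface, DEJ, and the three midpoints), paired
   normal/discoloured mean grey levels over two measurement rounds, the
   10-value mineral-density-difference (mdd) vector, and a two-sided
   Wilcoxon signed-rank test of mdd against zero.
2. **2D profiles** (`profiles`) — DEJ→surface line profiles resampled to 99
   equidistant points, the pointwise fractional deficit curve, the
   mid-enamel deficit, and gradient-direction labels (normal enamel rises
   DEJ→surface; hypomineralised enamel shows the reverse gradient).
3. **XRF screening** (`xrf`) — paired stained (DC) vs normal (NO) relative
   concentrations of Mn, Fe, Cu, Pb; per-tooth signed-rank p-value and
   per-element contamination flags (fold change ≥ 3 and non-overlapping
   repeats by default).

A rule-based classifier (`diagnosis`) merges the strands into one of:
`sound`, `hypomineralised`, `hypomineralised_with_postmortem_uptake`,
`taphonomic_stain`, `acid_dissolution_suspect`, `indeterminate`, with a full
rule trace.

Supporting modules: `volume_core` (TIFF+YAML volume I/O, reslicing to the
cervical plane of section, transect extraction), `npstats` (Wilcoxon
signed-rank with exact enumeration and normal-approximation variants;
Fleiss' kappa), and `phantom` (synthetic enamel slabs with programmable
deficits, taphonomic staining, acid-dissolution shells, XRF simulation, and
rater panels).

## CLI

```sh
# full pipeline on a synthetic phantom (or a volume+landmarks config)
paleoenamel run --config config.yaml --seed 7 --out results/

# individual stages on files
paleoenamel densito volume.tiff landmarks.csv --edge 49 --method normal_approx
paleoenamel profile volume.tiff landmarks.csv --plot profile.png
paleoenamel xrf measurements.csv TOOTH_ID
```

Synthetic-mode config:

```yaml
phantom:
  lesion_class: hypomineralised          # sound | hypomineralised |
                                         # taphonomic_stain |
                                         # hypomineralised_with_uptake |
                                         # acid_dissolution
  deficit_mid: 0.10                      # fractional deficit at mid-enamel
  noise_sd: 615.0                        # grey levels
seed: 7
```

Data-mode config keys: `volume` (16-bit multi-page TIFF with a YAML sidecar
holding voxel size/axis order/origin), `landmarks` (CSV
`label,x_um,y_um,z_um` with `normal_surface_1`, `normal_dej_1`, …,
`disc_surface_2`, `disc_dej_2` and `profile_{normal,disc}_{surface,dej}`
rows), optional `xrf_csv` (tidy CSV `tooth,element,condition,repeat,value`
with conditions `DC`/`NO`).

Conventions: axis order `(z, y, x)` with z the stack-page axis; 0-based
voxel-centred coordinates in µm; trilinear interpolation for reslicing and
transect sampling.

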