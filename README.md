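# colonyprofile

Quantification of clonal patch (strand) width in two-channel fluorescence
images of expanding microbial colonies.

Two genotypes tagged with different fluorophores (eGFP → "green",
mCherry → "red") self-organize into radial strands as a colony expands from
a central inoculation zone. `colonyprofile` measures how strongly the two
populations are intermixed as a function of radial distance:

1. **image_io** — read single-plane grayscale TIFFs (8/16-bit), convert to
   8-bit, build cyan/magenta pseudo-color overlays.
2. **preprocess** — integer-factor bicubic coarsening (default 8×) and a
   circular moving-average smoother (default ≈10 μm arc window).
3. **radial_profile** — sample both channels along circles of increasing
   radius, starting at the edge of the inoculation zone.
4. **patch_stats** — per-radius Otsu threshold of the circle's intensities,
   threshold-corrected signal, circular crossing statistics, and the mean
   arc length of contiguous above-threshold runs ("patches"), per channel
   and combined. Radii without crossings are flagged `reliable=False`.
5. **synthetic_data** — generator for two-channel colony images with exactly
   known per-radius sector structure (fixed, narrowing, widening, or
   annihilating/branching random-walk boundaries), used as the ground-truth
   oracle for every stage.
6. **hydration** — matric potential ψ = −ρgh/1000 kPa for porous-surface
   suction setups, plus the inverse.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, analytic sector recovery, parameter recovery, demixing
regime, conservation/equivariance, hydration identities).

## CLI

All pipeline runs are driven by one YAML config (see keys in
`colonyprofile/config.py`; every dataclass field is a config key):

```yaml
synthetic:            # or an `inputs:` section with green_tiff/red_tiff,
  image_size_px: 512  # pixel_size_um, center_px, inoc_radius_um
  pixel_size_um: 5.0
  inoc_radius_um: 1000.0
  colony_radius_um: 2400.0
  mode: narrowing     # fixed_sectors | narrowing | widening | boundary_walk
  width_start_um: 100.0
  width_end_um: 10.0
preprocess:
  coarsen_factor: 1
  smooth_window_um: 10.0
sweep:
  r_end_um: 2300.0
  dr_um: 10.0
output_dir: out
seed: 0
```

```sh
colonyprofile simulate -c config.yaml          # TIFF pair + ground-truth CSV
colonyprofile analyze  -c config.yaml          # curve CSV, abundance CSV,
                                               # overlay PNG, plot, manifest
colonyprofile hydration --height-m 0.102       # psi_m in kPa
colonyprofile hydration --psi-kpa -0.5         # column height in m
```

`analyze` writes `patch_width_curve.csv` with one row per (radius, channel):
`radius_um, channel, threshold, n_crossings, n_patches, mean_patch_width_um,
covered_fraction, reliable`.

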