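# ntk

Toolkit for two plate-and-microscope protocols used when characterizing soft
hydrogel substrates and the neurons cultured on them:

1. **Sphere-indentation elastography** (`ntk.mechanics`, `ntk.stacks`) — a
   dense sphere resting on a gel under its buoyancy-corrected weight indents
   the surface; the elastic modulus follows from the Hertz solution with a
   frictionless thin-film correction for finite gel thickness. Thickness
   `h` and indentation depth `delta` can be supplied directly or extracted
   from two-channel confocal z-stacks (green = stained gel, red = surface
   beads) via an intensity-profile-derivative boundary detector and a
   per-column bead-surface map.
2. **Voltage-dye plate analytics** (`ntk.flipr`) — 5×5 area-scan well reads
   are normalized against dye-only background wells, converted to
   membrane-potential changes `dE = (RT/z'F)·ln(1/(dF/F0+1))`, QC'd by
   per-well COV, calibrated (z' from KCl titrations), and compared across
   groups with pooled-variance / paired t tests.

`ntk.synth` generates ground-truth-known inputs for every stage (scenes,
plates, titrations), so the whole pipeline is testable without external data.

## CLI

```sh
# modulus from scalar geometry (catalog: si3n4_1_32, zro2_1_32, wc_1_8)
ntk modulus from-measurements --indenter si3n4_1_32 --h 0.4mm --delta 100um \
    --nu 0.5 --grouping printed --out result.json

# modulus from a two-channel OME-TIFF z-stack
ntk modulus from-stack scene.ome.tif --green 0 --red 1 --indenter zro2_1_32 \
    --out report.json

# plate analysis and dye calibration
ntk flipr analyze plate.csv --map map.csv --zprime -0.64 --temp-c 22 --out report.json
ntk flipr calibrate titration.csv --kr 5.4 --space loglog

# synthetic data with truth sidecars
ntk simulate scene --e-true 300 --h 350um --noise-cv 0.05 --seed 17 --out scene_dir/
ntk simulate plate --groups neurons:2:4:rest,neurons:22:4:stimulated --out plate_dir/
ntk simulate titration --zprime -0.64 --noise-cv 0.05 --out titration.csv
```

All lengths take explicit unit tags (`um`, `mm`, …); densities accept
`g/cm3` or bare kg/m³. Validation failures exit with code 2. Reports embed
the toolkit version, configuration, seed, and SHA-256 digests of inputs.

## Layout

- `src/ntk/mechanics.py` — Hertz + thin-film model, validity gate, inversion
- `src/ntk/stacks.py` — axial profiles, thickness, surface map, depth
- `src/ntk/flipr.py` — normalization, dE conversion, COV, z' fit, statistics
- `src/ntk/synth.py` — scene/plate/titration generators (seeded, invertible)
- `src/ntk/io.py`, `src/ntk/cli.py`, `src/ntk/units.py` — formats + CLI
- `tests/` — unit, property (hypothesis), and acceptance suites
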