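# phasemorph

Label-free cell morphometry from quantitative phase maps.

Quantitative phase microscopy images transparent, unstained cells by the
optical path delay they impose, `phi = (2*pi/lambda) * (n_c - n_m) * h`.
Because refractive index `n_c` and thickness `h` are coupled in `phi`, a
phase map does not directly reveal a cell's substructure — but every
refractive-index boundary crossed by the beam produces a spike ("jump")
in the lateral phase gradient.  `phasemorph` turns that observation into
a measurement pipeline for cell and nucleus sizes:

1. **Simulate** a nested-sphere phantom (cytoplasm sphere + eccentric
   nucleus) as a phase map on a calibrated raster, optionally corrupted
   with white Gaussian noise at a chosen SNR — or load a real phase
   raster (float TIFF / CSV) with its pixel calibration.
2. **Differentiate**: forward-difference lateral gradients
   `g[c] = (phi[c+1] - phi[c]) / dx` and the all-positive
   modulus-squared edge map that removes the "shadow artifact".
3. **Detect and pair jumps** along 1D traversals: gradient spikes are
   grouped, localized, and paired as nested boundaries — for a hill
   traversed left to right, `m` rising spikes then `m` falling spikes,
   outermost pair = cell outline, inner pairs = inclusions.
4. **Convert**: pair separations in pixels times the pixel pitch give
   physical diameters and edge gaps, with error statistics against known
   set values.

It is aimed at QPM users who want fast, label-free size estimates of
cell body and nucleus without refractive-index decoupling, and at method
developers who need a controlled phantom + noise testbed for
gradient-based boundary detection.  See `docs/methods.md` for the model,
the detector design and its noise analysis.

## Worked example

The reference phantom: a 6 um-radius cytoplasm sphere (n = 1.37) with a
2.5 um-radius nucleus (n = 1.45) centred at x = 3 um, in watery medium
(n = 1.33), 632.8 nm illumination, 15 x 15 um^2 field at 255 x 255 px.

```python
import phasemorph as pm

model = pm.nucleated_cell_model()
grid = pm.nucleated_cell_grid()          # 15 um / 255 px, pitch 0.0588 um

phase = pm.render_phase_map(model, grid)
gx = pm.forward_diff_gradient(phase, "x")
profile = pm.extract_profile(gx, pm.RowLine(grid.nearest_row(0.0)))

jumps = pm.detect_jumps(profile)
print([(j.pixel_index, j.sign) for j in jumps])
# [(26, 1), (136, 1), (220, -1), (228, -1)]

report = pm.build_distance_report(pm.pair_jumps(jumps), profile.step_um)
for row in report.rows:
    print(f"{row.label:>12}  {row.pixels:3d} px  {row.microns:7.3f} um")
#          1-1  202 px   11.882 um
#          2-2   84 px    4.941 um
#   1-2 (left)  110 px    6.471 um
#  1-2 (right)    8 px    0.471 um

stats = pm.diameter_error_stats(report, [12.0, 5.0, 6.5, 0.5])
print(f"{stats.max_diameter_error_um:.3f} um  {stats.mean_relative_error_pct:.2f} %")
# 0.118 um  2.12 %
```

Reading the output: the outermost jump pair (label `1-1`) spans the cell
body — 202 px x 15/255 um = 11.882 um against the set 12 um diameter;
the inner pair `2-2` recovers the 5 um nucleus as 4.941 um; the left and
right gap rows locate the nucleus inside the body (6.5 um and 0.5 um set
values).  All recovered distances sit within two pixel pitches of truth,
the localization limit of integer-pixel edge detection.  Traversals that
miss the nucleus (e.g. the vertical line through the body centre) yield
a single pair.  At 35 dB SNR the detected jump indices are unchanged
from the noiseless run in ~99% of noise realizations.

## Command line

```sh
phasemorph fixtures nucleated_cell --out fx/          # write a demo config
phasemorph simulate --config fx/nucleated_cell.yaml --out sim/
phasemorph analyze  --in fx/nucleated_cell.yaml --truth 12,5,6.5,0.5 --out run/
phasemorph analyze  --in my_phase.tif --pixel-um 0.4 --out run2/   # real data
phasemorph report   --bundle run/ --truth 12,5,6.5,0.5
```

`analyze` writes gradient maps (float32 TIFF + JSON calibration
sidecars), per-traversal distance reports (CSV/JSON) and a `bundle.json`
with the seed, config hash and versions needed to reproduce the run
bit-for-bit.

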