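# qdfscope

Quadrant darkfield (QDF) microscopy: forward simulation, reconstruction, and
single-cell quantification of sub-cellular puncta.

## The problem

In transillumination darkfield, only light scattered or refracted into the
objective forms the image. Two very different structures light up: large
features (cell and bead edges, ≫ λ) refract light *directionally* along their
surface slope, while sub-wavelength puncta (organelles such as melanosomes,
~λ) scatter into a broad, weakly directional Mie cone. Edge signal depends
strongly on cell shape — a cell rounding up before division brightens
dramatically — which confounds darkfield as a label-free readout of organelle
content.

QDF separates the two by illuminating from four quadrants of the darkfield
LED annulus and acquiring one image per quadrant (TL, TR, BL, BR). Directional
edge refraction appears only under illumination from the opposing quadrant;
isotropic puncta appear equally in all four. Pixel-wise:

```
E   = |TL − BR| + |BL − TR|          (edge image)
DF  = TL + TR + BL + BR              (summed darkfield)
QDF = c·DF − E
```

where `c` is a system-specific scaling factor (typically 0.8–1.0) calibrated
by least squares so that `c·DF` matches `E` on edge pixels. Puncta cancel in
`E` and survive in `QDF`; edges cancel in `QDF`.

The package implements the full downstream pipeline — camera bit-depth
rescaling, empty-field reference subtraction, masked polynomial background
removal, scaling-factor calibration, watershed cell segmentation on
co-registered quantitative-phase images, dry mass via the specific refractive
increment (ρ = φλ/2πα, α = 1.8×10⁻⁴ m³/kg), Crocker–Grier track linking,
debris filtering, per-cell signal totals, puncta SNR (threshold at 4× the
99th percentile of background), and population statistics (Pearson
correlation, least-squares fit with an F-test against the intercept-only
model) — plus an optical forward model that renders quadrant sets, phase
images, reference frames and ground truth for bead phantoms and cells, so
every stage is testable without microscope data.

## Worked example

Simulate a bead phantom with a central "imperfection" punctum, calibrate `c`
on it, then compare a flat adherent cell against its volume-conserving rounded
form:

```python
from qdf import simulate as sim
from qdf.pipeline import FrameParams, analyze_frame

params = FrameParams(poly_degree=3)          # small synthetic field

bead = sim.bead_phantom(seed=11)
cal = analyze_frame(sim.render_quadrants(bead), sim.render_reference_set(bead),
                    sim.render_phase(bead), c=None, params=params).calibration
print(f"c = {cal.c:.3f}")                    # c = 0.994

flat = sim.adherent_cell(seed=1)             # 20 um disc, 200 puncta
rounded = sim.morph_roundness(flat, 1.0)     # hemispherical cap, same volume/puncta
for name, scene in [("flat", flat), ("rounded", rounded)]:
    r = analyze_frame(sim.render_quadrants(scene), sim.render_reference_set(scene),
                      sim.render_phase(scene), c=cal, params=params)
    cell = r.table.iloc[0]
    print(f"{name:8s} mass {cell.mass_pg:7.1f} pg  total_df {cell.total_df:9.0f}  "
          f"total_qdf {cell.total_qdf:9.0f}  snr {cell.snr:5.1f}")
```

prints (numbers from this exact script):

```
c = 0.994
flat     mass  1072.0 pg  total_df   1081331  total_qdf    600452  snr  23.1
rounded  mass  1072.4 pg  total_df   1525518  total_qdf    614673  snr  30.0
```

Dry mass is conserved through the shape change (0.04%), total darkfield grows
by ~41% (edge lensing of the rounded cell), while total QDF changes by only
~2.4% — the punctum content did not change, and QDF sees that.

A command-line interface wraps the same pipeline for TIFF datasets on disk:

```bash
qdf simulate --config scene.yaml --out data/ --seed 1
qdf reconstruct --quadrants data/pos0_t0 --reference data/reference --out out/
qdf run --config run.yaml          # batch: positions x timepoints, tracking, CSV
qdf stats --x mass_per_area --y qdf_per_mass --cells out/cells.csv
```

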