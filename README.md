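# osteosect

Quantitative analysis of transiliac (iliac-crest) bone-section images:

- **calibration** — two-point material calibration of backscattered-electron
  gray levels against embedded carbon and aluminum standards, producing
  calcium weight-percent maps;
- **bmdd** — bone mineralization density distribution histograms and their
  five canonical parameters (CaMean, CaPeak, CaWidth, CaLow, CaHigh) per
  skeletal compartment, with the cortical summary taken as the arithmetic
  mean of both cortices;
- **histomorphometry** — 2D structural indices (BV/TV, Tb.Th, Tb.N, Ct.Wd)
  from the mineralized mask, and static osteoid/surface indices (O.Th,
  OS/BS, OV/BV, Ob.S/BS, Oc.S/BS, ES/BS) from phase-labelled sections;
- **marrow adiposity** — adipocyte detection with a minimum-area filter
  (default 525 µm²) and circularity gate, reported as the adipocyte share
  of marrow area;
- **synthetic_section** — a seeded generator of paired synthetic
  backscatter-style images, phase label maps and ground truth (two cortical
  plates, trabecular strips, mixture-distributed mineralization, osteoid
  seams, roundish adipocytes, calibration patches, detector noise), so the
  entire chain is testable without specimen data;
- **reporting** — comparison against bundled pediatric reference ranges
  (z-scores for mean ± SD references, interval position for median/IQR) and
  assembly of table-style JSON/CSV reports.

## Command line

```sh
osteosect simulate --seed 1 --out section/           # synthetic section + truth
osteosect calibrate --image section/image.tif \
    --carbon-roi 330,346,4,20 --aluminum-roi 354,370,4,20 --out curve.json
osteosect bmdd --image section/image.tif --curve curve.json \
    --masks section/compartments.tif --out bmdd_out/
osteosect morpho --labels section/labels.tif \
    --masks section/compartments.tif --out morpho.json
osteosect adipo --labels section/labels.tif --min-area 525 --out adipo_out/
osteosect run --config config.yaml --out run_out/     # full pipeline + report
```

A minimal pipeline config:

```yaml
seed: 1
simulate: {}          # default synthetic section; or use an `inputs:` block
analysis:
  mineralized_t0: 5.2
  bin_width: 0.17
```

With an `inputs:` block the pipeline instead reads `image`, `labels`,
`annotations` and `compartments` TIFFs plus a `calibration:` block (either a
fitted `curve` JSON or `carbon_roi`/`aluminum_roi` rectangles); a
configuration with neither calibration source is rejected.

## Notes and conventions

- The aluminum standard is anchored at 34.583 wt% Ca equivalent, derived
  from a backscatter signal linear in mean atomic number (carbon Z=6 at
  0 wt%; hydroxyapatite at 39.86 wt% Ca with mean atomic number 14.068).
  Both constants are explicit and overridable.
- Default BMDD settings: 0.17 wt% Ca bin width, mineralized threshold
  5.2 wt% Ca, CaLow/CaHigh thresholds 17.68/25.30 wt% Ca with linear
  sub-bin apportionment, FWHM on the global peak with linear interpolation.
- Trabecular thickness uses the 2D plate model Tb.Th = 2·Area/Perimeter
  (distance-transform alternative behind `tb_th_method`); perimeters are
  sub-pixel marching-squares lengths, so image-border faces add no surface.
- **Cortical width units:** Ct.Wd is measured and reported in millimetres.
  The bundled reference row (0.70 ± 0.28) is printed with a µm unit in its
  source table, which is physically implausible for an iliac cortex; values
  are compared as printed and the report row carries an explanatory note
  rather than silently rescaling.
- Reports render missing result blocks as "Not evaluable"; all randomness
  flows from a single top-level seed and reports are byte-reproducible.
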