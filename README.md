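# perihalo

Analysis pipeline for studies of perivascular exosome "halos" and their
effect on dendritic-cell migration, reimplemented as a tested, reusable
Python package. It covers:

- **tracks** — per-track chemotaxis/chemokinesis statistics (track length,
  displacement, chemotactic displacement, chemotactic index, speed,
  migratory angle change), displacement filtering, rose-plot angle
  histograms and Welch group comparisons.
- **morphometry** — cell-shape circularity (4π·Area/Perimeter²) from
  polygonal contours, plus an iso-contour utility for raster masks.
- **halo** — per-channel fluorescence band widths (σ) from cross-sectional
  line profiles and the marker/vessel diameter ratio (e.g. CD9/podoplanin).
- **proteomics** — six-channel isobaric reporter quantitation: median
  normalization with input-concentration scaling, Top3 interprotein
  abundance, TNFα/ss ratios with a dual significance rule (Welch sample
  p-value and BH-adjusted peptide-ratio p-value), ratio-density summaries,
  heat-map matrices and protein-cluster enrichment against GMT sets.
- **assays** — point-to-vessel minimum distances with a
  complete-spatial-randomness normalization, the "three consecutive
  seconds" adhesion rule, transwell standard-curve calibration and kinetic
  summaries, replicate particle-size histogram averaging, and membrane
  pore-coverage geometry.
- **synthetic** — seeded generators with known ground truth for every input
  class (biased persistent random walks with a protrusion parameter,
  spike-in peptide tables, Gaussian band profiles, vessel fields and point
  patterns, size histograms, star contours, transwell kinetics), so the
  whole pipeline is exercisable without any external data.
- **io / pipeline / cli** — plain-text readers and writers (CSV/TSV, GMT,
  JSON/YAML), a config-driven multi-stage runner with an auditable report,
  and the `perihalo` command-line interface.

## Command line

```sh
perihalo simulate --design design.yaml --out sim/ --seed 1
perihalo tracks sim/tracks.csv --gradient-dx 1 --gradient-dy 0 --min-displacement 24.1
perihalo shape contours.csv
perihalo halo profile.csv --marker CD9 --vessel podoplanin --sigma-mode band
perihalo proteomics quantify peptides.tsv meta.yaml --out quant/
perihalo proteomics enrich peptides.tsv meta.yaml clusters.gmt
perihalo distance points.csv vessels.csv --seed 1
perihalo adhesion events.csv --min-duration 3
perihalo transwell curve.csv readings.csv
perihalo nta histograms.csv
perihalo pore-coverage --diameter 3 --density 8e5
perihalo run --config pipeline.yaml --out results/ --seed 1
```

A pipeline config names the stages to run and their inputs, e.g.

```yaml
seed: 1
out_dir: results
stages:
  tracks:
    groups: {control: control_tracks.csv, treated: treated_tracks.csv}
    gradient_dx: 1.0
    min_displacement: 24.1
    reference: control
  halo: {profile_csv: profile.csv}
  pore_coverage: {}
```

Every stage records in `report.json` the parameters it used, flagging each
default that was applied implicitly.

## File formats

| data | format |
| --- | --- |
| tracks | CSV `track_id,t_min,x_um,y_um` |
| contours | CSV `contour_id,frame,vertex_index,x_um,y_um` |
| line profiles | CSV `distance_um,<channel>,...` |
| peptide tables | TSV `protein_id,peptide_id,c1..c6` |
| sample metadata | YAML/JSON `channel: {group, concentration}` |
| clusters | GMT (name, description, members) |
| vessels | CSV `polyline_id,vertex_index,x_um,y_um` |
| size histograms | CSV `replicate,bin_lo_nm,bin_hi_nm,conc_per_ml` |
| standard curves | CSV `fluorescence,cell_count` |

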