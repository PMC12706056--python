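# polasym

Pole-resolved single-cell quantification for rod-shaped bacteria.

Stationary- and transition-phase *E. coli* develop a striking internal
asymmetry: glycogen accumulates at the old cell pole, the nucleoid is
displaced toward the new pole, and the division septum follows the
nucleoid, producing daughters of unequal size and composition. Measuring
this requires a stack of small, careful estimators downstream of
segmentation. `polasym` implements that stack as a tested library for
microbiologists and image analysts who already have labeled cell masks
(from Omnipose, SuperSegger, Oufti, …) and co-registered fluorescence
channels:

- **Morphometry** — subpixel medial axis from a distance-transform-
  weighted polynomial fit; length, width, area, circularity; feature
  filtering.
- **Constriction detection** — peak finding on smoothed, inverted
  half-width profiles (prominence 0.1, separation 15 samples); the
  division-asymmetry statistic `|s/L − 1/2|`.
- **Nucleoid analysis** — in-cell Otsu + watershed segmentation;
  midpoint offset (distal-pair and mean-relative conventions); the
  nucleocytoplasmic ratio (nucleoid area / cell area).
- **Pole-resolved signals** — normalized pole difference
  `(⟨I⟩_pole1 − ⟨I⟩_pole2)/⟨I⟩_cell` over 30%-length pole masks eroded
  2 px; the signal correlation factor (SCF), a Pearson correlation over
  a 4-px axial strip trimmed 5 px per pole; glycogen-sensor pole-area
  asymmetry; computational division of constricting cells into future
  daughters.
- **Lineages** — DBSCAN microcolony/trench clustering, mother-cell
  tracking, old/new-pole polarity and generation bookkeeping,
  instantaneous growth rates from log-length fits, per-generation
  statistics with bootstrap CIs.
- **FRAP** — control-cell photobleach correction, 0-to-1 normalization,
  single-exponential recovery fit; half-time `τ·ln 2`.
- **AFM** — contact-point detection, 80–100%-force surface stiffness,
  20-nm-bin stiffness tomography with per-depth median deviation,
  membrane-rupture detection and post-rupture intracellular stiffness,
  cell height.
- **Synthetic data** — a first-class generator of masks, channels,
  lineages, FRAP traces and force curves with recorded ground truth, so
  every estimator is testable without real images.

## Worked example

```python
import numpy as np
from polasym import synthetic_data as syn, pipeline

ds = syn.make_snapshot_dataset(200, seed=3)          # masks + channels + ground truth
df, _ = pipeline.run_snapshot_analysis(ds, seed=3)   # one row per cell
merged = df.merge(ds.table, on="cell_id")

con = merged[np.isfinite(merged["true_constriction_rel"])]
det = con[con["constriction_present"]]
print(f"constriction recall:  {con['constriction_present'].mean():.3f}")
off_err = (det["constriction_norm_offset"]
           - (det["true_constriction_rel"] - 0.5).abs()).abs()
print(f"division-offset MAE:  {off_err.mean():.4f}")
true_off = (merged["true_nucleoid_rel_midpoint"] - 0.5).abs()
print(f"nucleoid-offset MAE:  {(merged['nucleoid_offset'] - true_off).abs().mean():.4f}")
print(f"PEG-3000 diameter:    {pipeline.dls_diameter_nm(3000):.2f} nm")
```

prints

```
constriction recall:  1.000
division-offset MAE:  0.0074
nucleoid-offset MAE:  0.0057
PEG-3000 diameter:    2.80 nm
```

All 67 truly constricting cells are found; the detected division site
and the nucleoid midpoint are both localized to better than 1% of the
cell length (the tolerances in the test suite are 2%); and the empirical
dynamic-light-scattering relation σ = 0.029·MW^0.571 puts a 3 kDa PEG
crowder at ~3 nm hydrodynamic diameter.

A command-line layer wraps the same functions:

```bash
polasym simulate snapshot --n 100 --seed 1 --out data/
polasym snapshot --data data/ --out results.csv
polasym simulate frap --n 4 --seed 2 --out frapdata/
polasym frap --traces frapdata/frap_traces.csv --out fits.csv
polasym afm --curves curves/ --mode penetration --out stiffness.csv
```

## Layout

```
src/polasym/
  synthetic_data.py   generators with ground truth
  geometry.py         medial axis, widths, constriction, pole regions
  nucleoid.py         nucleoid segmentation and positioning
  signal_metrics.py   pole difference, SCF, sensor asymmetry, stats
  lineage.py          clustering, genealogy, polarity, growth rates
  frap.py             bleach correction, normalization, recovery fit
  afm.py              force-curve stiffness analysis
  pipeline.py         orchestration + biophysical utilities
  io.py, cli.py       TIFF/CSV/JSON/YAML IO and the `polasym` CLI
```

See `docs/methods.md` for the models, numerical choices and limitations.
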