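# enspec

Reconstruction of ensemble electronic absorption spectra without hand-tuned
broadening.

Given per-geometry, per-transition vertical excitation energies (eV) and
oscillator strengths from quantum-chemistry calculations, `enspec` builds
absorption cross-section spectra two ways:

- **auto-delta** — the classic broadened discrete sum, with each band's
  Gaussian full-width chosen automatically from a weighted kernel-density
  rule of thumb (`delta = 2h`, robust to mild non-normality via the IQR);
- **gmm-nea** — a closed-form, bandwidth-free spectrum obtained by fitting a
  bivariate Gaussian mixture to each band's (energy, transition-dipole)
  cloud, with an explicit point mass for dark (`f = 0`) geometries,
  constrained covariance families (EII…VVV) and BIC model selection.

Around these it provides percentile-bootstrap confidence bands, robust
Mahalanobis/FDR screening of anomalous quantum-chemistry points, relative
integral-change metrics (`RIC`, band-wise `bRIC`, sequential `bRIC_seq` with
stopping thresholds for active-learning workflows), photolysis-rate
integration against actinic-flux files, and a seeded synthetic-ensemble
generator used both as a demo fixture and as the testing backbone.

## Input format

Long-format CSV with header `geom_id,state,delta_E,f`: one row per geometry
and transition, energies in eV, oscillator strengths dimensionless. Every
geometry must carry the same set of states (incomplete grids are rejected —
bootstrap resampling acts jointly across states). A column-name map is
available for other headers (`read_ensemble(path, dialect=...)`).

## CLI

```sh
enspec simulate --n-geoms 500 --seed 0 --out ensemble.csv
enspec spectra  --input ensemble.csv --method gmm-nea -B 999 --seed 0 --out run/
enspec spectra  --input ensemble.csv --method auto-delta --out run2/
enspec qc       --input ensemble.csv --q 0.001 --out qc.csv --write-clean clean.csv
enspec metrics  --old run_old/spectrum.csv --new run/spectrum.csv --threshold 0.05
enspec photolysis --spectrum run/spectrum.csv --flux flux.txt
```

`spectra` writes `spectrum.csv` (energy grid, total and per-band cross
sections with CI bands) and `band_report.csv` (per-band `delta`/`h` or
`K|model` mixture parameters). Photolysis requires spectra built with
`--prefactor-mode physical` (cm²) and a two-column flux file
(wavelength nm, quanta s⁻¹ cm⁻² nm⁻¹; `#` comments allowed). Use a flat
`key=value` file with `--config` to pre-set any option; flags win. Exit
codes: 0 ok, 1 validation, 2 fit failure, 3 I/O.

## Library sketch

```python
import enspec

table = enspec.read_ensemble("ensemble.csv")
report = enspec.screen_ensemble(table, q=0.001)        # outlier QC
table = table.drop_geoms(report.flagged_geoms)

cfg   = enspec.FitConfig(seed=0)
bands = [enspec.fit_band_gmm(s, cfg) for s in table.bands()]
grid  = enspec.EnergyGrid.linear(3.0, 8.0, 2001)
full  = enspec.full_spectrum_gmm(bands, grid)          # bandwidth-free

bw    = enspec.auto_delta(table.band(1))               # delta = 2h baseline
```

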