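# cosan-ftirm

Single-cell FTIR micro-spectroscopy analysis of boron-cluster drug
uptake: preprocessing, region-wise PCA, amide-I secondary-structure
deconvolution, band-metric indices, and hyperspectral B–H mapping — with
a synthetic single-cell generator so the whole pipeline runs and is
tested end-to-end without instrument data.

## The problem

Cobaltabis(dicarbollide) salts (Na[*o*-COSAN]) are candidate boron
carriers for boron neutron capture therapy (BNCT). Their B–H stretching
doublet (2557 cm⁻¹ with a 2537 cm⁻¹ sub-peak) falls in the
2600–2500 cm⁻¹ region of the mid-IR where organic cell material does not
absorb, so micro-FTIR spectra of single cells can report drug uptake and
subcellular localization directly, and the protein / DNA / lipid regions
of the same spectra report what the drug does to the cell. This package
implements the analysis chain for such experiments:

* **preprocessing** — extended multiplicative signal correction (EMSC,
  per-spectrum model *a* + *b*·m(ν) + polynomial), standard normal
  variate (SNV) and unit-vector normalization, rubber-band (lower convex
  hull) and linear baseline correction, Savitzky–Golay derivatives
  (third polynomial order, 9 smoothing points);
* **chemometrics** — mean-centered PCA per spectral region (DNA
  1350–900, fingerprint 1800–1000, lipids 3000–2800 cm⁻¹) with a
  deterministic sign convention;
* **amide-I deconvolution** — the amide-I window (1700–1600 cm⁻¹) is
  modeled as five Gaussians assigned by second-derivative minima near
  1610 (sidechain), 1630 (β-sheet), 1652 (α-helix), 1682 (β-turn) and
  1690 cm⁻¹ (antiparallel β-sheet); a bound-constrained least-squares
  fit yields component areas *h*·σ·√(2π), percent areas, the
  ∫α/∫β ratio and the residual ΣError²;
* **band metrics** — the B–H uptake index (band integral 2620–2460 cm⁻¹
  above a local baseline, with a detection floor), the lipid
  unsaturation index (3010 / 2850 cm⁻¹ band integrals), the CH₃/CH₂
  peak ratio (2960 / 2921 cm⁻¹), and per-pixel band integration of
  hyperspectral rasters with hotspot/centroid localization;
* **statistics & orchestration** — Welch t-tests with significance
  stars, the viability-percent formula, and a config-driven pipeline
  producing deterministic, seed-stamped report tables.

## Worked example

Recovery of programmed α/β composition through the full deconvolution
procedure (`python examples/03_amide_deconvolution.py`):

```
group          programmed  recovered       SSE
GIC7 control         2.37       2.36   3.6e-07
GIC7 200uM           1.26       1.28   2.8e-06
PG88 control        10.62      10.67   4.1e-08
PG88 200uM           7.19       7.21   7.2e-08
```

Each row builds a noiseless five-Gaussian amide-I profile whose
α-helix/β-sheet area ratio is programmed to the stated value, then runs
the complete procedure (window averaging, endpoint-anchored linear
baseline, unit-vector normalization, second-derivative center
assignment, bounded five-Gaussian fit). The recovered column is the
fitted area ratio; agreement within a few percent shows the procedure
returns the composition it assumes.

Treatment-effect detection on synthetic populations
(`python examples/04_band_metrics_stats.py`, 50 cells per group):

```
bh_index             control   0.000  treated   0.719  p=3.62e-13 ***
unsaturation_index   control   0.305  treated   0.220  p=3.87e-06 ***
ch3_ch2_ratio        control   0.649  treated   0.628  p=2.70e-01
```

Controls read a B–H index of exactly 0 (below the detection floor —
there is no drug band to integrate), treated cells read a positive
index, and the programmed lipid-saturation shift is recovered as a drop
in the unsaturation index.

The other examples cover population synthesis (`01`), region PCA (`02`),
hyperspectral B–H mapping with nuclear localization (`05`) and the full
config-driven pipeline (`06` with `examples/pipeline.yaml`). A thin CLI
wraps the same functions:

```sh
cosan-ftirm synth --seed 7 --n-per-group 50 --out cells.csv
cosan-ftirm deconv cells.csv
cosan-ftirm run --config examples/pipeline.yaml
```

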