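# ectimetry

Quantitative morphometry of the **epithelial–connective tissue interface
(ECTI)** in two-channel nonlinear optical microscopy cross-sections, with a
synthetic phantom and cohort generator so the entire measurement chain is
testable end to end.

## The problem

In stratified squamous epithelium (oral mucosa in particular), dysplasia
deforms the normally flat interface between the epithelium and the underlying
lamina propria: hyperproliferating epithelium pushes rete ridges down into
the connective tissue. Second-harmonic generation (SHG) microscopy gives a
hard image of this interface — fibrillar collagen below it produces SHG
signal, the epithelium above it produces none — while multiphoton
autofluorescence (MPAM) shows the keratin band, epithelium and stroma.

`ectimetry` implements the shape statistic that quantifies this deformation.
For a traced interface of arc length *l* whose endpoints are joined by a
straight chord *L*:

```
ΔL = l − L          (ΔL)_norm = ΔL / L
```

(ΔL)_norm ("ΔLinearity") is 0 for a flat interface and grows with
undulation; it separates dysplastic from normal mucosa with high sensitivity
and specificity. The package covers:

- **`ectimetry.phantom`** — cross-sectional and en-face phantoms with
  analytic ground truth (boundary models, partial-volume SHG rendering,
  hard-core nucleus placement), plus per-site ΔLinearity cohort simulation
  from published group distributions (normal 0.11 ± 0.04,
  pooled dysplasia 0.41 ± 0.24 for the imaging readout; 0.09 ± 0.03 vs
  0.28 ± 0.16 for histology).
- **`ectimetry.trace`** — the extraction chain: Otsu threshold →
  threshold-clipped Canny edges → per-column topmost candidates →
  minimal-cost (Dijkstra) path across the gradient field → single-valued
  subpixel boundary → *l*, *L*, ΔL, (ΔL)_norm; plus stack reslicing to
  x-z / y-z planes.
- **`ectimetry.morphometry`** — epithelial thickness (surface-to-interface
  distance averaged over four fixed lateral positions) and nuclear density
  (Laplacian-of-Gaussian blob counting per 100 μm²).
- **`ectimetry.stats`** — one-way ANOVA with Tukey HSD, box-plot summaries,
  empirical ROC/AUC and the Youden-optimal operating point with
  within-class TP/FP/TN/FN rates.
- **`ectimetry.cli`** — a thin command line (`ectimetry simulate-phantom`,
  `simulate-cohort`, `trace`, `morphometry`, `stats`, `all`) over the
  library, driven by one YAML/JSON config; TIFF in/out with pixel sizes in
  the resolution tags and JSON metrics validated against shipped schemas.

## Worked example

```sh
python examples/01_phantom_and_trace.py
```

renders a 512×512 px phantom (0.625 μm/px lateral, 1 μm axial) whose
interface undulates with 20 μm amplitude and 80 μm period, traces the ECTI
from the SHG channel and prints:

```
arc length l       =   462.29 um
chord L            =   319.50 um
delta L            =   142.78 um
measured (dL)_norm =   0.4469
true (dL)_norm     =   0.4637
```

The measured ΔLinearity recovers the analytic tortuosity of the phantom to
within a few percent; a flat interface measures ≈ 0. The other examples
(`02_cohort_discrimination.py`, `03_morphometry.py`) run the cohort
statistics stage on a simulated 33-normal / 27-dysplasia cohort and the
thickness/nuclear-density measurements.

The same pipeline from the shell:

```sh
ectimetry simulate-phantom --seed 1 --outdir run/
ectimetry trace run/phantom.tif --outdir run/
ectimetry all --seed 7 --outdir run_all/   # phantoms -> traces -> cohort -> stats
```

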