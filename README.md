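# adipo3d

3D adipocyte morphometry from two-channel confocal stacks.

Adipose depots differ in how their cells are sized and shaped: visceral
adipocytes tend to be larger than subcutaneous ones, and cells inside an
intact tissue are pressed into angular polyhedra by the extracellular
matrix (ECM), while freshly extracted cells float free and round up.
Quantifying this requires 3D imaging — in 2D sections the pole of a large
cell is indistinguishable from a small cell — and per-cell 3D measures.
`adipo3d` is a tested pipeline for exactly that workflow, aimed at
researchers who image cleared adipose tissue (ECM + lipid co-staining) or
extracted adipocytes on a confocal microscope:

1. **simulate** — a synthetic-tissue generator producing
   ground-truth-labelled stacks that emulate in situ tissue (space-filling
   Laguerre-tessellated cells behind ECM walls, depth attenuation, noise)
   and ex situ preparations (sparse spheres), so every later stage can be
   validated without any microscope data;
2. **segment** — a classical 3D watershed segmenter (or ingest of label
   stacks produced by an external tool such as Cellpose);
3. **measure** — per-cell volume, surface area, equivalent spherical
   diameter, sphericity, centroid and border contact;
4. **qc** — the mask filters used in practice: discard cells touching a
   stack border, cells under 5000 voxels (≈ 24.4 µm equivalent diameter at
   the 1.15 µm acquisition pitch), and cells with sphericity under 0.35 —
   all strict inequalities, with a count-conserving report;
5. **compare** — kernel density estimates (Silverman bandwidth), a
   permutation two-sample Kolmogorov–Smirnov test with the Phipson–Smyth
   estimator p = (b+1)/(m+1), and an OLS model of per-sample means on
   tissue, sex and body weight.

The core per-cell measures, for a cell of volume *V* (µm³) and surface
area *A* (µm²):

- equivalent diameter d = (6V/π)^{1/3} — the diameter of the sphere with
  the cell's volume;
- sphericity ψ = (36π V²)^{1/3} / A — 1 for a perfect sphere, lower for
  angular, matrix-constrained cells.

The KS comparison reports D = sup|ECDF₁ − ECDF₂| between pooled per-cell
diameter (or sphericity) distributions, with a Monte-Carlo permutation
p-value that can never be exactly zero.

## Worked example

Simulate one visceral-like sample (lognormal diameters, mean 81.32 µm,
CV 0.30) and one subcutaneous-like sample (mean 63.88 µm, CV 0.35) of 120
cells each, then run the blind pipeline (segment → measure → qc →
compare) on the rendered stacks:

```python
from adipo3d.workflows import depot_comparison_study

study = depot_comparison_study(seed=1, n_cells=120)
for name, s in (("VAT-like", study["vat"]), ("SCAT-like", study["scat"])):
    r = s["qc_report"]
    print(f"{name}: {r.n_input} segmented, {r.n_retained} retained after QC")
    print(f"  mean equivalent diameter: {s['recovered_mean_diameter']:.2f} um")
    print(f"  mean sphericity:          {s['recovered_mean_sphericity']:.3f}")
ks = study["ks"]
print(f"permutation KS: D = {ks.d_observed:.3f}, p = {ks.p_value:.3g} "
      f"({ks.m_permutations} permutations)")
```

prints

```
VAT-like: 120 segmented, 120 retained after QC
  mean equivalent diameter: 81.08 um
  mean sphericity:          0.954
SCAT-like: 120 segmented, 117 retained after QC
  mean equivalent diameter: 67.56 um
  mean sphericity:          0.952
permutation KS: D = 0.294, p = 0.0002 (10000 permutations)
```

The recovered means land within sampling error of the generating
presets (the pipeline never sees the ground truth), three SCAT cells grazing a
stack border are discarded, and the depot size distributions
differ decisively: with 10 000 permutations the smallest reportable
p-value is 1/10001 ≈ 1e-4.

The same stages are available as a CLI for on-disk data (TIFF stacks,
CSV cell tables, JSON reports):

```sh
adipo3d simulate --config cohort.yaml --out runs/demo
adipo3d segment  --input runs/demo/vat1_stack.tif --out vat1_labels.tif --spacing 1.15
adipo3d measure  --labels vat1_labels.tif --out vat1_cells.csv --spacing 1.15
adipo3d qc       --table vat1_cells.csv --out vat1_qc.csv
adipo3d compare  --table-a vat1_qc.csv --table-b scat1_qc.csv --out ks.json
```

Externally produced label stacks (e.g. Cellpose `*_masks` TIFFs) can
enter at `measure` via `adipo3d.load_labels(path, spacing)`.

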