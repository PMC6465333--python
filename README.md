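# cotranscoloc

Quantification toolkit for asking where a protein sits relative to the mRNA
that encodes it — the image-analysis and qPCR statistics used to demonstrate
co-translational assembly of protein complexes (e.g. the TAF8–TAF10
histone-fold dimer of TFIID) in single cells.

It is written for microscopists and molecular biologists who have:

* **IF-smiFISH data** — sequential immunofluorescence (protein) and
  single-molecule FISH (mRNA) on the same cells — and want the per-cell
  **enrichment ratio** of IF signal at RNA positions;
* **dual-colour smiFISH data** and want the **co-localized fraction** of two
  mRNA species by gated optimal assignment of the two 3D point clouds;
* **RIP-qPCR data** (RNA immunoprecipitation from polysome extracts read out
  by RT-qPCR) and want **% input RNA**, mock-relative **ΔΔCp fold
  enrichment**, and their replicate aggregation with −RT contamination QC.

Everything upstream is included: focus-based 2D projection, Otsu + watershed
nucleus segmentation, nucleus-seeded watershed cell segmentation, 3D LoG
spot detection with sub-voxel localization — plus a synthetic-scene
generator with known ground truth, so the whole pipeline is testable
without any raw data.

## The statistics

**Enrichment ratio (per cell).** With IF intensity $I(v)$ sampled at the
nearest voxel of each detected cytoplasmic RNA position, and the z-range
$[z_\min, z_\max]$ spanned by those RNAs,

$$
R_{\text{cell}} \;=\; \frac{\operatorname{median}_{\text{RNA positions}} I}
     {\operatorname{median}_{\text{cytoplasm},\, z\in[z_\min,z_\max]} I},
$$

so $R > 1$ means the protein is locally concentrated at its mRNA. The
statistic is invariant to cell-to-cell IF intensity scaling. Conditions are
compared per-cell with the two-sample Kolmogorov–Smirnov test.

**Co-localized fraction.** Two detected spot clouds $A, B$ (coordinates in
nm) are paired by a linear assignment problem solved with the Hungarian
algorithm; pairings beyond a gating radius $d_{\max}$ (default 300 nm, one
z-step) are forbidden via dummy assignments of cost $d_{\max}$. The fraction
is (number of gated pairs) / $|A|$. A cytoplasm-randomization null gives an
empirical p-value when no negative-control channel exists.

**RIP-qPCR.** Enrichment relative to input RNA is
$100 \times 2^{(Cp_{\text{input}} - 6.644) - Cp_{\text{IP}}}$ (“% input
RNA”; $6.644 = \log_2 100$ corrects the input dilution), mock-relative fold
enrichment is $2^{\Delta\Delta Cp[\text{IP}/\text{mock}]}$, and −RT controls
must sit ≥ 10 Cp above the +RT reactions. Technical replicates are averaged
on the Cp scale, statistics computed per biological replicate, then
mean ± SD.

## Worked example

Simulate a two-colour scene with a known IF enrichment factor (r = 2 is the
default), then run the full chain from the command line:

```bash
cotranscoloc simulate --seed 4 --out sim
cotranscoloc segment --dapi sim/dapi.tif --fish sim/fish1.tif --out seg
cotranscoloc detect --stack sim/fish1.tif --threshold 40 --out spots1.csv
cotranscoloc enrich --if sim/if.tif --spots spots1.csv \
    --cells seg/cells.tif --nuclei seg/nuclei.tif --out enr
```

`enr/enrichment.csv` then holds one row per analysable cell:

```
cell_id,n_spots,median_at_spots,normalization,ratio,z_range,norm_method
1,22,93.5,48.0,1.9479166666666667,"(1, 5)",median
2,21,137.0,70.0,1.957142857142857,"(2, 5)",median
```

Both cells recover a ratio close to the simulated factor 2: the median IF
intensity at the detected RNA positions (93.5 and 137.0 counts — the two
cells differ in overall IF level, which the ratio normalizes away) is about
twice the median cytoplasmic intensity within the RNA z-range (48.0 and
70.0). The same library calls are available in Python
(`cotranscoloc.enrichment_ratio`, `match_clouds`, `percent_input`, …), and
`cotranscoloc run --config cfg.yaml` executes multi-stage pipelines with a
single seed and a provenance report.

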