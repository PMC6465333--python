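# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states nothing the tests or the
reproducibility script do not themselves compute.

## Coordinate and mask conventions

Images are `(z, y, x)` arrays; voxel `i` along an axis has its physical
centre at `i * voxel_size` (0-based). Default geometry follows confocal
smiFISH practice: 70 nm lateral pixels, 300 nm z-spacing, 8-bit counts.
Spot coordinates are physical nanometres everywhere; Euclidean distances in
nm therefore absorb the lateral/axial anisotropy, and no per-axis weighting
is used. Cell and nucleus outlines are 2D label masks (as produced by
manual outlining or projection-based segmentation); they are applied to 3D
spots by `(y, x)` containment only, with z unrestricted except where an
operation defines a z-range. The cytoplasm of a cell is its footprint minus
its nucleus; cells with an empty cytoplasm are kept but flagged
non-analysable.

## Synthetic scenes

The generator emulates exactly the statistical structure the downstream
estimators assume, with known ground truth:

* **Cells** are non-overlapping 2D ellipses extruded over z, each with a
  concentric smaller nuclear ellipse. Placement is a jittered grid whose
  pitch guarantees disjoint bounding boxes with a 2 px margin; a scene that
  provably cannot hold the requested cells raises a placement error naming
  the offending parameters. The 2D-extruded geometry mirrors the hybrid
  2D-outline / 3D-spot analysis; it does not model curved or touching
  cells.
* **FISH spots** are anisotropic 3D Gaussians (defaults σ_xy = 1.3 px,
  σ_z = 1 slice, amplitude 120 counts) at uniform positions in the
  cytoplasm, over a cell-confined background (default 20 counts) that
  stands in for the diffuse cytoplasmic signal real smiFISH channels carry
  — it is what makes nucleus-seeded cell segmentation possible. Defaults of
  50–500 spots per cell span the plausible single-cell mRNA regime; the
  true per-cell densities of any particular transcript are not claimed.
* **Two-colour co-localization**: exactly `round(ρ·n)` channel-2 spots are
  placed at a distinct channel-1 partner plus per-axis Gaussian jitter
  truncated at 3 SD (so "partnered" is unambiguous); the remainder are
  independent uniform cytoplasmic positions. At high spot density and large
  gating radius, chance proximity of unpartnered spots inflates the
  recovered fraction; the validation studies use 40 spots/cell,
  15 nm jitter and a 100 nm gate, where that inflation is ≤ 0.01.
* **IF channel**: a per-cell background level — the nominal background
  (default 60 counts) times a per-cell factor with CV 0.2 (truncated below
  at 0.2), reflecting the cell-to-cell IF variability that motivates a
  per-cell ratio statistic in the first place — elevated by the factor *r*
  in a σ_xy-radius neighbourhood (the nearest voxel always included) of
  every channel-1 spot. Because enrichment is a factor on background, the
  true per-cell enrichment ratio equals *r* by construction. IF noise
  (default SD 6 = 10% of background) is Gaussian and independent of the
  FISH camera noise (default SD 2).
* All channels are rounded and clipped to the bit depth; clipped-voxel
  counts are reported and a warning raised. One RNG stream per operation,
  seeded from the parameter set: identical parameters and seed give
  bit-identical scenes, stacks and tables.

What the simulator does **not** model: realistic PSFs (no Gibson–Lanni),
photobleaching, autofluorescence gradients within a cell, 3D nuclear
texture, chromatic aberration, or touching cells. Passing recovery tests on
these scenes shows the estimators are correct and well-calibrated under
their own assumptions, not that those assumptions hold for any particular
real data set.

* **Cp tables**: template amounts follow a log2-linear model,
  `Cp = cp_at_unit − log2(amount) + N(0, σ)`. Input wells assay
  `abundance × input_dilution`, IP wells `abundance × ip_efficiency`, mock
  wells `abundance × mock_efficiency`. The default `input_dilution =
  2^−6.644` matches the % input formula's dilution-correction constant, so
  the formula applied to noise-free rows returns exactly
  `100 × ip_efficiency`. Default efficiencies (IP 0.10, mock 0.002) sit in
  the experimentally plausible range. −RT wells sit `rt_minus_gap`
  (default 15, floor 12) cycles above +RT and become "not detected" beyond
  45 cycles.

## Segmentation

The 2D projection picks, per pixel, the z-plane maximizing local intensity
variance in an odd window (default 15 px), restricted to ±1 plane of the
globally best-focused plane (highest mean local variance); ties go to the
lowest z. Local variance is the simplest metric combining local and global
focus; the function accepts any stack, and the metric could be swapped
without affecting downstream contracts.

Nuclei: Otsu threshold, Euclidean distance transform, seeds at maxima of
the smoothed distance map, watershed on the negated distance map, objects
below `min_area` (default 50 px) removed, labels renumbered 1..K. Cells:
the FISH projection is median-filtered (7 px) so Otsu separates background
from cell body rather than cell body from spots, smoothed (σ = 1.5 px), and
a nucleus-seeded watershed on the inverted smoothed image partitions the
Otsu foreground; every cell inherits its seed's label, nuclei are forced
inside their cells, and a nucleus outside the foreground yields
cell = nucleus with a warning. Watershed flooding order is deterministic.
These parameter choices are documented defaults, not claims about any
published workflow's settings.

`load_geometry` accepts externally drawn (manual) masks, matches nuclei to
cells by maximal overlap, relabels pairs consistently, trims nucleus pixels
outside their cell, and reports every rejected or degenerate label. It is
idempotent on its own output.

## Spot detection

Laplacian-of-Gaussian filtering at the expected scales (σ_xy, σ_z kept
separate — data are never resampled), normalized by the numerically
computed peak response of a unit-amplitude matched Gaussian so that the
detection threshold is an amplitude in camera counts. Local maxima within
one (anisotropy-normalized) σ are merged keeping the brighter; sub-voxel
positions are intensity-weighted centroids of the positive LoG response in
a ±2σ window (the positive response is background-free, which keeps the
centroid unbiased near flat backgrounds). Spots whose window is clipped by
the image border are flagged `border`, not dropped. Detection settings are
recorded verbatim in the output — comparisons across conditions are only
meaningful at identical settings. A full 3D Gaussian least-squares refiner
was deliberately not made the default: at the package's scales the centroid
localizes well under 0.25 voxel RMSE, and the point-cloud contract is what
downstream consumers depend on.

## Enrichment ratio

Per cell: restrict spots to the cytoplasm; read IF at each spot's nearest
voxel, take the median; the normalization factor is the median IF over
cytoplasm pixels across the inclusive z-slice range spanned by the spots;
the ratio is the quotient. Cells with fewer than `min_spots` (default 5 —
a median over fewer reads is unstable) are excluded with a recorded reason,
as are cells with a zero normalization factor. The cytoplasm normalization
uses the **median** by default with a `norm="mean"` switch: descriptions of
this procedure name both, and for a scale-invariant ratio the choice is a
convention, not a model change. Condition summaries report mean, SD (n−1)
and the 95% t-interval of the mean.

The two-sample KS comparison computes D as the sup ECDF difference over the
pooled sample points and takes p from the limiting Kolmogorov distribution
at effective size `n_a·n_b/(n_a+n_b)` — the classic asymptotic used by
common implementations. An exact small-sample option is deliberately
omitted; at the per-condition cell counts this package targets (≳ 20) the
asymptotic is adequate, and its mild conservatism is quantified by the null
calibration study below.

## Dual-colour matching

The gated assignment augments the nm distance matrix (entries beyond
`d_max` forbidden) with one dummy column per reference point at cost
`d_max`, and solves the square/rectangular LAP with the Hungarian
algorithm. This makes "unmatched" a first-class outcome: the solution
minimizes matched distance plus `d_max` per unmatched reference point,
which is the standard gated-LAP objective, and an extra match is taken
exactly when it costs less than leaving both points unmatched. Among
equal-cost optima the solver's deterministic choice is returned; all
oracle comparisons are on the (tie-invariant) total cost. The default gate
of 300 nm equals one axial step — the natural resolution bound — and is
always reported. The co-localized fraction divides by the first cloud by
default (switchable), matching the convention that the first colour is the
reference.

The randomization null redraws cloud B uniformly over the cytoplasm pixels
(sub-pixel jittered) with z uniform over B's observed z-extent — the
outlines being 2D, no z information exists to condition on — and reports
the add-one empirical p-value `(1 + #null ≥ obs)/(n_perm + 1)`.

## qPCR calculus

All formulas are closed-form on Cp values; "not detected" is a distinct
missing state, never a sentinel. `ΔΔCp[IP/mock]` is the input-normalized
double delta when input Cps are supplied and the single delta
`2^(Cp_mock − Cp_IP)` otherwise; outputs label which was used. The
dilution-correction constant 6.644 is exposed as `input_correction` for
labs with other input fractions. Aggregation averages technical replicates
on the Cp (log) scale, computes the statistic per biological replicate, and
reports mean ± SD with the per-replicate values retained; the order
(tech-then-bio) is declared, deterministic, and invariant to row order.
Combinations failing the −RT QC (gap < 10 cycles) are excluded by default.

## Validation studies and problem sizes

The studies in `cotranscoloc.studies` (run by the test suite and
`scripts/acceptance.py`) use deliberately compact scenes so a full run
completes in about a minute on one core: 30 cells per condition for
enrichment recovery (8×220×270 voxels per 5-cell scene, 50 spots/cell, IF
noise 10% of background), 20 cells per ρ for fraction recovery (40
spots/cell, 15 nm jitter, 100 nm gate), 200 replicate pairs of 50 small
cells × 20 spots for KS null calibration, 500 random cloud pairs of size
≤ 6 against exhaustive enumeration for the matcher, and 4-cell scenes for
segmentation. The calibration study uses many small cells with modest spot
counts because integer (bit-depth) camera counts quantize the per-cell
medians; with too few, large cells the ratios tie heavily and the KS test
becomes degenerate — a property of idealized flat synthetic cells, which
the per-cell IF variability factor (present in real data, and in the
generator) removes.

## Known limitations

* Segmentation is 2D and intensity-based; no learned models, no tracking,
  no 3D segmentation.
* The detector does not decompose dense spot clusters nor quantify
  transcription sites; counts saturate at high density.
* The matcher assumes chromatic registration has been handled upstream.
* The enrichment ratio reads single voxels; it is a per-cell statistic and
  deliberately does not quantify protein per spot.
* Microarray processing and probe design are out of scope.
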