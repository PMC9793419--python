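# Methods

This note documents the models, parameter choices and numerical conventions
behind `memfish`, and what the synthetic-data tests do and do not establish.

## The enrichment statistic

For each cell, the distance of every molecule to the nearest membrane is the
anisotropy-aware Euclidean distance transform (scipy EDT, sampling = voxel
spacing in µm) of the cell's label, with everything outside the cell —
background *and* neighboring cells — acting as boundary. Distances are
normalized per cell by the maximum interior distance (an inradius proxy), so
the deepest point of every cell maps to 1.0 regardless of cell size or
stage; this is what makes profiles comparable across embryos. Molecules are
binned in 10 half-open bins of normalized distance (last bin closed), with
bin 1 the outermost 10%. Each bin's count is divided by the bin's shell
volume fraction, computed by counting the cell's voxels whose normalized
distance falls in the bin:

    freq(b) = (count_b / N) · (V_cell / vol_b)

Properties maintained exactly: `Σ_b freq(b)·volfrac(b) = 1` for any profile
with ≥ 1 molecule (counts and shell volumes derive from the same field), and
invariance to a global rescaling of the voxel size. Pooled (whole-embryo)
profiles sum counts and shell volumes across cells before renormalizing;
per-cell profiles are also emitted.

**Spot assignment.** A spot belongs to the cell whose label contains its
voxel. Spots on background — typically membrane-hugging detections whose
fitted center crossed the boundary — are rescued to the nearest labeled
voxel within one voxel step and inherit that voxel's distance bin; anything
farther is discarded and counted in a discard report. Counts are weighted by
each spot's decomposed molecule count.

**Discretization limits (important).** The distance convention is the
standard voxel-center EDT: a cell voxel face-adjacent to background in z has
raw distance equal to the z spacing, and distances are measured to
background voxel centers. This convention carries an O(h) surface offset
(~0.16 voxel on average for a digital sphere) that does not cancel against
the normalization constant (whose offset at the cell center is ~0.02 voxel).
Consequences, quantified on digital spheres of radius 30–80 voxels:

* the voxelized outermost-10% shell holds 2.0–3.6% less volume than the
  analytic `1 − 0.9³ = 0.271`, so an all-membrane fixture's bin-1 frequency
  reads ≈ 3.80 rather than the continuum 3.690, at any practical radius;
* bin volumes are atoms of lattice distances (many voxels share the exact
  same EDT value), so shell fractions respond discontinuously to
  sub-milli-voxel changes in the normalization constant.

None of this affects *self-consistency*: molecules placed by the same field
reproduce frequency 1 per bin exactly in expectation, planted membrane
fractions are recovered unbiased, and conservation is exact. It only limits
agreement with closed-form continuum geometry. The acceptance tests state
the continuum claims verbatim and two of them are therefore expected to
fail at tolerance (bin-1 = 3.690 ± 2%; and the ±0.05 per-bin uniform
calibration at n = 50,000, whose two innermost bins have multinomial SDs of
0.053 and 0.141 — larger than the band — because they hold only 0.7% and
0.1% of a sphere's volume; ±0.05 at 3σ in the innermost bin would need
n ≈ 3.6 million).

## The synthetic embryo

**Geometry.** An eggshell ellipsoid (default semi-axes 0.46 × the grid
extent) is partitioned into 1/2/4/8 cells as the µm-metric Voronoi
compartments of stage-specific anchor points, jittered ±5% of the semi-axes
per seed. Cells are convex, packed, connected and disjoint; nuclei sit at
cell centroids. This preserves the geometry the statistic depends on
(closed cells with shared membranes, realistic aspect ratios at 0.2 µm axial
× 0.1 µm lateral spacing) and nothing else: there is no eggshell
autofluorescence, no developmental asymmetry (AB/P1 volume difference), no
non-convex cell shapes.

**Localization models.**

* `uniform` — every voxel of a cell equally likely, uniform within the
  voxel; each molecule's true normalized distance is read from the same
  field the quantification uses, making calibration checks exact in
  expectation.
* `membrane` — with probability `membrane_fraction` a molecule is placed
  uniformly in the shell (normalized distance < `membrane_shell`, default
  0.1), otherwise uniformly in the complement. Sampling the complement
  (rather than the whole cell) makes the planted fraction identical to the
  expected measured membrane fraction, i.e. an exactly recoverable
  parameter. Default `membrane_fraction = 0.5`, matching the ~1.8-fold
  bin-1 enrichment typical of strongly membrane-localized transcripts
  (1.8 × 0.271 ≈ 0.49).
* `clustered` — `n_clusters` isotropic Gaussian clusters (default 5 × 20
  molecules, σ = 0.1 µm, the scale of germ-granule aggregates), centers
  ≥ max(8σ, 1 µm) apart and ≥ 2σ from the membrane so planted clusters are
  unambiguous; remaining molecules are uniform singletons.

An optional `min_distance` rejection produces *resolvable* spot fields for
detection benchmarks (see below).

**Rendering.** The smFISH channel is a sum of peak-normalized anisotropic
Gaussians, σ = (0.35, 0.13, 0.13) µm — a typical widefield 60×/1.42 NA
point-spread scale — evaluated at voxel centers (voxel i spans
[i·h, (i+1)·h)). Default peak amplitude 150 photons over a 100-photon
baseline with Poisson shot noise and Gaussian read noise (SD 2). Controlled
fixtures use Gaussian-only noise with SD = amplitude/SNR, so "SNR 5" means
peak/noise = 5. The membrane channel is the smoothed label interface; DAPI
(and the optional GFP reporter) are Gaussian nuclear blobs. Default
abundance is 2400 molecules per four-cell embryo, the scale of a strongly
expressed localized transcript.

## Detection and counting

Band-pass: difference of Gaussians with σ_small = PSF prior and σ_large =
2.5 × PSF, both specified in µm and converted per axis. The detection
threshold is expressed in robust SDs (1.4826 × MAD) of the filtered volume,
default 5 — an explicit, reproducible stand-in for interactive threshold
picking. Candidates are 26-connected local maxima, excluding the one-voxel
border (reflect padding fabricates maxima there; real analyses exclude edge
slices anyway), suppressed to a minimum pairwise separation (default 0.6 µm;
strongest response wins, ties broken by raw intensity then voxel order).
Each candidate is refined by least squares against
`A·exp(−Δz²/2σ_z² − (Δy²+Δx²)/2σ_xy²) + b` in a 9³-voxel window; fits are
rejected if σ leaves [0.5×, 3×] the PSF prior, the center leaves the window,
the amplitude is non-positive, or R² < 0.05. Integrated intensity is
`A·(2π)^{3/2}·σ_z·σ_xy²` in voxel units.

**What a green detection test establishes.** Precision/recall ≥ 0.95 is
asserted on fields whose spots are ≥ 1 µm apart — beyond the ~3σ_z axial
resolution. At realistic abundances (2400/embryo) a large fraction of
molecule pairs are intrinsically unresolvable; raw recall then drops to
~0.5–0.7 *by physics, not by detector defect*, and the pipeline's abundance
estimate is instead the decomposed molecule total, which stays within ~10%
of truth at that density. Counting: the reference single-molecule intensity
is the median after iteratively trimming intensities > 2 × the current
median (removes aggregates), spread = 1.4826 × MAD of the retained spots;
each spot receives `argmax_k N(I; k·μ, k·s²)` with s floored at 5% of μ,
ties toward smaller k, k ≤ 20. Spatial clusters are single-linkage
components at 0.3 µm whose summed molecule counts reach 3.

## Statistics

Welch's two-sample t-test is computed from the closed form (t, the
Welch–Satterthwaite df, two-sided p from the t distribution) and is verified
against scipy's independent implementation to 1e-10. Groups need n ≥ 2 and
nonzero variance. Stars follow the smFISH-literature legend convention
(**** p<0.00005, *** p<0.0005, ** p<0.005, * p<0.05); no multiple-testing
correction is applied, matching the practice the tables feed into.

Localization calls: an embryo is `localized` iff its pooled bin-1 frequency
≥ 1.5, a threshold placed between the random baseline (1.0) and the weakest
enrichment class seen in practice (~1.8-fold); profiles with < 50 molecules
are `indeterminate` and excluded from proportions. The call is monotone in
the bin-1 frequency and the threshold is configurable.

Nuclear RFU: Otsu threshold of DAPI within the embryo mask, objects < 27
voxels removed; RFU = mean reporter in nuclei − mean reporter outside the
embryo (complement eroded by 2 voxels against edge bleed).

## Recoding

Per codon, the synonymous codon with maximal Hamming distance to the
original is chosen among codons with within-family usage ≥ `min_usage`
(default 0.05, bundled approximate C. elegans usage table); ties break to
the higher-usage codon, then alphabetically. Stops stay within the stop
family. The rule is deterministic (the seed argument is reserved for a
future stochastic mode). Translation preservation is exact by construction
and property-tested. Note the nucleotide identity this rule attains (~54% on
random sequences) is a *lower* bound than vendor recoders typically leave;
no specific nt-identity value is a target of this implementation.

## Degenerate inputs and tie-breaking (summary)

Empty spot sets: detection returns an empty set (not an error); profiling a
zero-spot cell yields zero frequencies; `membrane_fraction` on an empty
profile raises. Cells with no interior after slice exclusion raise a
degenerate-cell error naming the cell. Polygon rasterization uses
pixel-center, half-open fill (a side-s axis-aligned square covers exactly s²
pixels; edge-sharing cells never double-claim); overlapping interiors are an
error, first-listed cell wins contested boundary pixels. All RNG is local
`numpy.random.default_rng(seed)`; no global state.

## Desk scaling in the test suite

End-to-end tests run at reduced scale to fit a single CPU: cohorts use
2-cell embryos at 24×128×128 voxels with 600 molecules; end-to-end
fraction recovery uses the full-size 40×256×256 four-cell stack at 1000
molecules. The localization models, SNR definitions, thresholds and all
defaults are unchanged by scaling; only stack sizes and molecule counts
shrink.
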