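# Methods

## The segmentation model

`retidiff` treats intraretinal layer segmentation as spectral clustering of a
coarse-grained affinity graph. Voxels are pooled into rectangular blocks; a
block is a graph node carrying its centroid `X` (voxel units) and its mean
intensity `F`. The affinity between two nodes is a product of Gaussian
kernels in feature space and in geometric space, truncated to zero at
geometric distance `r` so the matrix stays sparse, with `k(i,i) = 1`. Degree
normalisation produces the row-stochastic transition matrix `P` of a
reversible Markov chain; its spectrum `λ₁ ≥ λ₂ ≥ …` (the trivial stationary
pair `λ = 1` with constant eigenvector is dropped) defines the diffusion
coordinates `Ψ_τ(i) = (λ₁^τ ψ₁(i), …, λ_ω^τ ψ_ω(i))`, and k-means on those
coordinates yields the clustering.

Assumptions: layers are distinguishable by regional mean intensity (texture),
not by edges; each layer is a depth-contiguous slab per lateral position; the
retina is the spatially middle of three depth bands. The method is designed
for scans of normal eyes; pathology that destroys the layered topology is out
of scope.

Numerically the eigenproblem is solved on the symmetric conjugate
`D^{-1/2} K D^{-1/2}`, which shares the spectrum of `P` (`ψ = D^{-1/2} v`).
Below 600 nodes a dense symmetric solver is used; above that, ARPACK with
tolerance 1e-7 and a seeded start vector — the default (machine-precision)
tolerance stalls on the near-degenerate spectra of strongly layered graphs,
and an unseeded start vector makes reruns non-reproducible. Eigenvector signs
are fixed by the largest-magnitude entry so identical inputs give identical
embeddings.

### Clustering in the embedding

Per-node embedding mass scales with `1/√degree`, so low-degree nodes
(boundary blocks, noise outliers) carry far larger coordinate norms than the
bulk. Plain k-means then spends clusters on those few nodes and merges real
layers — we observed exactly this on phantoms. `cluster_embedding` therefore
projects the coordinate rows onto the unit sphere before k-means (the
standard practice in spectral clustering) unless `normalize_rows=False`; the
projection is skipped for one-dimensional embeddings, where it would collapse
everything to ±1. k-means runs 10 seeded restarts and keeps the lowest
within-cluster sum of squares, so reruns are deterministic.

## Two-stage segmentation

**Stage 1 — band isolation.** Blocks of 4×2×2 voxels, `σ_feature = 0.2`
(fixed), `ω = 3`, three clusters on the raw (unnormalised) coordinates. The
soft feature scale is deliberate: with the range-derived scale
(`0.15 ×` distance range — the package's `estimate_scale` rule, still the
default for generic use) every layer of a high-contrast volume becomes its
own graph component and a three-way partition of ~13 components is arbitrary.
At `σ_feature = 0.2` the layered retina coheres into one component while the
dark vitreous and the sub-RPE region cut off, and the three clusters are the
three depth bands. Clusters are ranked by mean depth; the middle one is the
retina. Its voxel labels are regularised per (x, z) column into one
contiguous interval (single-voxel gaps filled, largest run kept); columns the
cluster missed inherit bounds from the nearest valid column; a band thinner
than 12 voxels is widened (12 surfaces must stay representable). On default
phantoms the band edges land within ~0.5 voxels of the true inner and outer
retinal boundaries.

**Stage 2 — layer localisation.** Blocks of 4×1×2 voxels (single-voxel axial
resolution), `σ_feature = 0.02`, `r = 6`, `ω = 12`, 11 clusters on
unit-normalised coordinates. The sharp feature scale makes every
between-layer reflectivity step a strong graph cut; `ω = 12` keeps one
coordinate more than the 11 indicator-like cut modes need. The graph is built
on the band eroded by one voxel at top and bottom: blocks straddling the
vitreous or sub-RPE boundary form wide outlier clouds in the embedding that
starve the layer clusters. Surfaces 1 and 12 still come from the full band
bounds.

Clusters map to layers 1–11 by **median** node depth (a mean is dragged out
of rank by a handful of stray nodes — observed on specific speckle
realisations). Voxel labels are median-smoothed along depth (valid for
ordinal labels), then converted per column: surface 1 = band top, surface
12 = band bottom + 1, interior surface `s+1` = first axial index of layer
`s+1`'s run at or below the previous surface. Columns missing a run are
filled by iterative 4-neighbour interpolation (a surface missing everywhere
is interpolated between its neighbours and flagged). Columns are projected
onto the monotone cone by isotonic regression, each surface is smoothed with
a 3×3 median filter, and monotonicity is re-imposed.

### Self-audit and retry ladder

On a small fraction of speckle realisations the stage-2 clustering fails
structurally: two feature-similar layers collide in the retained eigenspace
while a thick layer splits. All observed failure modes are visible without
ground truth, so `localize_layers` audits each attempt:

* empty clusters;
* a parasite cluster far below `0.2 × n/11` nodes;
* depth-adjacent clusters with mean-feature gap `< 0.08` (a split pair);
* `> 1 %` of in-band voxel pairs whose ordinal label drops by ≥ 3 along
  depth (a non-adjacent merge);
* disagreement between the mean-depth and median-depth cluster orderings
  (a dragged-out-of-rank cluster).

If the audit fails, the embedding is recomputed over a deterministic
six-step ladder varying `ω` (12 → 11), `σ_feature` (0.02 → 0.03) and the
seed; the best-scoring attempt is kept. On 28 phantom instances (14 seeds ×
{noise-free, speckle 0.1}) the audited pipeline recovers all 12 surfaces
with mean unsigned error 0.62–0.77 voxels and worst single-surface error
1.5 voxels; most instances accept the first attempt, so the ladder costs
nothing in the common case.

Segmentation min–max renormalises the volume first, so results are invariant
to global affine intensity rescaling.

## Thickness, fovea, ETDRS, statistics

Layer `L` thickness at (x, z) is `(depth[L+1] − depth[L]) ×` axial spacing
(µm); the total map is the sum of the 11 layer maps, an exact identity by
construction. The foveal centre is the argmin of the NFL thickness map after
a mean filter (window 5 — a raw argmin is unstable under noise; the window is
a package choice), with ties broken toward the grid centre and then
lexicographically.

The ETDRS grid defaults to 1 / 3 / 6 mm circle diameters (the standard
ETDRS geometry; configurable). Ring boundaries are half-open with the inner
edge included; quadrants split on the ±45° diagonals with diagonal pixels
assigned to the superior/inferior sectors; superior is −z; nasal is +x for OD
and −x for OS, so mirroring swaps sectors 3↔5 and 7↔9 and is an involution.
Sector summaries use the sample SD (n−1). Cohort statistics: pooled-variance
unpaired *t* for sex, one-way ANOVA *F* across sectors, and the *t*-test on
the least-squares slope for age, all via scipy.stats behind the package's
interface; degenerate inputs (zero variance, constant response) resolve by
convention and are flagged. No multiplicity correction is applied by default,
matching common practice in normative-thickness reports; Bonferroni is a
flag.

## The phantom

The generator emulates what the pipeline keys on: a dark vitreous
(reflectivity 0.05) above 11 layers with pairwise-distinct mean
reflectivities (bright NFL 0.85, IPL 0.70 and RPE 0.90; dark nuclear layers,
ONL complex 0.25; adjacent contrast ≥ 0.05), a dim sub-RPE region (0.12),
peripheral layer thicknesses summing to 335 µm (NFL 35, GCL/IPL/INL 30,
OPL 25, ONL complex 80, ISL 25, CL 15, OSL 25, VM 15, RPE/BM 25 µm — in the
range of normal macular anatomy), a Gaussian foveal pit (90 µm deep,
500 µm radius) thinning the inner layers 1–4 in proportion to their
thickness (an optional ONL bulge is off by default), low-frequency surface
undulation (5 µm amplitude), and multiplicative log-normal speckle with unit
mean (`σ = 0.1` by default; additive Gaussian available). The default volume
is 64×128×16 voxels at (94, 3.87, 375) µm spacing so the lateral field spans
6×6 mm (the full ETDRS grid) and the full pipeline runs in seconds.

Cohorts draw age uniform over 18–89 years, sex Bernoulli(0.4 male) — the
demographic profile typical of normative studies — and perturb the total
thickness by `−0.3 µm/yr × (age − mid-age) + 8 µm × [male] + N(0, 10 µm)`,
spread over layers proportionally to baseline thickness, alternating OD/OS
with x-mirroring. These defaults give ~85 % power for the sex effect at
n = 60, so an individual cohort draw can miss significance — that is honest
sampling behaviour, not a defect.

What the phantom does **not** model: vessel shadows, motion artifacts, the
device point-spread function, depth-dependent signal roll-off, pathology,
and real OCT speckle correlation. Passing tests therefore demonstrate that
the algorithmic chain is correct and robust to uncorrelated multiplicative
noise at realistic contrast — not that the pipeline meets any particular
error level on clinical scans.

## Problem sizes and determinism

Tests and the acceptance script use the default 64×128×16 phantom
(~8 000 stage-1 and ~14 000 stage-2 nodes), 100 random kernels up to n = 300
for the Markov contract, 50 disconnected-graph instances up to n = 200 for
the oracle-equivalence check, 2000 null simulations for type-I calibration,
and 60-subject cohorts (ground-truth surfaces only) for parameter recovery —
sizes chosen so the whole suite runs in a few minutes on one CPU. Every
random draw is seeded; rerunning any entry point with the same seed
reproduces its output bit for bit.

## Known limitations

* The cluster→surface conversion assumes one run of each layer per column;
  heavy label noise is handled by interpolation and flagged, not modelled.
* Stage-2 feature scales are tuned to min–max-normalised volumes; volumes
  whose layer contrast is far below 0.05 after normalisation may need a
  custom `DiffusionConfig`.
* The ETDRS outer ring (6 mm) only just fits the default phantom's lateral
  field; off-centre foveae clip the outer sectors (flagged as `partial`).
* Cohort statistics pool eyes and subjects without modelling intra-subject
  correlation when both eyes of a subject are present; the manifest carries
  eye side so users can filter.
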