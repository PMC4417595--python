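# retidiff

Three-dimensional intraretinal layer segmentation for macular SD-OCT volumes
using coarse-grained diffusion maps, with downstream thickness mapping, ETDRS
nine-sector summaries and the cohort statistics used for normative thickness
databases.

Spectral-domain optical coherence tomography resolves the retina into about a
dozen reflectivity bands. Quantifying the thickness of each anatomical layer —
nerve fiber layer (NFL), ganglion cell layer (GCL), inner plexiform (IPL),
inner nuclear (INL), outer plexiform (OPL), the outer nuclear complex
(ONL+OLM+HFL), inner segments (ISL), connecting cilia (CL), outer segments
(OSL), Verhoeff membrane (VM) and RPE/Bruch membrane — across the ETDRS
macular sectors underpins normative databases and the study of glaucoma,
diabetic retinopathy and photoreceptor disease. `retidiff` segments all 11
layers (12 surfaces) at once from regional texture rather than image
gradients, so it tolerates low layer-to-layer contrast.

## Method

A volume is pooled into rectangular voxel blocks; each block becomes a graph
node *i* with position *X₍ᵢ₎* (centroid, voxel units) and feature *F₍ᵢ₎*
(mean intensity). Affinities use a joint Gaussian kernel truncated at radius
*r*:

```
k(i,j) = exp(−‖F₍ᵢ₎−F₍ⱼ₎‖² / 2σ²_feature) · exp(−‖X₍ᵢ₎−X₍ⱼ₎‖² / 2σ²_geo),   ‖X₍ᵢ₎−X₍ⱼ₎‖ < r
```

Degree normalisation `s(x) = Σ_y k(x,y)`, `p₁(x,y) = k(x,y)/s(x)` turns the
kernel into the transition matrix **P** of a reversible Markov chain (every
row sums to 1). Its eigenpairs `Pψᵢ = λᵢψᵢ` define the diffusion map after τ
steps,

```
Ψ_τ(i) = (λ₁^τ ψ₁(i), …, λ_ω^τ ψ_ω(i)),
```

and k-means in this ω-dimensional space clusters the nodes. Segmentation runs
the machinery twice: stage 1 partitions the volume into three depth bands
(vitreous / retina / below) and keeps the middle band; stage 2 re-clusters
the band into 11 texture classes, orders them by depth, and converts the
labels into 12 non-crossing boundary surfaces (isotonic projection plus
median smoothing). Surfaces become per-layer thickness maps in µm; the foveal
centre is the minimum of the smoothed NFL map; the ETDRS grid (1/3/6 mm
circles, nasal/temporal mirrored between OD and OS) yields per-sector
mean ± SD, and cohort-level sex (unpaired *t*), sector (one-way ANOVA *F*)
and age (regression-slope *t*) statistics.

A synthetic phantom module generates OCT-like volumes with known 12-surface
ground truth — 11 layers with realistic reflectivity contrast, a Gaussian
foveal pit, surface undulation, multiplicative speckle, and programmable
age/sex effects for cohorts — so the whole pipeline is testable without
clinical data.

## Worked example

```bash
python examples/segment_phantom.py
```

```
phantom: (64, 128, 16) voxels, speckle sigma=0.1
surface |  unsigned error (µm) | signed error (µm)
   1    |      1.41            |    +1.41
   2    |      1.52            |    +1.52
  ...
  12    |      1.52            |    -0.03
mean unsigned: 2.41 µm (0.62 voxels)
```

The phantom's 12 true surfaces are recovered with a mean unsigned
border-positioning error of 2.41 µm (0.62 axial voxels) under speckle —
every boundary lands within about one axial sample of the true interface.
Other examples cover thickness maps and foveal localisation
(`thickness_and_fovea.py`), ETDRS sector tables and OD/OS mirroring
(`etdrs_sectors.py`), cohort statistics recovering programmed age/sex effects
(`cohort_statistics.py`) and the bare diffusion-map machinery
(`diffusion_map_basics.py`).

A thin CLI wraps the same functions:

```bash
retidiff phantom --seed 0 --out work/
retidiff segment work/phantom.tif --out work/seg/
retidiff thickness work/seg/surfaces.tsv --axial-um 3.87 --out work/maps/
retidiff sectors work/maps --eye OD --spacing-um 94 375 --out work/sectors.csv
```

## Coordinate conventions

Arrays are indexed `(x, y, z)`: `x` lateral within a B-scan, `y` axial depth
increasing downward (vitreous at `y = 0`), `z` B-scan index; indices are
0-based. Intensities are min–max normalised to [0, 1] per volume. Voxel
spacing (µm) must be supplied as metadata — it is never guessed.

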