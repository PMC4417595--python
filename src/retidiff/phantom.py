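"""Synthetic OCT phantoms with known 12-surface ground truth.

The phantom emulates the features of a macular SD-OCT volume that the
segmentation pipeline keys on: a dark vitreous above a band of 11
piecewise-smooth layers, each with its own mean reflectivity (bright nerve
fiber / plexiform / RPE layers, dark nuclear layers — the qualitative
reflectivity pattern by which OCT layers are recognised), a Gaussian foveal
pit thinning the inner layers, gentle low-frequency surface undulation, and
multiplicative speckle.  Cohorts add per-subject age/sex covariate effects
on layer thickness so the downstream statistics can be exercised with known
programmed effects.

It deliberately omits vessel shadows, motion artifacts, the device
point-spread function and pathology; see the methods note for what that
implies about passing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .io_volume import N_LAYERS, N_SURFACES, SubjectMeta, SurfaceSet, Volume

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "CohortSubject",
    "ground_truth_surfaces",
    "generate_phantom",
    "generate_cohort",
]

#: Default per-layer mean reflectivities, inner to outer.  Chosen so every
#: pair of layers differs by at least 0.05: bright NFL/IPL and RPE, darker
#: nuclear layers (GCL/INL and especially the ONL complex).
DEFAULT_REFLECTIVITY: tuple[float, ...] = (
    0.85,  # NFL
    0.45,  # GCL
    0.70,  # IPL
    0.35,  # INL
    0.60,  # OPL
    0.25,  # ONL+OLM+HFL
    0.55,  # ISL
    0.40,  # CL
    0.65,  # OSL
    0.50,  # VM
    0.90,  # RPE/BM
)

#: Default peripheral layer thicknesses (µm), inner to outer; total 335 µm,
#: in the range of normal macular total retinal thickness.
DEFAULT_THICKNESS_UM: tuple[float, ...] = (
    35.0,  # NFL
    30.0,  # GCL
    30.0,  # IPL
    30.0,  # INL
    25.0,  # OPL
    80.0,  # ONL+OLM+HFL
    25.0,  # ISL
    15.0,  # CL
    25.0,  # OSL
    15.0,  # VM
    25.0,  # RPE/BM
)


@dataclass
class PhantomConfig:
    """Geometry, optics and noise of one synthetic volume.

    ``spacing_um`` defaults put the 64 × 16 lateral grid over a 6 × 6 mm
    macular field (so the full ETDRS grid fits) with ~3.9 µm axial sampling.
    ``foveal_pit`` is (depth µm, radius µm, indices of the thinned layers);
    by default only the inner layers 1–4 thin at the fovea, matching the
    foveal minima of the nerve fiber, plexiform and nuclear inner layers
    (optionally layer 6 can instead thicken, see ``foveal_onl_bulge_um``).
    """

    shape: tuple[int, int, int] = (64, 128, 16)
    spacing_um: tuple[float, float, float] = (94.0, 3.87, 375.0)
    base_depth_um: float = 80.0
    layer_thickness_um: Sequence[float] = DEFAULT_THICKNESS_UM
    layer_reflectivity: Sequence[float] = DEFAULT_REFLECTIVITY
    vitreous_reflectivity: float = 0.05
    sub_rpe_reflectivity: float = 0.12
    foveal_pit: tuple[float, float, tuple[int, ...]] = (90.0, 500.0, (1, 2, 3, 4))
    foveal_onl_bulge_um: float = 0.0
    surface_undulation: tuple[float, float] = (5.0, 16.0)  # amplitude µm, corr. px
    speckle_sigma: float = 0.1
    noise_model: str = "lognormal"  # or "gaussian" (additive)
    eye_side: str = "OD"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_thickness_um) != N_LAYERS:
            raise ValidationError("need 11 layer thicknesses")
        if len(self.layer_reflectivity) != N_LAYERS:
            raise ValidationError("need 11 layer reflectivities")
        if any(t < 0 for t in self.layer_thickness_um):
            raise ValidationError("layer thicknesses must be >= 0")
        if any(not (0 <= rf <= 1) for rf in self.layer_reflectivity):
            raise ValidationError("reflectivities must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise ValidationError("speckle_sigma must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValidationError("noise_model must be 'lognormal' or 'gaussian'")

    def adjacent_contrast(self) -> float:
        """Diagnostic: smallest reflectivity contrast between adjacent layers."""
        refl = np.asarray(self.layer_reflectivity)
        steps = np.abs(np.diff(np.concatenate([
            [self.vitreous_reflectivity], refl, [self.sub_rpe_reflectivity]
        ])))
        return float(steps.min())


@dataclass
class CohortConfig:
    """Programmed covariate structure of a synthetic cohort.

    Age slope and sex offset act on the total retinal thickness (µm of total
    per unit of covariate) and are distributed over the layers in proportion
    to their baseline thickness; between-subject noise perturbs the total
    the same way.
    """

    n_subjects: int = 60
    age_range: tuple[float, float] = (18.0, 89.0)
    male_fraction: float = 0.4
    age_slope_um_per_year: float = -0.3
    sex_offset_um: float = 8.0  # men minus women, on total thickness
    between_subject_sd_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValidationError("male_fraction must lie in [0, 1]")
        if self.between_subject_sd_um < 0:
            raise ValidationError("between_subject_sd_um must be >= 0")


@dataclass
class CohortSubject:
    """One synthetic subject: volume (optional), ground truth, covariates."""

    truth: SurfaceSet
    age: float
    sex: str
    eye_side: str
    volume: Optional[Volume] = None
    subject_id: int = 0


def _smooth_field(shape_xz, amplitude, corr_px, rng) -> np.ndarray:
    """Zero-mean low-frequency random field with the given amplitude (max |.|)."""
    if amplitude == 0.0:
        return np.zeros(shape_xz)
    white = rng.standard_normal(shape_xz)
    smooth = ndimage.gaussian_filter(white, sigma=corr_px, mode="wrap")
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros(shape_xz)
    return smooth / peak * amplitude


def _thickness_field_um(cfg: PhantomConfig) -> np.ndarray:
    """(11, nx, nz) ground-truth thickness field in µm, before any noise."""
    nx, _, nz = cfg.shape
    sx, _, sz = cfg.spacing_um
    base = np.asarray(cfg.layer_thickness_um, dtype=np.float64)
    field_um = np.broadcast_to(base[:, None, None], (N_LAYERS, nx, nz)).copy()

    pit_depth, pit_radius, pit_layers = cfg.foveal_pit
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    dx = (np.arange(nx)[:, None] - cx) * sx
    dz = (np.arange(nz)[None, :] - cz) * sz
    r2 = dx**2 + dz**2
    bump = np.exp(-r2 / (2 * (pit_radius / 2.0) ** 2))  # Gaussian pit profile

    if pit_depth > 0 and pit_layers and base[[int(L) - 1 for L in pit_layers]].sum() > 0:
        idx = [int(L) - 1 for L in pit_layers]
        share = base[idx] / base[idx].sum()
        for s, L in zip(share, idx):
            field_um[L] -= pit_depth * s * bump
    if cfg.foveal_onl_bulge_um:
        field_um[5] += cfg.foveal_onl_bulge_um * bump

    return np.clip(field_um, 0.0, None)


def ground_truth_surfaces(cfg: PhantomConfig, rng=None) -> SurfaceSet:
    """Ground-truth surfaces (voxel units) for a phantom, before rendering.

    The top surface is the base depth plus a low-frequency undulation; the
    remaining surfaces follow by accumulating the per-layer thickness field.
    """
    nx, ny, nz = cfg.shape
    ax_um = cfg.spacing_um[1]
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    amp, corr = cfg.surface_undulation
    top_um = cfg.base_depth_um + _smooth_field((nx, nz), amp, corr, rng)
    if top_um.min() < 0:
        raise ValidationError("undulation pushes the top surface above y=0")

    thick_um = _thickness_field_um(cfg)
    depths_um = np.empty((N_SURFACES, nx, nz))
    depths_um[0] = top_um
    np.cumsum(thick_um, axis=0, out=depths_um[1:])
    depths_um[1:] += top_um[None]

    if depths_um[-1].max() > ny * ax_um:
        raise ValidationError(
            f"layers exceed axial extent: deepest surface "
            f"{depths_um[-1].max():.1f} µm > {ny * ax_um:.1f} µm"
        )
    return SurfaceSet(depths=depths_um / ax_um)


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, SurfaceSet]:
    """Render one phantom volume and its ground-truth surfaces.

    Each inter-surface region is filled with its layer reflectivity; speckle
    is multiplicative lognormal with unit mean (or additive Gaussian when
    configured) and the result is clipped to [0, 1].  Deterministic per seed.
    """
    nx, ny, nz = cfg.shape
    rng = np.random.default_rng(cfg.seed)
    truth = ground_truth_surfaces(cfg, rng=rng)
    depths_vox = truth.depths

    # voxel layer index: number of surfaces at or above the voxel centre
    y = np.arange(ny)[None, :, None]
    region = np.zeros((nx, ny, nz), dtype=np.int64)  # 0 = vitreous .. 12 = sub-RPE
    for s in range(N_SURFACES):
        region += y >= depths_vox[s][:, None, :]

    lut = np.concatenate(
        [
            [cfg.vitreous_reflectivity],
            np.asarray(cfg.layer_reflectivity, dtype=np.float64),
            [cfg.sub_rpe_reflectivity],
        ]
    )
    img = lut[region]

    if cfg.speckle_sigma > 0:
        if cfg.noise_model == "lognormal":
            sig = cfg.speckle_sigma
            noise = rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=img.shape)
            img = img * noise
        else:
            img = img + rng.normal(0.0, cfg.speckle_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    volume = Volume(
        intensities=img, spacing_um=cfg.spacing_um, eye_side=cfg.eye_side
    )
    return volume, truth


def generate_cohort(
    cfg: CohortConfig,
    phantom_cfg: Optional[PhantomConfig] = None,
    render_volumes: bool = True,
) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Draw a cohort of phantoms with programmed age/sex thickness effects.

    Per subject: age uniform over the configured range, sex Bernoulli, a
    total-thickness shift ``slope·(age − mid-age) + offset·[male] + noise``
    spread proportionally over the layers, and alternating OD/OS with the
    volume mirrored in x for OS.  Returns the subjects plus a manifest frame
    (subject id, age, sex, eye side, programmed total thickness).
    """
    if phantom_cfg is None:
        phantom_cfg = PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    base = np.asarray(phantom_cfg.layer_thickness_um, dtype=np.float64)
    base_total = float(base.sum())
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])

    subjects: list[CohortSubject] = []
    manifest_rows = []
    for k in range(cfg.n_subjects):
        age = float(rng.uniform(*cfg.age_range))
        sex = "M" if rng.random() < cfg.male_fraction else "F"
        eye_side = "OD" if k % 2 == 0 else "OS"
        delta = (
            cfg.age_slope_um_per_year * (age - mid_age)
            + (cfg.sex_offset_um if sex == "M" else 0.0)
            + rng.normal(0.0, cfg.between_subject_sd_um)
        )
        scale = max((base_total + delta) / base_total, 0.0)
        if base_total + delta < 0:
            import warnings

            warnings.warn("programmed effects drove thickness negative; clipped at 0")
        sub_cfg = replace(
            phantom_cfg,
            layer_thickness_um=tuple(base * scale),
            eye_side=eye_side,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if render_volumes:
            volume, truth = generate_phantom(sub_cfg)
        else:
            volume, truth = None, ground_truth_surfaces(sub_cfg)
        if eye_side == "OS":
            truth = SurfaceSet(depths=truth.depths[:, ::-1].copy())
            if volume is not None:
                volume = Volume(
                    intensities=volume.intensities[::-1].copy(),
                    spacing_um=volume.spacing_um,
                    eye_side="OS",
                )
        if volume is not None:
            volume = Volume(
                intensities=volume.intensities,
                spacing_um=volume.spacing_um,
                eye_side=eye_side,
                subject_meta=SubjectMeta(age=age, sex=sex),
            )
        subjects.append(
            CohortSubject(
                truth=truth,
                age=age,
                sex=sex,
                eye_side=eye_side,
                volume=volume,
                subject_id=k,
            )
        )
        manifest_rows.append(
            {
                "subject_id": k,
                "age": age,
                "sex": sex,
                "eye_side": eye_side,
                "programmed_total_um": base_total + max(delta, -base_total),
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    return subjects, manifest
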