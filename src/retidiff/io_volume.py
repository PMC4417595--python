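"""Volume, surface and thickness-map I/O plus the coordinate conventions.

Every array in the package follows one axis convention, fixed here and
nowhere else:

* axis 0 — ``x``, lateral position within a B-scan;
* axis 1 — ``y``, axial depth, increasing downward (vitreous at ``y = 0``);
* axis 2 — ``z``, B-scan index.

Indices are 0-based.  Intensities are min–max normalised to ``[0, 1]`` per
volume on read, so that feature distances downstream live on a fixed scale.

Supported on-disk formats: multi-page TIFF (pages are B-scans), NIfTI
(``.nii``/``.nii.gz``, stored ``(x, y, z)``), and raw ``float32`` with a JSON
sidecar.  Voxel spacing is never guessed: a volume without spacing metadata
is a configuration error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

#: Anatomical names of the 11 segmented layers, inner (vitreous side) first.
LAYER_NAMES: tuple[str, ...] = (
    "NFL",
    "GCL",
    "IPL",
    "INL",
    "OPL",
    "ONL+OLM+HFL",
    "ISL",
    "CL",
    "OSL",
    "VM",
    "RPE/BM",
)

N_LAYERS = len(LAYER_NAMES)
N_SURFACES = N_LAYERS + 1

_EYE_SIDES = ("OD", "OS")


@dataclass(frozen=True)
class SubjectMeta:
    """Optional per-subject covariates attached to a volume."""

    age: Optional[float] = None
    sex: Optional[str] = None  # "M" or "F"

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class Volume:
    """A 3D OCT intensity volume in the package's axis convention.

    Parameters
    ----------
    intensities
        3D float array indexed ``(x, y, z)`` with values in ``[0, 1]``.
    spacing_um
        Voxel spacing in micrometres along ``(x, y, z)``.
    eye_side
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    subject_meta
        Optional age/sex covariates.
    """

    intensities: np.ndarray
    spacing_um: tuple[float, float, float]
    eye_side: str = "OD"
    subject_meta: Optional[SubjectMeta] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"volume must be 3D, got ndim={self.intensities.ndim}"
            )
        if any(d < 2 for d in self.intensities.shape):
            raise ValidationError(
                f"every axis needs >= 2 voxels, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("volume contains non-finite intensities")
        lo, hi = float(self.intensities.min()), float(self.intensities.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"intensities must lie in [0, 1], got range [{lo}, {hi}]"
            )
        self.spacing_um = tuple(float(s) for s in self.spacing_um)  # type: ignore[assignment]
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValidationError(
                f"spacing_um must be 3 positive reals, got {self.spacing_um}"
            )
        if self.eye_side not in _EYE_SIDES:
            raise ValidationError(f"eye_side must be OD or OS, got {self.eye_side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class SurfaceSet:
    """Twelve ordered depth maps bounding the 11 retinal layers.

    ``depths`` has shape ``(12, nx, nz)`` and holds axial positions in voxel
    units; surface ``s`` is the upper boundary of layer ``s`` (0-based), and
    surface 11 is the lower boundary of the RPE/BM.  Surfaces never cross:
    ``depths[s] <= depths[s + 1]`` everywhere.
    """

    depths: np.ndarray
    layer_names: Sequence[str] = LAYER_NAMES

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.depths.ndim != 3 or self.depths.shape[0] != N_SURFACES:
            raise ValidationError(
                f"depths must have shape (12, nx, nz), got {self.depths.shape}"
            )
        if len(self.layer_names) != N_LAYERS:
            raise ValidationError(
                f"expected {N_LAYERS} layer names, got {len(self.layer_names)}"
            )
        if not np.all(np.isfinite(self.depths)):
            raise ValidationError("surface depths contain non-finite values")
        if self.depths.min() < 0:
            raise ValidationError("surface depths must be >= 0")
        gaps = np.diff(self.depths, axis=0)
        if gaps.min() < 0:
            s = int(np.argwhere(gaps.min(axis=(1, 2)) < 0)[0][0])
            raise ValidationError(
                f"surface ordering violated: surface {s} crosses surface {s + 1}"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.depths.shape[1], self.depths.shape[2]


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.name.split(".")[0] + ".json")


def _load_sidecar(path: Path, metadata_path: Optional[Path]) -> dict:
    candidate = Path(metadata_path) if metadata_path else _sidecar_path(path)
    if not candidate.exists():
        raise ConfigurationError(
            f"no metadata sidecar found for {path} (looked for {candidate}); "
            "voxel spacing must be supplied, it is never guessed"
        )
    with open(candidate) as fh:
        return json.load(fh)


def _normalize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateInputError("constant image: max equals min, cannot normalise")
    return (arr - lo) / (hi - lo)


def read_volume(path, metadata_path=None) -> Volume:
    """Read a volume from TIFF, NIfTI or raw float32 + JSON sidecar.

    Intensities are min–max normalised to ``[0, 1]`` and axes permuted into
    the ``(x, y-axial, z)`` convention.  A JSON sidecar (``<stem>.json`` next
    to the file, or ``metadata_path``) must supply ``spacing_um``; it may also
    carry ``eye_side``, ``age``, ``sex`` and — for raw input — ``shape``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")

    name = path.name.lower()
    meta = _load_sidecar(path, metadata_path)
    if "spacing_um" not in meta:
        raise ConfigurationError(f"sidecar for {path} lacks required 'spacing_um'")

    if name.endswith((".tif", ".tiff")):
        import tifffile

        try:
            pages = tifffile.imread(path)  # (z, y, x)
        except Exception as exc:  # pragma: no cover - tifffile error text varies
            raise FormatError(f"could not read TIFF {path}: {exc}") from exc
        if pages.ndim != 3:
            raise FormatError(f"TIFF {path} is not a 3D stack (ndim={pages.ndim})")
        arr = np.transpose(pages, (2, 1, 0))
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise FormatError(f"could not read NIfTI {path}: {exc}") from exc
        arr = np.asarray(img.get_fdata())  # stored (x, y, z)
        if arr.ndim != 3:
            raise FormatError(f"NIfTI {path} is not 3D (ndim={arr.ndim})")
    elif name.endswith((".raw", ".bin")):
        if "shape" not in meta:
            raise ConfigurationError(f"raw volume {path} needs 'shape' in its sidecar")
        shape = tuple(int(s) for s in meta["shape"])
        data = np.fromfile(path, dtype=np.float32)
        if data.size != int(np.prod(shape)):
            raise FormatError(
                f"raw file {path} has {data.size} values, sidecar shape "
                f"{shape} needs {int(np.prod(shape))}"
            )
        arr = data.reshape(shape)  # stored (x, y, z)
    elif name.endswith(".npy"):
        arr = np.load(path)
        if arr.ndim != 3:
            raise FormatError(f"{path} is not a 3D array")
    else:
        raise FormatError(f"unsupported volume format: {path}")

    subject_meta = None
    if "age" in meta or "sex" in meta:
        subject_meta = SubjectMeta(age=meta.get("age"), sex=meta.get("sex"))

    return Volume(
        intensities=_normalize(arr),
        spacing_um=tuple(meta["spacing_um"]),
        eye_side=meta.get("eye_side", "OD"),
        subject_meta=subject_meta,
    )


def write_volume(volume: Volume, path) -> None:
    """Write a volume plus JSON sidecar; inverse of :func:`read_volume`.

    TIFF output is float32 multi-page with pages as B-scans; raw output is
    little-endian float32 in ``(x, y, z)`` order.
    """
    path = Path(path)
    name = path.name.lower()
    meta = {
        "spacing_um": list(volume.spacing_um),
        "eye_side": volume.eye_side,
        "shape": list(volume.shape),
    }
    if volume.subject_meta is not None:
        if volume.subject_meta.age is not None:
            meta["age"] = volume.subject_meta.age
        if volume.subject_meta.sex is not None:
            meta["sex"] = volume.subject_meta.sex

    if name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(
            path,
            np.transpose(volume.intensities, (2, 1, 0)).astype(np.float32),
            photometric="minisblack",
        )
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing_um) + [1.0])
        nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), str(path))
    elif name.endswith((".raw", ".bin")):
        volume.intensities.astype(np.float32).tofile(path)
    else:
        raise FormatError(f"unsupported output format: {path}")

    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Surface I/O
# ---------------------------------------------------------------------------


def write_surfaces(surfaces: SurfaceSet, path) -> None:
    """Write surfaces as long-form TSV plus a JSON header with layer names.

    TSV columns: ``surface_index``, ``x``, ``z``, ``depth_voxels``.  The JSON
    header (``<path stem>.json``) records layer names and grid shape.
    """
    path = Path(path)
    n_s, nx, nz = surfaces.depths.shape
    s_idx, x_idx, z_idx = np.meshgrid(
        np.arange(n_s), np.arange(nx), np.arange(nz), indexing="ij"
    )
    with open(path, "w") as fh:
        fh.write("surface_index\tx\tz\tdepth_voxels\n")
        for s, x, z, d in zip(
            s_idx.ravel(), x_idx.ravel(), z_idx.ravel(), surfaces.depths.ravel()
        ):
            fh.write(f"{s}\t{x}\t{z}\t{d:.6f}\n")
    header = {"layer_names": list(surfaces.layer_names), "grid_shape": [nx, nz]}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=1)


def read_surfaces(path) -> SurfaceSet:
    """Exact inverse of :func:`write_surfaces`; validates surface ordering."""
    path = Path(path)
    header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise FormatError(f"surface header not found: {header_path}")
    with open(header_path) as fh:
        header = json.load(fh)
    nx, nz = header["grid_shape"]
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.shape[0] != N_SURFACES * nx * nz:
        raise FormatError(
            f"surface TSV {path} has {data.shape[0]} rows, "
            f"expected {N_SURFACES * nx * nz}"
        )
    depths = np.full((N_SURFACES, nx, nz), np.nan)
    s = data[:, 0].astype(int)
    x = data[:, 1].astype(int)
    z = data[:, 2].astype(int)
    depths[s, x, z] = data[:, 3]
    return SurfaceSet(depths=depths, layer_names=header["layer_names"])


# ---------------------------------------------------------------------------
# Thickness-map output
# ---------------------------------------------------------------------------


def write_thickness_outputs(maps, out_dir) -> None:
    """Write per-layer CSV grids (µm), pseudo-colour PNGs and the total map.

    ``maps`` is a :class:`retidiff.thickness.ThicknessMaps`.  Produces, per
    layer ``L``, ``layer_<L>_<name>.csv`` / ``.png``, plus ``total.csv`` /
    ``total.png``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_maps = list(maps.per_layer) + [maps.total]
    for m in all_maps:
        if not np.all(np.isfinite(m)):
            raise ValidationError("thickness map contains non-finite values")
        if np.asarray(m).min() < 0:
            raise ValidationError("negative thickness encountered")

    def _write_one(grid: np.ndarray, stem: str, title: str) -> None:
        np.savetxt(out_dir / f"{stem}.csv", grid, delimiter=",", fmt="%.4f")
        fig, ax = plt.subplots(figsize=(4, 3))
        im = ax.imshow(grid.T, cmap="turbo", origin="upper", aspect="auto")
        ax.set_xlabel("x (lateral)")
        ax.set_ylabel("z (B-scan)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="thickness (µm)")
        fig.tight_layout()
        fig.savefig(out_dir / f"{stem}.png", dpi=100)
        plt.close(fig)

    for i, (grid, name) in enumerate(zip(maps.per_layer, maps.layer_names), start=1):
        safe = name.replace("/", "-").replace("+", "_")
        _write_one(np.asarray(grid), f"layer_{i:02d}_{safe}", name)
    _write_one(np.asarray(maps.total), "total", "total retina")
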