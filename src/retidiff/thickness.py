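"""Per-layer and total thickness maps in micrometres; foveal-centre location.

Layer ``L``'s thickness at a column is the axial gap between its bounding
surfaces scaled by the axial voxel spacing; the total retinal thickness is
the sum of the 11 layer maps (an exact identity, preserved by construction).
The foveal centre is the minimum of the smoothed nerve-fiber-layer map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io_volume import LAYER_NAMES, N_LAYERS, SurfaceSet

__all__ = ["ThicknessMaps", "compute_thickness_maps", "locate_fovea"]


@dataclass
class ThicknessMaps:
    """Eleven per-layer thickness grids (µm) plus their exact sum."""

    per_layer: np.ndarray  # (11, nx, nz), µm
    total: np.ndarray  # (nx, nz), µm
    layer_names: Sequence[str] = LAYER_NAMES
    lateral_spacing_um: Optional[tuple[float, float]] = None  # (x, z)

    def __post_init__(self) -> None:
        self.per_layer = np.asarray(self.per_layer, dtype=np.float64)
        self.total = np.asarray(self.total, dtype=np.float64)
        if self.per_layer.ndim != 3 or self.per_layer.shape[0] != N_LAYERS:
            raise ValidationError(
                f"per_layer must have shape (11, nx, nz), got {self.per_layer.shape}"
            )
        if self.total.shape != self.per_layer.shape[1:]:
            raise ValidationError("total grid must match per-layer grid shape")
        if self.per_layer.min() < 0:
            raise ValidationError("layer thickness must be nonnegative")

    def layer(self, name: str) -> np.ndarray:
        """Thickness grid of a layer by anatomical name (e.g. ``"NFL"``)."""
        try:
            i = list(self.layer_names).index(name)
        except ValueError:
            raise KeyError(f"unknown layer {name!r}") from None
        return self.per_layer[i]


def compute_thickness_maps(
    surfaces: SurfaceSet,
    axial_spacing_um: float,
    lateral_spacing_um: Optional[tuple[float, float]] = None,
) -> ThicknessMaps:
    """Thickness of layer ``L`` = (depth[L+1] − depth[L]) × axial spacing.

    The total map is formed by summing the 11 layer maps, so the identity
    ``total == per_layer.sum(axis=0)`` holds exactly.
    """
    if axial_spacing_um <= 0:
        raise ValidationError("axial spacing must be positive")
    gaps = np.diff(surfaces.depths, axis=0)  # (11, nx, nz), >= 0 by invariant
    if gaps.min() < -1e-12:
        raise ValidationError("internal error: negative surface gap")
    per_layer = np.clip(gaps, 0, None) * float(axial_spacing_um)
    total = per_layer.sum(axis=0)
    return ThicknessMaps(
        per_layer=per_layer,
        total=total,
        layer_names=surfaces.layer_names,
        lateral_spacing_um=lateral_spacing_um,
    )


def locate_fovea(rnfl_map: np.ndarray, smooth_window: int = 5) -> tuple[int, int]:
    """Foveal centre: argmin of the mean-filtered nerve-fiber-layer map.

    Ties are broken by proximity to the grid centre, then lexicographically;
    an all-equal map therefore returns the grid centre.
    """
    grid = np.asarray(rnfl_map, dtype=np.float64)
    if grid.ndim != 2:
        raise ValidationError("RNFL map must be 2D")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValidationError("smooth_window must be a positive odd integer")
    if min(grid.shape) < smooth_window:
        raise ValidationError(
            f"grid {grid.shape} smaller than smoothing window {smooth_window}"
        )
    smoothed = ndimage.uniform_filter(grid, size=smooth_window, mode="nearest")
    minval = smoothed.min()
    candidates = np.argwhere(smoothed == minval)
    centre = (np.array(grid.shape) - 1) / 2.0
    d2 = np.sum((candidates - centre) ** 2, axis=1)
    best = candidates[d2 == d2.min()]
    # lexicographic tie-break among equally central candidates
    best = best[np.lexsort((best[:, 1], best[:, 0]))][0]
    return int(best[0]), int(best[1])
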