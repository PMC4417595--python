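"""ETDRS 9-sector grid, per-sector thickness summaries, and cohort statistics.

The ETDRS grid partitions the macula into three concentric circles (default
diameters 1 / 3 / 6 mm) centred on the fovea.  Sector 1 is the central
foveal disk; the parafoveal ring splits into superior (2), nasal (3),
inferior (4) and temporal (5) quadrants along the ±45° diagonals, and the
perifoveal ring likewise into sectors 6–9.  Nasal/temporal labels mirror
between right (OD) and left (OS) eyes: sectors 3↔5 and 7↔9 swap.

Cohort statistics follow the normative-mapping conventions: unpaired
two-sample t-tests (pooled variance) for sex differences, one-way ANOVA F
tests across sectors, and the t-test on the slope of a simple linear
regression for age associations.  No multiplicity correction is applied by
default; Bonferroni is available as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .thickness import ThicknessMaps

__all__ = [
    "SectorMap",
    "StatResult",
    "sector_grid",
    "mirror_sectors",
    "sector_stats",
    "layer_sector_table",
    "unpaired_t_test",
    "anova_f",
    "slope_test",
    "cohort_report",
]

@dataclass
class SectorMap:
    """Integer sector labels 0–9 on an (x, z) grid (0 = outside the grid)."""

    labels: np.ndarray  # (nx, nz) int
    center: tuple[float, float]
    diameters_mm: tuple[float, float, float]
    eye_side: str
    partial: bool = False  # outer circle clipped by the grid

    def __post_init__(self) -> None:
        if self.eye_side not in ("OD", "OS"):
            raise ValidationError(f"eye_side must be OD or OS, got {self.eye_side!r}")
        if not (0 < self.diameters_mm[0] < self.diameters_mm[1] < self.diameters_mm[2]):
            raise ValidationError("diameters must be strictly increasing and positive")


@dataclass
class StatResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    df: float
    effect: Optional[float] = None  # mean difference or slope
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of range: {self.p_value}")


def sector_grid(
    shape: tuple[int, int],
    center: tuple[float, float],
    lateral_spacing_um: tuple[float, float],
    eye_side: str,
    diameters_mm: tuple[float, float, float] = (1.0, 3.0, 6.0),
) -> SectorMap:
    """Build the ETDRS sector label grid around the foveal centre.

    ``shape`` and ``center`` are in (x, z) pixels; ``lateral_spacing_um``
    converts pixels to micrometres.  Ring boundaries are half-open with the
    inner edge included.  For OD the nasal direction is +x, for OS −x;
    superior is −z.  Pixels exactly on a 45° diagonal belong to the
    superior/inferior sectors.
    """
    nx, nz = shape
    cx, cz = center
    sx, sz = (float(s) for s in lateral_spacing_um)
    if sx <= 0 or sz <= 0:
        raise ValidationError("lateral spacing must be positive")
    if not (0 <= cx < nx and 0 <= cz < nz):
        raise ValidationError(f"center {center} outside grid {shape}")

    r0, r1, r2 = (1000.0 * d / 2.0 for d in diameters_mm)  # radii in µm

    dx = (np.arange(nx)[:, None] - cx) * sx
    dz = (np.arange(nz)[None, :] - cz) * sz
    dx, dz = np.broadcast_arrays(dx, dz)
    r = np.hypot(dx, dz)

    edge_um = min(cx * sx, (nx - 1 - cx) * sx, cz * sz, (nz - 1 - cz) * sz)
    partial = bool(r2 > edge_um)
    if partial:
        warnings.warn(
            "outer ETDRS circle exceeds the thickness-map extent; "
            "outer sectors are partial",
            stacklevel=2,
        )

    nasal_sign = 1.0 if eye_side == "OD" else -1.0
    u = dx * nasal_sign  # nasal positive
    v = dz  # superior negative

    quadrant = np.where(
        np.abs(v) >= np.abs(u),  # diagonal ties go superior/inferior
        np.where(v <= 0, 0, 1),  # 0 = superior, 1 = inferior
        np.where(u > 0, 2, 3),  # 2 = nasal, 3 = temporal
    )
    quadrant_sector = np.array(
        [
            [2, 4, 3, 5],  # parafoveal ring
            [6, 8, 7, 9],  # perifoveal ring
        ]
    )

    labels = np.zeros((nx, nz), dtype=np.int64)
    labels[r < r0] = 1
    ring1 = (r >= r0) & (r < r1)
    ring2 = (r >= r1) & (r < r2)
    labels[ring1] = quadrant_sector[0][quadrant[ring1]]
    labels[ring2] = quadrant_sector[1][quadrant[ring2]]

    return SectorMap(
        labels=labels,
        center=(float(cx), float(cz)),
        diameters_mm=tuple(float(d) for d in diameters_mm),
        eye_side=eye_side,
        partial=partial,
    )


def mirror_sectors(sectors: SectorMap) -> SectorMap:
    """Relabel for the fellow eye: swap 3↔5 and 7↔9, flip the eye side.

    Applying the operation twice returns the original map (involution).
    """
    labels = sectors.labels.copy()
    for a, b in ((3, 5), (7, 9)):
        ma, mb = labels == a, labels == b
        labels[ma], labels[mb] = b, a
    return replace(
        sectors,
        labels=labels,
        eye_side="OS" if sectors.eye_side == "OD" else "OD",
    )


def sector_stats(
    thickness_map: np.ndarray,
    sectors: SectorMap,
    exclude: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-sector mean and sample SD (n−1) of a thickness grid.

    Flagged pixels (``exclude`` True) are left out; empty sectors are simply
    absent from the result rather than reported as zero.
    """
    grid = np.asarray(thickness_map, dtype=np.float64)
    if grid.shape != sectors.labels.shape:
        raise ValidationError(
            f"map shape {grid.shape} != sector grid {sectors.labels.shape}"
        )
    valid = np.isfinite(grid)
    if exclude is not None:
        valid &= ~np.asarray(exclude, dtype=bool)
    rows = []
    for s in range(1, 10):
        sel = (sectors.labels == s) & valid
        n = int(sel.sum())
        if n == 0:
            continue
        vals = grid[sel]
        rows.append(
            {
                "sector": s,
                "mean_um": float(vals.mean()),
                "sd_um": float(vals.std(ddof=1)) if n > 1 else 0.0,
                "n_pixels": n,
            }
        )
    return pd.DataFrame(rows, columns=["sector", "mean_um", "sd_um", "n_pixels"])


def layer_sector_table(
    maps: ThicknessMaps,
    sectors: SectorMap,
    exclude: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Long-form per-(layer, sector) summary including the total map.

    Columns: ``layer`` (1–11 or ``"total"``), ``layer_name``, ``sector``,
    ``mean_um``, ``sd_um``, ``n_pixels``.
    """
    frames = []
    for i, name in enumerate(maps.layer_names, start=1):
        df = sector_stats(maps.per_layer[i - 1], sectors, exclude)
        df.insert(0, "layer_name", name)
        df.insert(0, "layer", i)
        frames.append(df)
    df = sector_stats(maps.total, sectors, exclude)
    df.insert(0, "layer_name", "total")
    df.insert(0, "layer", "total")
    frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def unpaired_t_test(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sample pooled-variance t-test, two-sided.

    Degenerate samples (zero pooled variance) resolve by convention: equal
    means give p = 1, unequal means p = 0, both flagged in ``note``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    df = a.size + b.size - 2
    effect = float(a.mean() - b.mean())
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if effect == 0.0:
            return StatResult(0.0, 1.0, df, effect, note="zero variance, equal means")
        return StatResult(
            float(np.inf) * np.sign(effect),
            0.0,
            df,
            effect,
            note="zero variance, unequal means",
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return StatResult(float(t), float(p), df, effect)


def anova_f(groups: Sequence[np.ndarray]) -> StatResult:
    """One-way ANOVA: F = between-group MS / within-group MS.

    For two groups, F equals the square of the pooled t statistic.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs at least 2 values")
    n_total = sum(g.size for g in groups)
    df = (len(groups) - 1, n_total - len(groups))
    if all(g.var(ddof=1) == 0.0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0.0:
            return StatResult(0.0, 1.0, df[1], note="zero variance everywhere")
        return StatResult(float(np.inf), 0.0, df[1], note="zero within-group variance")
    f, p = stats.f_oneway(*groups)
    return StatResult(float(f), float(p), df[1], note=f"df=({df[0]}, {df[1]})")


def slope_test(x: np.ndarray, y: np.ndarray) -> StatResult:
    """t-test on the slope of the least-squares regression of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples of length >= 3")
    if np.ptp(x) == 0.0:
        raise ValidationError("x is constant: slope undefined")
    df = x.size - 2
    if np.ptp(y) == 0.0:
        return StatResult(0.0, 1.0, df, 0.0, note="constant response")
    res = stats.linregress(x, y)
    if res.stderr == 0.0 or not np.isfinite(res.stderr):
        # perfect fit (or constant y): slope 0 gives p = 1, otherwise p -> 0
        p = 1.0 if res.slope == 0.0 else 0.0
        t = 0.0 if res.slope == 0.0 else float(np.inf) * np.sign(res.slope)
        return StatResult(t, p, df, float(res.slope), note="zero residual variance")
    t = res.slope / res.stderr
    return StatResult(float(t), float(res.pvalue), df, float(res.slope))


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------


def cohort_report(
    subjects: Sequence[tuple[pd.DataFrame, float, str, str]],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Sex and age associations per (layer, sector) across a cohort.

    ``subjects`` holds, per subject, a long-form sector table (as produced by
    :func:`layer_sector_table`), age in years, sex (``"M"``/``"F"``) and eye
    side.  For every (layer, sector) cell the report carries the male−female
    pooled t-test and the age-slope test; with ``bonferroni`` the p-values
    are multiplied by the number of cells (capped at 1).  A single-sex cohort
    skips the sex comparison with a notice.
    """
    if len(subjects) < 3:
        raise ValidationError("cohort_report needs at least 3 subjects")
    records = []
    for k, (table, age, sex, eye_side) in enumerate(subjects):
        t = table.copy()
        t["subject"] = k
        t["age"] = age
        t["sex"] = sex
        records.append(t[["subject", "layer", "sector", "mean_um", "age", "sex"]])
    long = pd.concat(records, ignore_index=True)

    sexes = set(long["sex"])
    single_sex = len(sexes) < 2
    if single_sex:
        warnings.warn("single-sex cohort: sex comparisons skipped", stacklevel=2)

    rows = []
    for (layer, sector), cell in long.groupby(["layer", "sector"], sort=False):
        row: dict = {"layer": layer, "sector": sector, "n_subjects": len(cell)}
        if not single_sex:
            m = cell.loc[cell["sex"] == "M", "mean_um"].to_numpy()
            f = cell.loc[cell["sex"] == "F", "mean_um"].to_numpy()
            if m.size >= 2 and f.size >= 2:
                res = unpaired_t_test(m, f)
                row.update(
                    sex_t=res.statistic,
                    sex_p=res.p_value,
                    sex_effect_um=res.effect,
                )
        if cell["age"].nunique() >= 3:
            res = slope_test(cell["age"].to_numpy(), cell["mean_um"].to_numpy())
            row.update(
                age_slope_um_per_year=res.effect,
                age_t=res.statistic,
                age_p=res.p_value,
            )
        rows.append(row)
    report = pd.DataFrame(rows)
    if bonferroni:
        n_cells = len(report)
        for col in ("sex_p", "age_p"):
            if col in report:
                report[col] = np.minimum(report[col] * n_cells, 1.0)
    return report
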