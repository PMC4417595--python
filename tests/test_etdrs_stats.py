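"""ETDRS sector geometry, per-sector summaries, and the cohort statistics.

The hypothesis tests are checked against brute-force evaluations of the
textbook formulas (pooled t, one-way ANOVA decomposition, normal equations),
written here independently of the implementation path.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retidiff.errors import ValidationError
from retidiff.etdrs_stats import (
    SectorMap,
    anova_f,
    cohort_report,
    layer_sector_table,
    mirror_sectors,
    sector_grid,
    sector_stats,
    slope_test,
    unpaired_t_test,
)
from retidiff.thickness import ThicknessMaps

# 121×121 px at 50 µm/px: centre 60,60; 1 mm = 20 px
GRID_KW = dict(
    shape=(121, 121),
    center=(60.0, 60.0),
    lateral_spacing_um=(50.0, 50.0),
)


class TestSectorGeometry:
    def test_centre_pixel_is_sector_one(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        assert sm.labels[60, 60] == 1

    def test_one_mm_nasal_is_sector_three_od(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        assert sm.labels[60 + 20, 60] == 3  # 1 mm along +x (nasal for OD)

    def test_same_pixel_is_sector_five_os(self):
        sm = sector_grid(eye_side="OS", **GRID_KW)
        assert sm.labels[60 + 20, 60] == 5

    def test_perifoveal_nasal_and_superior(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        assert sm.labels[60 + 40, 60] == 7  # 2 mm nasal -> perifoveal
        assert sm.labels[60, 60 - 20] == 2  # 1 mm superior (-z)
        assert sm.labels[60, 60 - 40] == 6
        assert sm.labels[60, 60 + 20] == 4  # inferior
        assert sm.labels[60 - 20, 60] == 5  # temporal for OD

    def test_ring_boundaries_inner_inclusive(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        assert sm.labels[60 + 10, 60] != 1  # exactly 0.5 mm -> parafoveal ring
        assert sm.labels[60 + 30, 60] in (6, 7, 8, 9)  # exactly 1.5 mm -> perifoveal
        assert sm.labels[60 + 60, 60] == 0  # exactly 3.0 mm -> outside

    def test_diagonal_ties_go_superior_inferior(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        assert sm.labels[60 + 15, 60 - 15] == 2  # 45° up-nasal -> superior
        assert sm.labels[60 + 15, 60 + 15] == 4  # 45° down-nasal -> inferior

    def test_disk_partition_complete_and_exclusive(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        x = (np.arange(121)[:, None] - 60) * 50.0
        z = (np.arange(121)[None, :] - 60) * 50.0
        r = np.hypot(x, z)
        inside = r < 3000.0
        assert np.array_equal(inside, sm.labels > 0)
        assert set(np.unique(sm.labels[inside])) == set(range(1, 10))

    def test_mirroring_is_involution_and_swaps_nasal_temporal(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        mirrored = mirror_sectors(sm)
        assert mirrored.eye_side == "OS"
        assert mirrored.labels[60 + 20, 60] == 5
        assert mirrored.labels[60 + 40, 60] == 9
        back = mirror_sectors(mirrored)
        assert back.eye_side == "OD"
        np.testing.assert_array_equal(back.labels, sm.labels)

    def test_outer_circle_clipping_flagged(self):
        with pytest.warns(UserWarning, match="partial"):
            sm = sector_grid(
                shape=(41, 41), center=(20, 20), lateral_spacing_um=(50, 50),
                eye_side="OD",
            )
        assert sm.partial


class TestSectorStats:
    def test_constant_map_means_and_zero_sd(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        table = sector_stats(np.full((121, 121), 100.0), sm)
        assert len(table) == 9
        np.testing.assert_array_equal(table["mean_um"], 100.0)
        np.testing.assert_array_equal(table["sd_um"], 0.0)

    def test_two_value_sector_sample_sd(self):
        # degenerate two-pixel grid with a hand-made sector map
        sm = SectorMap(
            labels=np.array([[1, 1], [0, 0]]),
            center=(0.0, 0.0),
            diameters_mm=(1, 3, 6),
            eye_side="OD",
        )
        table = sector_stats(np.array([[10.0, 20.0], [0, 0]]), sm)
        row = table.iloc[0]
        assert row["mean_um"] == 15.0
        assert row["sd_um"] == pytest.approx(np.std([10, 20], ddof=1))
        assert row["n_pixels"] == 2

    def test_flagged_pixels_excluded(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        grid = np.full((121, 121), 50.0)
        flag = np.zeros_like(grid, bool)
        flag[sm.labels == 2] = True
        flag[60, 60 - 25] = False  # keep one pixel of sector 2
        table = sector_stats(grid, sm, exclude=flag).set_index("sector")
        assert table.loc[2, "n_pixels"] == 1

    def test_empty_sector_absent_not_zero(self):
        sm = SectorMap(
            labels=np.array([[1, 1], [3, 3]]),
            center=(0.0, 0.0),
            diameters_mm=(1, 3, 6),
            eye_side="OD",
        )
        table = sector_stats(np.full((2, 2), 5.0), sm)
        assert set(table["sector"]) == {1, 3}

    def test_layer_table_covers_all_layers_and_total(self):
        sm = sector_grid(eye_side="OD", **GRID_KW)
        per_layer = np.tile(np.arange(1.0, 12.0)[:, None, None], (1, 121, 121))
        maps = ThicknessMaps(per_layer=per_layer, total=per_layer.sum(axis=0))
        table = layer_sector_table(maps, sm)
        assert len(table) == 12 * 9
        total_rows = table[table["layer"] == "total"]
        np.testing.assert_allclose(total_rows["mean_um"], 66.0)


def _pooled_t_bruteforce(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def _anova_bruteforce(groups):
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, stats.f.sf(f, df1, df2)


def _slope_bruteforce(x, y):
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    beta = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    resid = y - (y.mean() + beta * (x - x.mean()))
    se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
    t = beta / se
    return beta, t, 2 * stats.t.sf(abs(t), n - 2)


class TestHypothesisTests:
    def test_t_matches_bruteforce(self, rng):
        a = rng.normal(0, 1, 13)
        b = rng.normal(0.4, 1.3, 19)
        res = unpaired_t_test(a, b)
        t, p = _pooled_t_bruteforce(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == 30

    def test_t_on_small_fixture(self):
        res = unpaired_t_test([1.0, 2, 3], [4.0, 5, 6])
        t, p = _pooled_t_bruteforce(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_t_identical_samples(self):
        res = unpaired_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_t_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=9)
        r1, r2 = unpaired_t_test(a, b), unpaired_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_t_degenerate_zero_variance(self):
        res = unpaired_t_test([2.0, 2, 2], [5.0, 5, 5])
        assert res.p_value == 0.0 and res.note is not None
        res = unpaired_t_test([2.0, 2, 2], [2.0, 2, 2])
        assert res.p_value == 1.0

    def test_anova_matches_bruteforce(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in [(0, 8), (0.5, 12), (1.0, 6)]]
        res = anova_f(groups)
        f, p = _anova_bruteforce(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_anova_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.3, 1, 14)
        f = anova_f([a, b]).statistic
        t = unpaired_t_test(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_anova_unequal_sizes_near_equal_means_finite(self):
        res = anova_f([[1.0, 2, 3], [1.4, 2.5], [2.0, 2.1, 2.0, 2.2]])
        assert np.isfinite(res.statistic)
        assert 0 < res.p_value <= 1

    def test_slope_matches_bruteforce(self, rng):
        x = rng.uniform(0, 10, 25)
        y = 1.5 * x + rng.normal(0, 2, 25)
        res = slope_test(x, y)
        beta, t, p = _slope_bruteforce(x, y)
        assert res.effect == pytest.approx(beta, abs=1e-10)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_slope_constant_y(self):
        res = slope_test(np.arange(5.0), np.full(5, 3.0))
        assert res.effect == 0.0
        assert res.p_value == 1.0

    def test_slope_perfect_fit(self):
        res = slope_test(np.arange(10.0), 2 * np.arange(10.0))
        assert res.effect == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_slope_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            slope_test(np.full(5, 1.0), np.arange(5.0))

    def test_anova_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            if anova_f(groups).p_value < 0.05:
                hits += 1
        rate = hits / n_sim
        assert 0.03 <= rate <= 0.075  # 99% binomial band at n=400


def _synthetic_cohort(rng, n=60, slope=-0.3, sex_offset=8.0, noise=5.0):
    subjects = []
    for k in range(n):
        age = rng.uniform(20, 80)
        sex = "M" if k % 2 == 0 else "F"
        rows = []
        for sector in range(1, 10):
            mean = 300 + slope * age + (sex_offset if sex == "M" else 0.0)
            mean += rng.normal(0, noise)
            rows.append({"layer": "total", "sector": sector, "mean_um": mean})
        subjects.append((pd.DataFrame(rows), age, sex, "OD"))
    return subjects


class TestCohortReport:
    def test_programmed_age_slope_recovered(self, rng):
        report = cohort_report(_synthetic_cohort(rng))
        total = report[report["layer"] == "total"]
        assert (total["age_slope_um_per_year"] < 0).all()
        assert (total["age_p"] < 0.05).all()
        # point estimates near the programmed -0.3
        assert total["age_slope_um_per_year"].mean() == pytest.approx(-0.3, abs=0.1)

    def test_programmed_sex_offset_detected(self, rng):
        report = cohort_report(_synthetic_cohort(rng))
        assert (report["sex_effect_um"] > 0).all()
        assert (report["sex_p"] < 0.05).all()

    def test_null_cohort_false_positive_rate(self, rng):
        subjects = _synthetic_cohort(rng, n=40, slope=0.0, sex_offset=0.0, noise=10.0)
        report = cohort_report(subjects)
        rate = (report["age_p"] < 0.05).mean()
        assert rate <= 0.35  # 9 correlated cells; just no systematic rejection

    def test_single_sex_cohort_skips_sex_tests(self, rng):
        subjects = [
            (tab, age, "F", eye)
            for tab, age, _, eye in _synthetic_cohort(rng, n=10)
        ]
        with pytest.warns(UserWarning, match="single-sex"):
            report = cohort_report(subjects)
        assert "sex_p" not in report.columns

    def test_bonferroni_inflates_p(self, rng):
        subjects = _synthetic_cohort(rng, n=20, noise=30.0)
        raw = cohort_report(subjects)
        adj = cohort_report(subjects, bonferroni=True)
        assert (adj["age_p"] >= raw["age_p"] - 1e-15).all()

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError):
            cohort_report(_synthetic_cohort(rng, n=2))
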