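"""Volumetry, thickness, signal, reliability and group statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbmpipe.core import GridSpec, ImageVolume, LabelVolume
from tbmpipe.morphometry import (
    _thickness_from_mask,
    cortical_thickness,
    group_compare,
    rater_reliability,
    relative_signal,
    roi_volume,
    sidak_adjust,
    stats_to_frame,
    two_way_anova,
    whole_brain_volume,
    compute_roi_stats,
)
from tbmpipe.phantom import default_tissue_params, perturb_segmentation, simulate_t2_image


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------


def _labels_with_counts(counts: dict[int, int], grid: GridSpec) -> LabelVolume:
    """Flat label array with exact voxel counts per id."""
    data = np.zeros(int(np.prod(grid.shape)), dtype=np.int16)
    pos = 0
    for lid, n in counts.items():
        data[pos : pos + n] = lid
        pos += n
    dictionary = {0: "background", **{lid: f"r{lid}" for lid in counts}}
    return LabelVolume(data.reshape(grid.shape), grid, dictionary)


class TestRoiVolume:
    def test_empty_region_is_zero(self):
        grid = GridSpec(shape=(8, 8, 8))
        lab = LabelVolume(np.zeros(grid.shape, np.int16), grid, {0: "background", 1: "roi"})
        assert roi_volume(lab, "roi") == 0.0

    def test_100_voxels_at_paper_spacing(self):
        # 100 x 0.175 x 0.175 x 0.5 = 1.53125 mm^3
        grid = GridSpec(shape=(10, 10, 10), spacing=(0.175, 0.175, 0.5))
        lab = _labels_with_counts({1: 100}, grid)
        assert roi_volume(lab, "r1") == pytest.approx(1.53125, abs=1e-12)

    def test_additive_over_disjoint_regions(self):
        grid = GridSpec(shape=(10, 10, 10))
        lab = _labels_with_counts({1: 123, 2: 77}, grid)
        merged = LabelVolume(
            np.where(lab.labels == 2, 1, lab.labels), grid, {0: "background", 1: "r1"}
        )
        assert roi_volume(merged, "r1") == pytest.approx(
            roi_volume(lab, "r1") + roi_volume(lab, "r2")
        )

    def test_axis_permutation_invariance(self):
        grid = GridSpec(shape=(10, 12, 14), spacing=(0.2, 0.3, 0.5))
        rng = np.random.default_rng(0)
        arr = (rng.random(grid.shape) < 0.2).astype(np.int16)
        lab = LabelVolume(arr, grid, {0: "background", 1: "roi"})
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            pg = GridSpec(
                shape=tuple(grid.shape[i] for i in perm),
                spacing=tuple(grid.spacing[i] for i in perm),
            )
            plab = LabelVolume(np.transpose(arr, perm), pg, {0: "background", 1: "roi"})
            assert roi_volume(plab, "roi") == pytest.approx(roi_volume(lab, "roi"))

    def test_unknown_region_raises(self):
        grid = GridSpec(shape=(8, 8, 8))
        lab = _labels_with_counts({1: 5}, grid)
        with pytest.raises(KeyError):
            roi_volume(lab, "nope")

    def test_whole_brain_excludes_skull_and_background(self, atlas):
        total = sum(
            atlas.voxel_count(n) for n in atlas.names if n not in ("background", "skull")
        )
        assert whole_brain_volume(atlas) == pytest.approx(total * atlas.grid.voxel_volume)


# --------------------------------------------------------------------------
# cortical thickness
# --------------------------------------------------------------------------


class TestCorticalThickness:
    def test_spherical_shell_one_mm(self):
        # analytic thickness 1 mm (inner r 4, outer r 5), tolerance one voxel
        grid = GridSpec(shape=(64, 64, 64), spacing=(0.175, 0.175, 0.175))
        c = grid.center_mm
        xs, ys, zs = grid.world_coordinates()
        r = np.sqrt((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2)
        shell = (r >= 4) & (r <= 5)
        samples = _thickness_from_mask(shell, grid.spacing)
        assert len(samples) == 5
        for t in samples:
            assert abs(t - 1.0) <= 0.175

    def test_single_voxel_sheet(self):
        grid = GridSpec(shape=(32, 32, 16))
        mask = np.zeros(grid.shape, bool)
        mask[16, 4:28, 4:12] = True  # one voxel thick along x (0.175 mm)
        samples = _thickness_from_mask(mask, grid.spacing)
        assert np.allclose(samples, 0.175, atol=1e-9)

    def test_scaling_scales_thickness(self):
        grid = GridSpec(shape=(48, 48, 48), spacing=(0.175,) * 3)
        c = grid.center_mm
        xs, ys, zs = grid.world_coordinates()
        r = np.sqrt((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2)
        shell = (r >= 2.5) & (r <= 3.5)
        base = np.mean(_thickness_from_mask(shell, grid.spacing))
        scaled = np.mean(_thickness_from_mask(shell, tuple(s * 1.1 for s in grid.spacing)))
        assert scaled / base == pytest.approx(1.1, abs=0.03)

    def test_empty_ribbon_fails(self, atlas):
        lab = LabelVolume(
            np.zeros(atlas.grid.shape, np.int16), atlas.grid, dict(atlas.dictionary)
        )
        with pytest.raises(ValueError, match="empty"):
            cortical_thickness(lab, "ctx_motor_L")

    def test_atlas_ribbons_give_five_positive_samples(self, atlas):
        for region in ("ctx_motor_L", "ctx_parietal_R", "ctx_temporal_L"):
            samples = cortical_thickness(atlas, region)
            assert len(samples) == 5
            assert all(t > 0 for t in samples)


# --------------------------------------------------------------------------
# relative signal
# --------------------------------------------------------------------------


class TestRelativeSignal:
    def test_reference_vs_itself(self, atlas, t2_clean):
        assert relative_signal(t2_clean, atlas, "ctx_visual_ref") == pytest.approx(1.0)

    def test_scale_invariance(self, atlas, t2_clean):
        scaled = ImageVolume(t2_clean.data * 3.7, atlas.grid)
        assert relative_signal(scaled, atlas, "caudate_L") == pytest.approx(
            relative_signal(t2_clean, atlas, "caudate_L")
        )

    def test_analytic_echo_sum_ratio(self, atlas):
        # region T2 half the reference's; zero noise -> exact echo-sum ratio
        params = default_tissue_params(0.0)
        tissues = dict(params.tissues)
        tissues["caudate_L"] = (1.0, 40.0)
        tissues["ctx_visual_ref"] = (1.0, 80.0)
        from tbmpipe.phantom import TissueParams

        p = TissueParams(tissues=tissues, noise_sd=0.0)
        img = simulate_t2_image(atlas, p, seed=0)
        te = np.arange(10.0, 90.0, 10.0)
        expected = np.exp(-te / 40.0).sum() / np.exp(-te / 80.0).sum()
        assert relative_signal(img, atlas, "caudate_L") == pytest.approx(expected, rel=1e-12)

    def test_zero_reference_fails(self, atlas):
        img = ImageVolume(np.zeros(atlas.grid.shape), atlas.grid)
        with pytest.raises(ZeroDivisionError):
            relative_signal(img, atlas, "caudate_L")


# --------------------------------------------------------------------------
# rater reliability
# --------------------------------------------------------------------------


class TestRaterReliability:
    def test_identical_lists(self):
        assert rater_reliability([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_negated_lists(self):
        a = [1.0, 2.0, 5.0, 9.0]
        b = [-x + 11.0 for x in a]
        assert rater_reliability(a, b) == pytest.approx(-1.0)

    def test_zero_variance_fails(self):
        with pytest.raises(ValueError):
            rater_reliability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_perturbed_segmentation_reliability(self, atlas):
        # 0.1 mm rater emulation across 12 ROIs: r > 0.9 against originals
        rois = [
            "caudate_L", "caudate_R", "putamen_L", "putamen_R",
            "SN_L", "SN_R", "hippocampus_L", "hippocampus_R",
            "ctx_motor_L", "ctx_motor_R", "ventricles", "ctx_visual_ref",
        ]
        second = perturb_segmentation(atlas, 0.1, seed=9)
        a = [roi_volume(atlas, r) for r in rois]
        b = [roi_volume(second, r) for r in rois]
        assert rater_reliability(a, b) > 0.9


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------


def anova_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Independently coded balanced two-way ANOVA sums-of-squares
    decomposition (brute force over cell means)."""
    y = df["value"].to_numpy()
    groups = sorted(df["group"].unique())
    cells = sorted(df["cell"].unique())
    grand = y.mean()
    n_per = len(df) // (len(groups) * len(cells))
    ss_a = sum(
        len(df[df.group == g]) * (df[df.group == g]["value"].mean() - grand) ** 2
        for g in groups
    )
    ss_b = sum(
        len(df[df.cell == c]) * (df[df.cell == c]["value"].mean() - grand) ** 2
        for c in cells
    )
    ss_cells = 0.0
    ss_err = 0.0
    for g in groups:
        for c in cells:
            sub = df[(df.group == g) & (df.cell == c)]["value"].to_numpy()
            ss_cells += len(sub) * (sub.mean() - grand) ** 2
            ss_err += ((sub - sub.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(groups) - 1
    df_b = len(cells) - 1
    df_ab = df_a * df_b
    df_err = len(df) - len(groups) * len(cells)
    return {
        "F_group": (ss_a / df_a) / (ss_err / df_err),
        "F_cell": (ss_b / df_b) / (ss_err / df_err),
        "F_interaction": (ss_ab / df_ab) / (ss_err / df_err),
    }


def _balanced_table(rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g, gm in (("control", 0.0), ("mptp", 1.0)):
        for c, cm in (("L", 0.0), ("R", 0.4)):
            for i in range(5):
                rows.append(
                    dict(subject=f"{g}{i}", group=g, cell=c,
                         value=gm + cm + rng.normal(0, 1))
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(5):
            df = _balanced_table(rng)
            res = two_way_anova(df)
            oracle = anova_oracle(df)
            assert res["group"]["F"] == pytest.approx(oracle["F_group"], rel=1e-8)
            assert res["cell"]["F"] == pytest.approx(oracle["F_cell"], rel=1e-8)
            assert res["interaction"]["F"] == pytest.approx(oracle["F_interaction"], rel=1e-8)


class TestSidak:
    def test_formula(self):
        assert sidak_adjust(0.01, 4) == pytest.approx(1 - 0.99**4)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        ps = rng.uniform(0, 1, 50)
        for p in ps:
            prev = 0.0
            for m in (1, 2, 5, 10):
                adj = sidak_adjust(float(p), m)
                assert adj >= p - 1e-15
                assert adj >= prev - 1e-15
                prev = adj


def _tidy_from_values(control_vals, mptp_vals, family="caudate", measure="volume"):
    rows = []
    for i, v in enumerate(control_vals):
        for side, dv in (("L", 0.0), ("R", 0.0)):
            rows.append(dict(subject=f"c{i}", group="control", measure=measure,
                             family=family, cell=side, value=v + dv))
    for i, v in enumerate(mptp_vals):
        for side, dv in (("L", 0.0), ("R", 0.0)):
            rows.append(dict(subject=f"m{i}", group="mptp", measure=measure,
                             family=family, cell=side, value=v + dv))
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_groups_zero_difference(self):
        df = _tidy_from_values([1.0, 1.1, 0.9, 1.0], [1.0, 1.1, 0.9, 1.0])
        out = group_compare(df)
        row = out.iloc[0]
        assert row["percent_difference"] == pytest.approx(0.0, abs=1e-9)
        assert row["cohens_d"] == pytest.approx(0.0, abs=1e-9)

    def test_twelve_percent_decrease(self):
        # control mean 2.00, treated mean 1.76 -> -12.0 %
        df = _tidy_from_values([1.9, 2.0, 2.1, 2.0], [1.66, 1.76, 1.86, 1.76, 1.76, 1.76, 1.76])
        out = group_compare(df)
        assert out.iloc[0]["percent_difference"] == pytest.approx(-12.0, abs=1e-9)

    def test_single_cell_uses_t_test(self):
        rows = []
        rng = np.random.default_rng(4)
        for i in range(4):
            rows.append(dict(subject=f"c{i}", group="control", measure="volume",
                             family="skull", cell="all", value=11.3 + rng.normal(0, 0.1)))
        for i in range(7):
            rows.append(dict(subject=f"m{i}", group="mptp", measure="volume",
                             family="skull", cell="all", value=11.15 + rng.normal(0, 0.1)))
        out = group_compare(pd.DataFrame(rows))
        row = out.iloc[0]
        assert row["test"] == "independent_t"
        a = [r["value"] for r in rows if r["group"] == "control"]
        b = [r["value"] for r in rows if r["group"] == "mptp"]
        expected = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert row["p_value"] == pytest.approx(expected, rel=1e-12)

    def test_bilateral_uses_anova_with_sidak(self, rng):
        df = _balanced_table(rng)
        df["measure"] = "volume"
        df["family"] = "caudate"
        out = group_compare(df)
        row = out.iloc[0]
        assert row["test"] == "two_way_anova_group"
        assert set(row["sidak_by_cell"]) == {"L", "R"}
        for cell, adj in row["sidak_by_cell"].items():
            sub = df[df.cell == cell]
            raw = stats.ttest_ind(
                sub[sub.group == "control"]["value"],
                sub[sub.group == "mptp"]["value"],
                equal_var=True,
            ).pvalue
            assert adj == pytest.approx(1 - (1 - raw) ** 2, rel=1e-12)
            assert adj >= raw

    def test_small_group_rejected(self):
        df = _tidy_from_values([1.0], [1.0, 1.1, 0.9])
        with pytest.raises(ValueError):
            group_compare(df)


class TestComputeRoiStats:
    def test_thickness_only_on_cortical_ribbons(self, atlas, t2_clean):
        rows = compute_roi_stats("s0", t2_clean, atlas)
        by_region = {r.region: r for r in rows}
        assert by_region["ctx_motor_L"].thickness_mm is not None
        assert len(by_region["ctx_motor_L"].thickness_mm) == 5
        assert by_region["caudate_L"].thickness_mm is None
        assert by_region["ctx_visual_ref"].thickness_mm is None
        assert "whole_brain" in by_region

    def test_stats_to_frame_layout(self, atlas, t2_clean):
        rows = compute_roi_stats("s0", t2_clean, atlas) + compute_roi_stats(
            "s1", t2_clean, atlas
        )
        df = stats_to_frame(rows, {"s0": "control", "s1": "mptp"})
        assert set(df.columns) == {"subject", "group", "measure", "family", "cell", "value"}
        assert set(df[df.family == "caudate"].cell) == {"L", "R"}
        assert set(df[df.family == "skull"].cell) == {"all"}
        assert (df[df.measure == "thickness"].family.isin(
            ["ctx_motor", "ctx_parietal", "ctx_temporal"])).all()
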