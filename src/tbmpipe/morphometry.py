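"""ROI volumetry, cortical thickness, relative signal and group statistics.

Emulates a manual ROI workflow: slice-wise volumes (voxel count times voxel
volume), five systematic thickness measurements per cortical ribbon,
signal normalized to a visual-cortex reference patch, rater reliability as
Pearson r, and group comparisons (independent t for skull / whole brain,
two-way ANOVA group x side with Sidak post-hoc for bilateral measures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import ImageVolume, LabelVolume

__all__ = [
    "ROIStats",
    "roi_volume",
    "whole_brain_volume",
    "cortical_thickness",
    "relative_signal",
    "rater_reliability",
    "sidak_adjust",
    "two_way_anova",
    "compute_roi_stats",
    "group_compare",
    "BILATERAL_FAMILIES",
    "CORTICAL_FAMILIES",
]

#: bilateral deep-grey families entering the group x side ANOVA on volume
BILATERAL_FAMILIES = ("caudate", "putamen", "SN", "hippocampus")
#: cortical families entering the group x side ANOVA on mean thickness
CORTICAL_FAMILIES = ("ctx_motor", "ctx_parietal", "ctx_temporal")


@dataclass
class ROIStats:
    """Per-subject, per-region measurements."""

    subject_id: str
    region: str
    volume_mm3: float
    mean_signal: float
    relative_signal: float
    thickness_mm: tuple[float, ...] | None = None  # 5 samples, cortical only

    def __post_init__(self) -> None:
        if self.volume_mm3 < 0:
            raise ValueError("volume must be >= 0")
        if self.thickness_mm is not None:
            self.thickness_mm = tuple(float(t) for t in self.thickness_mm)
            if any(t <= 0 for t in self.thickness_mm):
                raise ValueError("thickness samples must be > 0")


def roi_volume(labels: LabelVolume, region: str) -> float:
    """ROI volume in mm^3: slice-wise (in-plane area x slice thickness),
    which equals voxel count x voxel volume."""
    return labels.voxel_count(region) * labels.grid.voxel_volume


def whole_brain_volume(labels: LabelVolume) -> float:
    """Everything inside the skull (all labels except background and skull)."""
    excluded = {labels.id_of("background"), labels.id_of("skull")}
    count = int(np.count_nonzero(~np.isin(labels.labels, list(excluded))))
    return count * labels.grid.voxel_volume


def _thickness_from_mask(mask: np.ndarray, spacing: Sequence[float], n_samples: int = 5) -> tuple[float, ...]:
    if not mask.any():
        raise ValueError("ribbon is empty")
    spacing = np.asarray(spacing, dtype=np.float64)
    edt, inds = ndimage.distance_transform_edt(
        mask, sampling=spacing, return_indices=True
    )

    coords_vox = np.argwhere(mask)
    coords_mm = coords_vox * spacing
    centered = coords_mm - coords_mm.mean(axis=0)
    # principal extent of the ribbon
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    proj = centered @ axis

    edges = np.linspace(proj.min(), proj.max(), n_samples + 1)
    samples: list[float] = []
    for b in range(n_samples):
        lo, hi = edges[b], edges[b + 1]
        sel = (proj >= lo) & (proj <= hi if b == n_samples - 1 else proj < hi)
        if not sel.any():
            raise ValueError("ribbon too sparse to place 5 systematic samples")
        sub = coords_vox[sel]
        d = edt[sub[:, 0], sub[:, 1], sub[:, 2]]
        k = int(np.argmax(d))
        vx = sub[k]
        # half-voxel correction along the direction to the nearest background
        nearest = inds[:, vx[0], vx[1], vx[2]]
        direction = (vx - nearest) * spacing
        norm = np.linalg.norm(direction)
        if norm > 0:
            unit = np.abs(direction) / norm
            h = float(unit @ spacing)
        else:
            h = float(spacing.min())
        samples.append(max(2.0 * float(d[k]) - h, float(spacing.min())))
    return tuple(samples)


def cortical_thickness(labels: LabelVolume, region: str, n_samples: int = 5) -> tuple[float, ...]:
    """Five systematic thickness measurements (mm) of a cortical ribbon.

    Thickness at a site = twice the Euclidean distance transform at the
    ribbon's medial voxel, with a half-voxel boundary correction; sites are
    the per-bin medial maxima of 5 even bins along the ribbon's principal
    extent.
    """
    mask = labels.mask(region)
    if not mask.any():
        raise ValueError(f"cortical ribbon {region!r} is empty")
    return _thickness_from_mask(mask, labels.grid.spacing, n_samples)


def relative_signal(image: ImageVolume, labels: LabelVolume, region: str) -> float:
    """Mean intensity in ``region`` divided by the visual-reference mean."""
    if not image.grid.matches(labels.grid):
        raise ValueError("image and labels must share a grid")
    ref_mask = labels.mask("ctx_visual_ref")
    roi_mask = labels.mask(region)
    if not ref_mask.any() or not roi_mask.any():
        raise ValueError("region and reference must be non-empty")
    ref_mean = float(image.data[ref_mask].mean())
    if ref_mean == 0:
        raise ZeroDivisionError("reference region mean signal is zero")
    return float(image.data[roi_mask].mean()) / ref_mean


def rater_reliability(volumes_a: Sequence[float], volumes_b: Sequence[float]) -> float:
    """Pearson product-moment correlation between two raters' volume lists."""
    a = np.asarray(volumes_a, dtype=np.float64)
    b = np.asarray(volumes_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length lists with >= 3 entries")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in rater volumes")
    return float(stats.pearsonr(a, b).statistic)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m."""
    if not (0.0 <= p <= 1.0) or m < 1:
        raise ValueError("p in [0,1] and m >= 1 required")
    return float(1.0 - (1.0 - p) ** m)


def two_way_anova(df: pd.DataFrame, value: str = "value") -> dict[str, dict[str, float]]:
    """Two-way ANOVA with factors ``group`` and ``cell`` (type-II SS via
    statsmodels OLS). Returns F and p per effect."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={value: "y"})
    model = smf.ols("y ~ C(group) * C(cell)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out: dict[str, dict[str, float]] = {}
    for row, key in (
        ("C(group)", "group"),
        ("C(cell)", "cell"),
        ("C(group):C(cell)", "interaction"),
    ):
        out[key] = {"F": float(table.loc[row, "F"]), "p": float(table.loc[row, "PR(>F)"])}
    return out


# --------------------------------------------------------------------------
# per-subject measurement table
# --------------------------------------------------------------------------


def compute_roi_stats(
    subject_id: str, image: ImageVolume, labels: LabelVolume
) -> list[ROIStats]:
    """Measure every named region of one subject (volume, signals, and
    5-point thickness for cortical ribbons)."""
    rows: list[ROIStats] = []
    for name in labels.names:
        if name == "background":
            continue
        mask = labels.mask(name)
        if not mask.any():
            continue
        thick = None
        if name.startswith("ctx_") and name != "ctx_visual_ref":
            thick = cortical_thickness(labels, name)
        rows.append(
            ROIStats(
                subject_id=subject_id,
                region=name,
                volume_mm3=roi_volume(labels, name),
                mean_signal=float(image.data[mask].mean()),
                relative_signal=relative_signal(image, labels, name),
                thickness_mm=thick,
            )
        )
    rows.append(
        ROIStats(
            subject_id=subject_id,
            region="whole_brain",
            volume_mm3=whole_brain_volume(labels),
            mean_signal=float("nan"),
            relative_signal=float("nan"),
        )
    )
    return rows


def stats_to_frame(all_stats: Iterable[ROIStats], groups: Mapping[str, str]) -> pd.DataFrame:
    """Tidy frame: subject, group, measure, family, cell, value.

    Bilateral volumes and cortical thickness get ``cell`` = L/R; skull and
    whole-brain volumes get a single cell.
    """
    records: list[dict] = []
    for s in all_stats:
        group = groups[s.subject_id]
        region = s.region
        if region in ("skull", "whole_brain"):
            records.append(
                dict(subject=s.subject_id, group=group, measure="volume",
                     family=region, cell="all", value=s.volume_mm3)
            )
        elif any(region == f"{fam}_{side}" for fam in BILATERAL_FAMILIES for side in "LR"):
            fam, side = region.rsplit("_", 1)
            records.append(
                dict(subject=s.subject_id, group=group, measure="volume",
                     family=fam, cell=side, value=s.volume_mm3)
            )
        if s.thickness_mm is not None:
            fam, side = region.rsplit("_", 1)
            records.append(
                dict(subject=s.subject_id, group=group, measure="thickness",
                     family=fam, cell=side, value=float(np.mean(s.thickness_mm)))
            )
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(var))


def group_compare(
    df: pd.DataFrame,
    control: str = "control",
    treated: str = "mptp",
) -> pd.DataFrame:
    """Group comparison table from a tidy measurement frame.

    Single-cell measures (skull, whole brain) use a classic two-tailed
    independent t-test; bilateral measures use a two-way ANOVA (group x
    side) with Sidak-adjusted per-side contrasts. Every row carries group
    means/sds on per-subject values (sides averaged), the percent
    difference and pooled-sd Cohen's d.
    """
    from .power import cohens_d

    for g in (control, treated):
        if df.loc[df.group == g, "subject"].nunique() < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")

    rows: list[dict] = []
    for (measure, family), sub in df.groupby(["measure", "family"], sort=True):
        per_subj = sub.groupby(["subject", "group"], as_index=False)["value"].mean()
        a = per_subj.loc[per_subj.group == control, "value"].to_numpy()
        b = per_subj.loc[per_subj.group == treated, "value"].to_numpy()
        mean_c, mean_t = float(a.mean()), float(b.mean())
        pct = 100.0 * (mean_t - mean_c) / mean_c if mean_c != 0 else float("nan")
        try:
            d = cohens_d(mean_c, float(a.std(ddof=1)), len(a), mean_t, float(b.std(ddof=1)), len(b))
        except ZeroDivisionError:
            # both groups internally constant
            d = 0.0 if mean_c == mean_t else float("inf")

        cells = sorted(sub.cell.unique())
        sidak: dict[str, float] = {}
        if len(cells) == 1:
            t_res = stats.ttest_ind(a, b, equal_var=True)
            test, p = "independent_t", float(t_res.pvalue)
            if np.isnan(p):  # zero variance in both groups
                p = 1.0 if mean_c == mean_t else 0.0
        else:
            anova = two_way_anova(sub)
            test, p = "two_way_anova_group", anova["group"]["p"]
            for cell in cells:
                ca = sub[(sub.group == control) & (sub.cell == cell)]["value"].to_numpy()
                cb = sub[(sub.group == treated) & (sub.cell == cell)]["value"].to_numpy()
                raw = float(stats.ttest_ind(ca, cb, equal_var=True).pvalue)
                if np.isnan(raw):  # zero variance in both cells
                    raw = 1.0 if ca.mean() == cb.mean() else 0.0
                sidak[cell] = sidak_adjust(raw, len(cells))
        rows.append(
            dict(
                measure=measure,
                region=family,
                control_mean=mean_c,
                control_sd=float(a.std(ddof=1)),
                mptp_mean=mean_t,
                mptp_sd=float(b.std(ddof=1)),
                percent_difference=pct,
                test=test,
                p_value=p,
                sidak_by_cell=sidak,
                cohens_d=d,
            )
        )
    return pd.DataFrame(rows)
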