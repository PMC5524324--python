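"""Voxel-wise group inference on Jacobian maps.

Two-sample pooled-variance t at each masked voxel (log-determinants by
default, for expansion/contraction symmetry), permutation p-values
(exhaustive enumeration of relabelings when feasible, Monte-Carlo
otherwise), Benjamini-Hochberg FDR masking and a direction map.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .core import GridSpec

__all__ = [
    "JacobianMap",
    "VoxelwiseResult",
    "voxelwise_t",
    "permutation_p",
    "fdr_mask",
    "direction_map",
    "analyze_groups",
    "EXHAUSTIVE_CAP",
]

#: enumerate all relabelings up to this many; Monte-Carlo beyond
EXHAUSTIVE_CAP = 10_000


@dataclass
class JacobianMap:
    """Per-subject Jacobian determinant map with group membership."""

    det: np.ndarray
    grid: GridSpec
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.det = np.asarray(self.det, dtype=np.float64)
        if self.det.shape != self.grid.shape:
            raise ValueError("det shape does not match grid")


@dataclass
class VoxelwiseResult:
    """t/p/direction maps plus FDR and voxel-threshold masks for a contrast."""

    t_map: np.ndarray
    p_map: np.ndarray
    direction: np.ndarray
    fdr_significant: np.ndarray
    voxel_significant: np.ndarray
    mask: np.ndarray
    q: float
    voxel_p: float
    n_permutations: int
    exhaustive: bool
    n_zero_variance: int = 0


def _stack_masked(maps: Sequence[np.ndarray], mask: np.ndarray) -> np.ndarray:
    return np.stack([np.asarray(m, dtype=np.float64)[mask] for m in maps], axis=0)


def _pooled_t(data: np.ndarray, is_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample pooled-variance t per column of ``data`` (subjects x voxels).

    Returns (t, zero_variance_flags); zero-pooled-variance voxels get t = 0.
    """
    na = int(is_a.sum())
    nb = data.shape[0] - na
    a = data[is_a]
    b = data[~is_a]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    pooled = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    zero = se == 0
    t = np.zeros_like(ma)
    np.divide(ma - mb, se, out=t, where=~zero)
    return t, zero


def voxelwise_t(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    mask: np.ndarray,
    *,
    log_transform: bool = True,
) -> np.ndarray:
    """Two-sample pooled t-map (A minus B) over the mask, on log-determinants
    by default. Zero-pooled-variance voxels are set to t = 0."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 maps per group")
    data = _stack_masked(list(group_a) + list(group_b), mask)
    if log_transform:
        if np.any(data <= 0):
            raise ValueError("log transform requires strictly positive determinants")
        data = np.log(data)
    is_a = np.zeros(data.shape[0], dtype=bool)
    is_a[: len(group_a)] = True
    t, _ = _pooled_t(data, is_a)
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask] = t
    return out


def _relabeling_matrix(n_total: int, n_a: int, cap: int, rng: np.random.Generator | None):
    """(labelings, exhaustive_flag): boolean matrix, row 0 = observed labels."""
    n_distinct = comb(n_total, n_a)
    if n_distinct <= cap:
        rows = np.zeros((n_distinct, n_total), dtype=bool)
        for r, idx in enumerate(combinations(range(n_total), n_a)):
            rows[r, list(idx)] = True
        # move the observed labeling (first n_a subjects) to row 0
        observed = tuple(range(n_a))
        obs_row = next(
            r for r, idx in enumerate(combinations(range(n_total), n_a)) if idx == observed
        )
        rows[[0, obs_row]] = rows[[obs_row, 0]]
        return rows, True
    if rng is None:
        raise ValueError("Monte-Carlo permutation requires a seeded generator")
    rows = np.zeros((cap + 1, n_total), dtype=bool)
    rows[0, :n_a] = True  # observed labeling
    for r in range(1, cap + 1):
        rows[r, rng.choice(n_total, size=n_a, replace=False)] = True
    return rows, False


def permutation_p(
    maps: Sequence[np.ndarray],
    group_labels: Sequence[str],
    mask: np.ndarray,
    *,
    log_transform: bool = True,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    seed: int | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Two-sided permutation p-values of the voxel-wise two-sample t.

    Exhaustive over all C(n, n_a) relabelings when that count is within
    ``exhaustive_cap`` (p = #{|t_perm| >= |t_obs|} / total, observed
    labeling included, so min p = 1/total); otherwise Monte-Carlo with the
    (b + 1) / (m + 1) estimator and the given seed.

    Returns (p-map, number of relabelings used, exhaustive flag).
    """
    groups = sorted(set(group_labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    order = np.argsort([0 if g == groups[0] else 1 for g in group_labels], kind="stable")
    maps = [maps[i] for i in order]
    n_a = sum(1 for g in group_labels if g == groups[0])
    n_total = len(maps)
    if n_a < 2 or n_total - n_a < 2:
        raise ValueError("need >= 2 subjects per group")

    data = _stack_masked(maps, mask)
    if log_transform:
        if np.any(data <= 0):
            raise ValueError("log transform requires strictly positive determinants")
        data = np.log(data)

    rng = np.random.default_rng(seed) if seed is not None else None
    rows, exhaustive = _relabeling_matrix(n_total, n_a, exhaustive_cap, rng)
    m = rows.shape[0]

    # vectorized pooled t over all relabelings: sums via matmul
    col_sum = data.sum(axis=0)
    col_sq = (data**2).sum(axis=0)
    nb = n_total - n_a
    P = rows.astype(np.float64)
    sum_a = P @ data
    sq_a = P @ (data**2)
    mean_a = sum_a / n_a
    mean_b = (col_sum - sum_a) / nb
    ssa = sq_a - n_a * mean_a**2
    ssb = (col_sq - sq_a) - nb * mean_b**2
    pooled = (ssa + ssb) / (n_total - 2)
    se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / n_a + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, (mean_a - mean_b) / se, 0.0)

    t_obs = np.abs(t_all[0])
    # tie tolerance is relative: exact ties (e.g. complement labelings with
    # equal group sizes) reach the observed |t| through different arithmetic
    tol = 1e-10 * np.maximum(t_obs, 1.0)
    exceed = (np.abs(t_all) >= t_obs - tol).sum(axis=0)
    if exhaustive:
        p = exceed / m
    else:
        # row 0 is the observed labeling: (b + 1) / (m + 1) with b over the
        # m random relabelings
        p = exceed / m
    out = np.ones(mask.shape, dtype=np.float64)
    out[mask] = p
    return out, m, exhaustive


def fdr_mask(p_map: np.ndarray, q: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all p <= p_(k) with
    k = max{i : p_(i) <= i q / m} over the masked voxels."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    p_map = np.asarray(p_map, dtype=np.float64)
    if mask is None:
        mask = np.ones(p_map.shape, dtype=bool)
    p = p_map[mask]
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must be in (0, 1]")
    m = p.size
    order = np.sort(p)
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= thresh)[0]
    out = np.zeros(p_map.shape, dtype=bool)
    if passing.size:
        p_crit = order[passing[-1]]
        out[mask] = p <= p_crit
    return out


def direction_map(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    mask: np.ndarray,
    *,
    log_transform: bool = True,
) -> np.ndarray:
    """Sign of (mean A - mean B) per masked voxel: +1 expansion of A relative
    to B, -1 atrophy, 0 equal."""
    a = _stack_masked(group_a, mask)
    b = _stack_masked(group_b, mask)
    if log_transform:
        a, b = np.log(a), np.log(b)
    sign = np.sign(a.mean(axis=0) - b.mean(axis=0))
    out = np.zeros(mask.shape, dtype=np.int8)
    out[mask] = sign.astype(np.int8)
    return out


def analyze_groups(
    maps: Sequence[JacobianMap],
    mask: np.ndarray,
    *,
    q: float = 0.05,
    voxel_p: float = 0.01,
    log_transform: bool = True,
    control_group: str = "control",
    seed: int | None = None,
) -> VoxelwiseResult:
    """Full voxel-wise contrast (treated minus control): t-map, permutation
    p-map, direction, FDR mask at ``q`` and the raw voxel-threshold mask."""
    groups = sorted({m.group for m in maps})
    if len(groups) != 2 or control_group not in groups:
        raise ValueError("need exactly two groups including the control group")
    treated_group = next(g for g in groups if g != control_group)
    treated = [m.det for m in maps if m.group == treated_group]
    control = [m.det for m in maps if m.group == control_group]

    t_map = voxelwise_t(treated, control, mask, log_transform=log_transform)
    p_map, n_perm, exhaustive = permutation_p(
        [m.det for m in maps],
        [m.group for m in maps],
        mask,
        log_transform=log_transform,
        seed=seed,
    )
    direction = direction_map(treated, control, mask, log_transform=log_transform)
    fdr = fdr_mask(p_map, q, mask)
    voxel_sig = mask & (p_map < voxel_p)
    zero_var = int(np.count_nonzero((t_map == 0) & mask))
    return VoxelwiseResult(
        t_map=t_map,
        p_map=p_map,
        direction=direction,
        fdr_significant=fdr,
        voxel_significant=voxel_sig,
        mask=mask,
        q=q,
        voxel_p=voxel_p,
        n_permutations=n_perm,
        exhaustive=exhaustive,
        n_zero_variance=zero_var,
    )
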