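"""Linear (6/9-dof) and fluid (demons-style) registration plus Jacobian maps.

Transforms and displacement fields use the pull-back convention throughout:
a transform maps fixed-space world coordinates to moving-space world
coordinates, so ``resampled(x) = moving(T(x))`` and
``warped(x) = moving(x + u(x))``. Fields are stored in mm, 4D with the
displacement component on the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .core import GridSpec, ImageVolume, LabelVolume

__all__ = [
    "LinearTransform",
    "FluidParams",
    "DeformationField",
    "RegistrationError",
    "register_linear",
    "resample",
    "population_mean",
    "register_fluid",
    "jacobian_map",
    "ncc",
]


class RegistrationError(RuntimeError):
    """Raised when an optimizer fails to converge; carries diagnostics."""

    def __init__(self, message: str, best=None, trace=None):
        super().__init__(message)
        self.best = best
        self.trace = trace


# --------------------------------------------------------------------------
# linear transforms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearTransform:
    """Rigid or rigid+scale map about a rotation center.

    ``T(p) = R @ (S @ (p - c)) + c + t`` with Euler rotations applied in
    x, y, z order. Scales are fixed at 1 for 6-dof fits.
    """

    rotations_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be > 0")

    @property
    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotations_rad
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix in world (mm) coordinates."""
        A = self.rotation_matrix @ np.diag(self.scales)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translations_mm)
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = c + t - A @ c
        return M

    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of world points."""
        pts_mm = np.asarray(pts_mm, dtype=np.float64)
        M = self.matrix
        return pts_mm @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "LinearTransform":
        raise NotImplementedError("compose via matrices; parametric inverse not needed")

    @property
    def scale_product(self) -> float:
        """Whole-volume ratio estimate from the three scales."""
        return float(np.prod(self.scales))

    def to_dict(self) -> dict:
        return {
            "rotations_rad": list(self.rotations_rad),
            "translations_mm": list(self.translations_mm),
            "scales": list(self.scales),
            "center_mm": list(self.center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearTransform":
        return cls(
            tuple(d["rotations_rad"]),
            tuple(d["translations_mm"]),
            tuple(d["scales"]),
            tuple(d["center_mm"]),
        )


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------


def _transform_indices(grid: GridSpec, transform: LinearTransform) -> np.ndarray:
    xs, ys, zs = grid.world_coordinates()
    pts = np.stack(
        [np.broadcast_to(a, grid.shape) for a in (xs, ys, zs)], axis=-1
    ).reshape(-1, 3)
    mapped = transform.apply_points(pts)
    idx = grid.index_from_world(mapped).reshape(grid.shape + (3,))
    return np.moveaxis(idx, -1, 0)


def _field_indices(grid: GridSpec, displacement_mm: np.ndarray) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=np.float64)
    spacing = np.asarray(grid.spacing)
    for ax in range(3):
        idx[ax] += displacement_mm[..., ax] / spacing[ax]
    return idx


def resample(volume, transform_or_field):
    """Resample an :class:`ImageVolume` (trilinear) or :class:`LabelVolume`
    (nearest-neighbour) through a :class:`LinearTransform` or a displacement
    field (mm). Out-of-field voxels become background/zero."""
    grid = volume.grid
    if isinstance(transform_or_field, LinearTransform):
        coords = _transform_indices(grid, transform_or_field)
    else:
        fld = np.asarray(transform_or_field, dtype=np.float64)
        if fld.shape != grid.shape + (3,):
            raise ValueError(f"field shape {fld.shape} != {grid.shape + (3,)}")
        coords = _field_indices(grid, fld)
    if isinstance(volume, LabelVolume):
        out = ndimage.map_coordinates(volume.labels, coords, order=0, mode="constant", cval=0)
        return LabelVolume(out.astype(np.int16), grid, dict(volume.dictionary))
    out = ndimage.map_coordinates(volume.data, coords, order=1, mode="constant", cval=0.0)
    return ImageVolume(out, grid)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two arrays (zero-mean, whole volume)."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


# --------------------------------------------------------------------------
# linear registration
# --------------------------------------------------------------------------


def _downsample(image: ImageVolume, factor: int) -> ImageVolume:
    """Anti-aliased decimation by an integer factor (voxel (0,0,0) kept, so
    origin is unchanged)."""
    if factor == 1:
        return image
    sm = ndimage.gaussian_filter(image.data, sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    grid = GridSpec(
        shape=data.shape,
        spacing=tuple(s * factor for s in image.grid.spacing),
        origin=image.grid.origin,
    )
    return ImageVolume(data, grid)


# parameter scaling so one optimizer step is comparable across dof types
_ROT_UNIT = 0.05  # rad
_SCALE_UNIT = 0.05  # log units


def _params_to_transform(p: np.ndarray, dof: int, center) -> LinearTransform:
    rot = tuple(p[0:3] * _ROT_UNIT)
    trans = tuple(p[3:6])
    if dof == 9:
        scales = tuple(np.exp(p[6:9] * _SCALE_UNIT))
    else:
        scales = (1.0, 1.0, 1.0)
    return LinearTransform(rot, trans, scales, tuple(center))


def register_linear(
    moving: ImageVolume,
    fixed: ImageVolume,
    dof: int = 6,
    *,
    levels: Sequence[int] = (4, 2, 1),
    maxiter: Sequence[int] = (60, 30, 2),
    max_rotation_rad: float = 0.35,
    max_translation_mm: float = 8.0,
    max_log_scale: float = 0.3,
) -> LinearTransform:
    """Fit a 6-dof (rigid) or 9-dof (rigid+scale) transform maximizing NCC,
    coarse to fine. The returned transform maps fixed to moving coordinates
    (pull-back); for dof=9 the scale product estimates the volume ratio.

    The search is bounded (by default rotations within 20 degrees) because
    inputs are assumed to share a scanner orientation; unbounded search can
    settle on spurious symmetry poses of near-ellipsoidal heads.
    """
    if dof not in (6, 9):
        raise ValueError("dof must be 6 or 9")
    n_par = 9 if dof == 9 else 6
    center = fixed.grid.center_mm
    identity = LinearTransform(center_mm=tuple(center))
    if moving.data.std() == 0 or fixed.data.std() == 0:
        # degenerate (constant) images carry no alignment information
        return identity
    p = np.zeros(n_par)
    bounds = [(-max_rotation_rad / _ROT_UNIT, max_rotation_rad / _ROT_UNIT)] * 3
    bounds += [(-max_translation_mm, max_translation_mm)] * 3
    if dof == 9:
        bounds += [(-max_log_scale / _SCALE_UNIT, max_log_scale / _SCALE_UNIT)] * 3
    trace: list[float] = []

    for factor, level_maxiter in zip(levels, maxiter):
        mov = _downsample(moving, factor)
        fix = _downsample(fixed, factor)

        def cost(q: np.ndarray) -> float:
            t = _params_to_transform(q, dof, center)
            warped = resample(mov, t)
            val = -ncc(warped.data, fix.data)
            trace.append(-val)
            return val

        res = optimize.minimize(
            cost,
            p,
            method="Powell",
            bounds=bounds,
            options={"maxiter": level_maxiter, "xtol": 1e-3, "ftol": 1e-8},
        )
        p = res.x
    t = _params_to_transform(p, dof, center)
    final = ncc(resample(moving, t).data, fixed.data)
    ncc_identity = ncc(moving.data, fixed.data)
    if final < ncc_identity:
        # optimizer drifted within tolerance of an already-aligned pair
        t, final = identity, ncc_identity
    if final < 0.2:
        raise RegistrationError(
            f"linear registration failed to converge (final NCC {final:.3f})",
            best=t,
            trace=trace,
        )
    return t


def population_mean(
    images: Sequence[ImageVolume], reference: ImageVolume, dof: int = 9
) -> ImageVolume:
    """Register each image to the reference and voxel-average the results."""
    if len(images) == 0:
        raise ValueError("need at least one image")
    acc = np.zeros(reference.grid.shape, dtype=np.float64)
    for i, img in enumerate(images):
        try:
            t = register_linear(img, reference, dof=dof)
        except RegistrationError as e:
            raise RegistrationError(f"registration failed for image {i}: {e}") from e
        acc += resample(img, t).data
    return ImageVolume(acc / len(images), reference.grid)


# --------------------------------------------------------------------------
# fluid (demons) registration
# --------------------------------------------------------------------------


@dataclass
class FluidParams:
    """Demons-style fluid registration knobs."""

    levels: Sequence[int] = (4, 2, 1)
    iterations: Sequence[int] = (80, 60, 40)
    smooth_sigma_mm: float = 1.0  # Gaussian regularization of each update
    max_step_vox: float = 0.4
    tolerance: float = 1e-7
    max_rejections: int = 25
    presmooth_mm: float = 0.25  # image blur before the demons force
    field_sigma_mm: float = 0.0  # diffusion-like blur of the total field


@dataclass
class DeformationField:
    """Dense displacement (mm) on a grid plus convergence metadata."""

    displacement_mm: np.ndarray
    grid: GridSpec
    iterations_run: int = 0
    final_ssd: float = float("nan")

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=np.float64)
        if self.displacement_mm.shape != self.grid.shape + (3,):
            raise ValueError("field shape does not match grid")


def _compose(u: np.ndarray, step: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Pull-back composition: (u o step)(x) = u(x + step(x)) + step(x)."""
    coords = _field_indices(grid, step)
    out = np.empty_like(u)
    for ax in range(3):
        out[..., ax] = ndimage.map_coordinates(
            u[..., ax], coords, order=1, mode="nearest"
        )
    return out + step


def _min_interior_jacobian(u: np.ndarray, grid: GridSpec) -> float:
    det = jacobian_map(u, grid)
    return float(det[1:-1, 1:-1, 1:-1].min())


def _upsample_field(u: np.ndarray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    zoom = [d / s for d, s in zip(dst.shape, src.shape)]
    out = np.empty(dst.shape + (3,), dtype=np.float64)
    for ax in range(3):
        out[..., ax] = ndimage.zoom(u[..., ax], zoom, order=1, mode="nearest")
    return out


def register_fluid(
    moving: ImageVolume,
    fixed: ImageVolume,
    params: FluidParams | None = None,
) -> DeformationField:
    """Compositive demons registration of pre-aligned, same-grid images.

    Per iteration the update is the classic stabilized demons force
    ``-diff * grad(fixed) / (|grad(fixed)|^2 + diff^2 / s^2)`` (s = mean
    spacing), Gaussian-smoothed (fluid-like regularization of the update),
    step-capped and composed with the running field. Steps that would make
    the accumulated field's interior Jacobian non-positive, or that increase
    SSD, are halved and finally rejected; SSD is non-increasing over
    accepted steps.
    """
    params = params or FluidParams()
    if not moving.grid.matches(fixed.grid):
        raise ValueError("fluid registration requires a common grid")

    u: np.ndarray | None = None
    prev_grid: GridSpec | None = None
    total_iters = 0
    rejections = 0
    ssd = float("nan")

    if params.presmooth_mm > 0:
        sig = params.presmooth_mm / np.asarray(moving.grid.spacing)
        moving = ImageVolume(ndimage.gaussian_filter(moving.data, sig), moving.grid)
        fixed = ImageVolume(ndimage.gaussian_filter(fixed.data, sig), fixed.grid)

    for factor, n_iter in zip(params.levels, params.iterations):
        mov = _downsample(moving, factor)
        fix = _downsample(fixed, factor)
        grid = fix.grid
        spacing = np.asarray(grid.spacing)
        mean_sp = float(spacing.mean())
        sigma_vox = params.smooth_sigma_mm / spacing

        if u is None:
            u = np.zeros(grid.shape + (3,), dtype=np.float64)
        else:
            u = _upsample_field(u, prev_grid, grid)
        prev_grid = grid

        grad = np.stack(np.gradient(fix.data, *spacing), axis=-1)
        gmag2 = np.sum(grad**2, axis=-1)

        warped = resample(mov, u)
        ssd = float(np.sum((warped.data - fix.data) ** 2))

        # adaptive trust-region-style step scale: shrink on rejection, grow
        # slowly on success, so every subject follows the same deterministic
        # schedule instead of stopping at the first non-improving step
        scale = 1.0
        for _ in range(n_iter):
            diff = warped.data - fix.data
            denom = gmag2 + (diff**2) / (mean_sp**2)
            with np.errstate(divide="ignore", invalid="ignore"):
                force = -diff[..., None] * grad / denom[..., None]
            force[~np.isfinite(force)] = 0.0

            step = np.empty_like(force)
            for ax in range(3):
                step[..., ax] = ndimage.gaussian_filter(force[..., ax], sigma=sigma_vox)

            max_vox = np.max(np.abs(step) / spacing)
            if max_vox > params.max_step_vox:
                step *= params.max_step_vox / max_vox
            step *= scale
            if not np.any(step):
                break

            accepted = False
            while scale >= 2.0 ** -8:
                cand = _compose(u, step, grid)
                if params.field_sigma_mm > 0:
                    fsig = params.field_sigma_mm / spacing
                    for ax in range(3):
                        cand[..., ax] = ndimage.gaussian_filter(cand[..., ax], sigma=fsig)
                if _min_interior_jacobian(cand, grid) <= 0:
                    # field would fold: hard rejection, halve and retry
                    step *= 0.5
                    scale *= 0.5
                    rejections += 1
                    if rejections > params.max_rejections:
                        raise RegistrationError(
                            f"fluid registration stalled after {rejections} "
                            f"Jacobian rejections (SSD {ssd:.4g})",
                            best=DeformationField(u, grid, total_iters, ssd),
                        )
                    continue
                cand_warped = resample(mov, cand)
                cand_ssd = float(np.sum((cand_warped.data - fix.data) ** 2))
                if cand_ssd <= ssd:
                    accepted = True
                    break
                step *= 0.5
                scale *= 0.5
            total_iters += 1
            if not accepted:
                # even the smallest admissible step cannot improve SSD
                break

            rel_change = (ssd - cand_ssd) / ssd if ssd > 0 else 0.0
            u, warped, ssd = cand, cand_warped, cand_ssd
            scale = min(scale * 1.26, 1.0)
            if 0 <= rel_change < params.tolerance:
                break

    assert u is not None
    if _min_interior_jacobian(u, fixed.grid) <= 0:
        raise RegistrationError("accepted fluid field has non-positive Jacobian")
    return DeformationField(u, fixed.grid, total_iters, ssd)


# --------------------------------------------------------------------------
# Jacobian maps
# --------------------------------------------------------------------------


def jacobian_map(displacement_mm: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Determinant of the spatial Jacobian of ``x -> x + u(x)``.

    Central finite differences in physical units (one-sided at borders);
    det > 1 marks expansion of the pull-back source region, det - 1 is the
    apparent fractional volume difference.
    """
    u = np.asarray(displacement_mm, dtype=np.float64)
    if u.shape != grid.shape + (3,):
        raise ValueError(f"field shape {u.shape} != {grid.shape + (3,)}")
    spacing = grid.spacing
    J = np.empty(grid.shape + (3, 3), dtype=np.float64)
    for comp in range(3):
        grads = np.gradient(u[..., comp], *spacing)
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
        J[..., comp, comp] += 1.0
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    d, e, f = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    g, h, i = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
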