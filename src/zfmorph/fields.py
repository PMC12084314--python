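"""Displacement fields, log-Jacobian-determinant maps and volumetry.

A registration of a subject brain to the reference atlas yields a mapping
``phi(x) = x + u(x)`` (atlas -> subject, physical units).  The local volume
change of the subject relative to the reference is ``det grad(phi)``; its
logarithm is the LJD map.  ``LJD < 0`` at a voxel means the subject is
locally *smaller* than the reference (the voxel had to be inflated during
registration to match the atlas).

Volumes of atlas-defined regions in subject space are obtained by
integrating ``exp(LJD)`` over the region, which is the change-of-variables
formula; an independent dense-lattice integrator (`warped_volume`) maps a
sub-voxel point lattice through ``phi`` and sums warped cell volumes, and is
used as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DisplacementField",
    "LjdMap",
    "FoldedFieldError",
    "log_jacobian",
    "jacobian_determinant",
    "region_volume",
    "warped_volume",
]


class FoldedFieldError(ValueError):
    """Raised when det(grad phi) <= 0 somewhere (non-invertible field)."""

    def __init__(self, voxels: np.ndarray):
        self.voxels = voxels
        example = voxels[:5].tolist()
        super().__init__(
            f"displacement field folds at {len(voxels)} voxel(s); first offenders {example}"
        )


@dataclass
class DisplacementField:
    """Dense displacement ``u(x)`` on the atlas grid, atlas -> subject.

    ``u`` has shape ``grid + (3,)`` and physical units (um); ``spacing`` is
    the per-axis voxel size in um.
    """

    u: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("u must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    @classmethod
    def identity(cls, shape, spacing) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)), tuple(spacing))


@dataclass
class LjdMap:
    """Log Jacobian determinant ``ln det(grad phi)`` per voxel (dimensionless)."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def _displacement_gradient(field: DisplacementField) -> np.ndarray:
    """grad u with shape grid + (3, 3); entry [..., i, j] = d u_i / d x_j.

    Central differences in the interior, one-sided at the boundary (this is
    exactly numpy.gradient's stencil), scaled by the physical spacing.
    """
    g = np.empty(field.shape + (3, 3))
    for i in range(3):
        grads = np.gradient(field.u[..., i], *field.spacing)
        for j in range(3):
            g[..., i, j] = grads[j]
    return g


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det(I + grad u) at every voxel."""
    if min(field.shape) < 3:
        raise ValueError("grid must be at least 3 voxels per axis")
    g = _displacement_gradient(field)
    g[..., 0, 0] += 1.0
    g[..., 1, 1] += 1.0
    g[..., 2, 2] += 1.0
    det = (
        g[..., 0, 0] * (g[..., 1, 1] * g[..., 2, 2] - g[..., 1, 2] * g[..., 2, 1])
        - g[..., 0, 1] * (g[..., 1, 0] * g[..., 2, 2] - g[..., 1, 2] * g[..., 2, 0])
        + g[..., 0, 2] * (g[..., 1, 0] * g[..., 2, 1] - g[..., 1, 1] * g[..., 2, 0])
    )
    return det


def log_jacobian(field: DisplacementField) -> LjdMap:
    """LJD map of a displacement field.

    Raises
    ------
    FoldedFieldError
        If the determinant is non-positive anywhere; the exception lists the
        offending voxels.
    """
    det = jacobian_determinant(field)
    bad = det <= 0
    if bad.any():
        raise FoldedFieldError(np.argwhere(bad))
    return LjdMap(np.log(det), field.spacing)


def region_volume(
    ljd: LjdMap,
    mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Subject-space volume of an atlas region, and optionally its percent of brain.

    ``volume = sum_{x in mask} exp(LJD(x)) * voxel_volume``.  If
    ``brain_mask`` is given, the percent of total brain volume (computed the
    same way) is returned as the second element, else ``None``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ljd.values.shape:
        raise ValueError("mask not congruent with LJD map")
    if not mask.any():
        raise ValueError("empty region mask")
    expj = np.exp(ljd.values)
    vol = float(expj[mask].sum() * ljd.voxel_volume)
    pct = None
    if brain_mask is not None:
        total = float(expj[np.asarray(brain_mask, dtype=bool)].sum() * ljd.voxel_volume)
        pct = 100.0 * vol / total
    return vol, pct


def _cell_center(arr: np.ndarray) -> np.ndarray:
    """Average the 8 corners of each lattice cell (trilinear cell center)."""
    out = arr
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(None, -1)
        sl1[ax] = slice(1, None)
        out = 0.5 * (out[tuple(sl0)] + out[tuple(sl1)])
    return out


def _cell_edge(arr: np.ndarray, axis: int) -> np.ndarray:
    """Cell-centered edge vector component along ``axis`` (second-order)."""
    d = np.diff(arr, axis=axis)
    for ax in range(3):
        if ax == axis:
            continue
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(None, -1)
        sl1[ax] = slice(1, None)
        d = 0.5 * (d[tuple(sl0)] + d[tuple(sl1)])
    return d


def warped_volumes(
    field: DisplacementField, masks: dict[str, np.ndarray], refine: int = 2
) -> dict[str, float]:
    """Subject-space volumes of several regions by dense-lattice integration.

    Independent of the LJD route: a lattice refined ``refine``-fold is mapped
    through ``phi`` (trilinear interpolation of u), and the volume of every
    warped lattice cell is the determinant of its cell-centered edge vectors.
    Cells are attributed to the voxel containing their center.  The lattice is
    mapped once and shared across all regions.
    """
    for mask in masks.values():
        if np.asarray(mask).shape != field.shape:
            raise ValueError("mask not congruent with field")
    axes = [np.linspace(0.0, n - 1.0, (n - 1) * refine + 1) for n in field.shape]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    mapped = []
    for c in range(3):
        u_c = map_coordinates(field.u[..., c], coords, order=1, mode="nearest")
        mapped.append(grid[c] * field.spacing[c] + u_c.reshape(grid[c].shape))

    edges = [[_cell_edge(m, ax) for ax in range(3)] for m in mapped]
    det = (
        edges[0][0] * (edges[1][1] * edges[2][2] - edges[1][2] * edges[2][1])
        - edges[0][1] * (edges[1][0] * edges[2][2] - edges[1][2] * edges[2][0])
        + edges[0][2] * (edges[1][0] * edges[2][1] - edges[1][1] * edges[2][0])
    )
    centers = [_cell_center(g) for g in grid]
    vox = tuple(
        np.clip(np.round(cc).astype(int), 0, n - 1) for cc, n in zip(centers, field.shape)
    )
    return {
        name: float(det[np.asarray(mask, dtype=bool)[vox]].sum())
        for name, mask in masks.items()
    }


def warped_volume(field: DisplacementField, mask: np.ndarray, refine: int = 2) -> float:
    """Subject-space volume of one region; see `warped_volumes`."""
    return warped_volumes(field, {"region": mask}, refine=refine)["region"]
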