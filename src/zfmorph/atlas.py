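"""Synthetic bilaterally symmetric labeled brain atlas.

The atlas stands in for an annotated larval zebrafish reference brain: an
ellipsoidal "brain" partitioned into divisions along the rostro-caudal axis,
with a paired lateral cerebellar-plate (LCeP) subregion carved out of the
cerebellar slab.  Geometry is fully parametric so every division volume is
known analytically and the label grid is exactly mirror-symmetric about the
midsagittal plane.

Axis convention: axis 0 is the left-right axis (the mirror axis), axis 1 is
dorso-ventral, axis 2 is rostro-caudal.  The mirror plane sits at voxel
coordinate ``(n0 - 1) / 2``, which is a half-integer for even grids; index
reflection ``i -> 2*plane - i`` is then still integer-valued.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelAtlas",
    "AtlasSizeError",
    "make_atlas",
    "mirror_volume",
]

#: label -> division name for the default synthetic atlas
DEFAULT_NAMES = {
    1: "telencephalon",
    2: "tectum",
    3: "cerebellar_plate_body",
    4: "hindbrain",
    5: "lcep_left",
    6: "lcep_right",
}

#: composite regions expressed as unions of labels
DEFAULT_REGIONS = {
    "brain": (1, 2, 3, 4, 5, 6),
    "cerebellar_plate": (3, 5, 6),
    "lcep": (5, 6),
}


class AtlasSizeError(ValueError):
    """Grid too small to carve out all divisions."""


def mirror_volume(grid: np.ndarray, mirror_axis: int = 0, mirror_plane: float | None = None) -> np.ndarray:
    """Reflect ``grid`` about a (possibly half-integer) plane along one axis.

    Voxel ``i`` maps to ``2 * mirror_plane - i``; positions whose reflection
    falls outside the grid are filled with zero.  The operation is an
    involution whenever the reflected range stays in bounds (always true for
    the default center plane).
    """
    n = grid.shape[mirror_axis]
    if mirror_plane is None:
        mirror_plane = (n - 1) / 2.0
    two_plane = 2.0 * mirror_plane
    if abs(two_plane - round(two_plane)) > 1e-9:
        raise ValueError("mirror_plane must be an integer or half-integer voxel coordinate")
    src = int(round(two_plane)) - np.arange(n)
    valid = (src >= 0) & (src < n)
    out = np.zeros_like(grid)
    idx_out = [slice(None)] * grid.ndim
    idx_in = [slice(None)] * grid.ndim
    idx_out[mirror_axis] = valid
    idx_in[mirror_axis] = src[valid]
    out[tuple(idx_out)] = np.take(grid, src[valid], axis=mirror_axis)
    return out


@dataclass
class LabelAtlas:
    """Integer label volume with names, spacing and a midsagittal mirror plane.

    Parameters
    ----------
    labels
        3D integer grid; 0 is background, positive labels partition the brain.
    names
        Mapping label -> division name.
    spacing
        Per-axis voxel size in micrometres.
    mirror_axis, mirror_plane
        Axis index and voxel coordinate of the midsagittal plane.
    regions
        Named unions of labels (always includes ``"brain"``).
    meta
        Construction parameters (ellipsoid centers/semi-axes) used by the
        subject simulator.
    """

    labels: np.ndarray
    names: dict[int, str]
    spacing: tuple[float, float, float]
    mirror_axis: int = 0
    mirror_plane: float | None = None
    regions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if self.mirror_plane is None:
            self.mirror_plane = (self.labels.shape[self.mirror_axis] - 1) / 2.0
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if "brain" not in self.regions:
            self.regions = {**self.regions, "brain": tuple(sorted(self.names))}

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return float(np.prod(self.spacing))

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def mask(self, region: str | int) -> np.ndarray:
        """Boolean mask for a label, division name, or composite region name."""
        if isinstance(region, (int, np.integer)):
            return self.labels == int(region)
        if region in self.regions:
            return np.isin(self.labels, self.regions[region])
        for lab, name in self.names.items():
            if name == region:
                return self.labels == lab
        raise KeyError(f"unknown region {region!r}")

    def division_names(self) -> list[str]:
        """Names of the atomic divisions (one per label, partitioning the brain)."""
        return [self.names[lab] for lab in sorted(self.names)]

    def mirror(self, grid: np.ndarray) -> np.ndarray:
        """Reflect an arbitrary congruent grid about the midsagittal plane."""
        if grid.shape[: 3] != self.labels.shape:
            raise ValueError("grid not congruent with atlas")
        return mirror_volume(grid, self.mirror_axis, self.mirror_plane)

    def homotopic_labels(self) -> dict[int, int]:
        """Label -> label mapping under left/right reflection."""
        pairs = {}
        for lab, name in self.names.items():
            if name.endswith("_left"):
                other = name[: -5] + "_right"
            elif name.endswith("_right"):
                other = name[: -6] + "_left"
            else:
                pairs[lab] = lab
                continue
            inv = {v: k for k, v in self.names.items()}
            pairs[lab] = inv[other]
        return pairs

    def is_mirror_symmetric(self) -> bool:
        """True iff every voxel's mirror voxel carries the homotopic label."""
        mirrored = self.mirror(self.labels)
        swap = self.homotopic_labels()
        expected = np.zeros_like(self.labels)
        for lab, other in swap.items():
            expected[mirrored == lab] = other
        return bool(np.array_equal(expected, self.labels))

    def with_labels(self, labels: np.ndarray) -> "LabelAtlas":
        return dataclasses.replace(self, labels=labels)


# ----------------------------------------------------------------------
def make_atlas(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
) -> LabelAtlas:
    """Build the default synthetic atlas.

    The brain is an ellipsoid with semi-axes 0.42*shape; it is split along the
    rostro-caudal axis into telencephalon / tectum / cerebellar slab /
    hindbrain, and a mirror-symmetric pair of LCeP ellipsoids is carved out of
    the cerebellar slab.  Geometry is deterministic; ``seed`` is accepted for
    interface uniformity with the stochastic generators.

    Raises
    ------
    AtlasSizeError
        If any axis is shorter than 32 voxels (the LCeP pair would not be
        resolvable).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise AtlasSizeError(f"shape {shape} too small; need >= 32 voxels per axis")

    n0, n1, n2 = shape
    plane = (n0 - 1) / 2.0
    c = np.array([(n - 1) / 2.0 for n in shape])
    a = np.array([0.42 * n for n in shape])  # semi-axes, voxel units

    i, j, k = np.indices(shape, dtype=float)
    # symmetric left-right coordinate guarantees exact mirror symmetry
    xs = np.abs(i - plane)
    ys = j - c[1]
    zs = k - c[2]

    brain = (xs / a[0]) ** 2 + (ys / a[1]) ** 2 + (zs / a[2]) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    zeta = zs / a[2]
    labels[brain & (zeta < -0.35)] = 1
    labels[brain & (zeta >= -0.35) & (zeta < 0.10)] = 2
    labels[brain & (zeta >= 0.10) & (zeta < 0.45)] = 3
    labels[brain & (zeta >= 0.45)] = 4

    # paired LCeP ellipsoids inside the cerebellar slab
    lcep_dx = 0.45 * a[0]
    lcep_center = np.array([0.0, 0.0, 0.275 * a[2]])  # offsets from grid center
    lcep_semi = np.array([0.16 * a[0], 0.20 * a[1], 0.12 * a[2]])
    q = (
        ((xs - lcep_dx) / lcep_semi[0]) ** 2
        + ((ys - lcep_center[1]) / lcep_semi[1]) ** 2
        + ((zs - lcep_center[2]) / lcep_semi[2]) ** 2
    )
    lcep = q <= 1.0
    if not np.all(labels[lcep] == 3):
        raise AtlasSizeError("LCeP ellipsoids do not fit inside the cerebellar slab")
    labels[lcep & (i < plane)] = 5
    labels[lcep & (i > plane)] = 6

    atlas = LabelAtlas(
        labels=labels,
        names=dict(DEFAULT_NAMES),
        spacing=tuple(float(s) for s in spacing),
        mirror_axis=0,
        mirror_plane=plane,
        regions=dict(DEFAULT_REGIONS),
        meta={
            "lcep_centers_vox": [
                [plane - lcep_dx, c[1] + lcep_center[1], c[2] + lcep_center[2]],
                [plane + lcep_dx, c[1] + lcep_center[1], c[2] + lcep_center[2]],
            ],
            "lcep_semi_vox": lcep_semi.tolist(),
            "brain_semi_vox": a.tolist(),
        },
    )
    if not atlas.is_mirror_symmetric():  # pragma: no cover - construction guarantee
        raise RuntimeError("constructed atlas is not mirror-symmetric")
    return atlas
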