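"""Multiplane z-splitter mosaic processing.

A z-splitter prism projects several focal planes side by side onto one
camera sensor, so a single frame is a tile mosaic (e.g. 3x3 for nine
planes).  This module splits mosaics into per-plane images using a
user-calibrated layout (integer crops only — interpolation would disturb
the noise statistics the contrast estimator relies on), batch-runs the HiLo
reconstruction per plane, and renders depth-coded projections.

The physical ordering of tiles on the sensor depends on the prism and is
supplied by the user via `MultiplaneLayout` (YAML-serializable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .hilo import CameraModel, HiLoParams, ImagePair, reconstruct
from .nlm import NLMParams

__all__ = [
    "MultiplaneLayout",
    "PlaneStack",
    "DepthProjection",
    "split_mosaic",
    "assemble_mosaic",
    "reconstruct_stack",
    "depth_coded_projection",
]


@dataclass(frozen=True)
class MultiplaneLayout:
    """Geometry mapping a mosaic frame to an ordered stack of focal planes.

    Attributes
    ----------
    grid_rows, grid_cols : int
        Tile grid dimensions.
    tile_shape : (int, int)
        Common crop size of every tile.
    offsets : list of (int, int)
        Per-tile crop origins (row, col) in the frame, one per tile in
        row-major tile order.
    plane_order : list of int
        Permutation mapping tile index -> depth index (0 = shallowest).
    z_spacing_um : float
        Inter-plane distance.
    gains : list of float
        Per-plane scalar intensity gains compensating prism transmission
        differences (default all 1).
    flips : list of str
        Per-tile flips: "" (none), "h", "v" or "hv".
    """

    grid_rows: int
    grid_cols: int
    tile_shape: tuple[int, int]
    offsets: tuple[tuple[int, int], ...]
    plane_order: tuple[int, ...]
    z_spacing_um: float = 1.0
    gains: Optional[tuple[float, ...]] = None
    flips: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        n = self.n_planes
        if self.grid_rows * self.grid_cols < n:
            raise ValueError("tile grid smaller than the number of planes")
        if len(self.offsets) != n:
            raise ValueError(f"expected {n} offsets, got {len(self.offsets)}")
        if sorted(self.plane_order) != list(range(n)):
            raise ValueError(f"plane_order must be a permutation of 0..{n - 1}")
        if self.gains is not None and len(self.gains) != n:
            raise ValueError("gains length must match the number of planes")
        if self.flips is not None:
            if len(self.flips) != n:
                raise ValueError("flips length must match the number of planes")
            for f in self.flips:
                if f not in ("", "h", "v", "hv"):
                    raise ValueError(f"flip must be '', 'h', 'v' or 'hv', got {f!r}")

    @property
    def n_planes(self) -> int:
        return len(self.plane_order)

    @classmethod
    def regular(
        cls,
        grid: tuple[int, int],
        tile_shape: tuple[int, int],
        plane_order: Optional[Sequence[int]] = None,
        z_spacing_um: float = 1.0,
        **kwargs,
    ) -> "MultiplaneLayout":
        """Layout for an exactly tiled frame with no gaps between crops."""
        rows, cols = grid
        th, tw = tile_shape
        offsets = tuple((i * th, j * tw) for i in range(rows) for j in range(cols))
        order = tuple(plane_order) if plane_order is not None else tuple(range(rows * cols))
        return cls(
            grid_rows=rows,
            grid_cols=cols,
            tile_shape=(th, tw),
            offsets=offsets,
            plane_order=order,
            z_spacing_um=z_spacing_um,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path) -> "MultiplaneLayout":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        rows, cols = d["grid"]
        return cls(
            grid_rows=int(rows),
            grid_cols=int(cols),
            tile_shape=tuple(int(v) for v in d["tile_shape"]),
            offsets=tuple(tuple(int(v) for v in o) for o in d["offsets"]),
            plane_order=tuple(int(v) for v in d["plane_order"]),
            z_spacing_um=float(d.get("z_spacing_um", 1.0)),
            gains=tuple(float(v) for v in d["gains"]) if d.get("gains") else None,
            flips=tuple(str(v) for v in d["flips"]) if d.get("flips") else None,
        )

    def to_yaml(self, path) -> None:
        d = {
            "grid": [self.grid_rows, self.grid_cols],
            "tile_shape": list(self.tile_shape),
            "offsets": [list(o) for o in self.offsets],
            "plane_order": list(self.plane_order),
            "z_spacing_um": self.z_spacing_um,
            "gains": list(self.gains) if self.gains else None,
            "flips": list(self.flips) if self.flips else None,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass(frozen=True)
class PlaneStack:
    """Ordered per-plane images, shallowest to deepest."""

    planes: tuple[np.ndarray, ...]
    z_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("PlaneStack needs at least one plane")
        shapes = {p.shape for p in self.planes}
        if len(shapes) != 1:
            raise ValueError(f"planes have mixed shapes: {shapes}")

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    def as_array(self) -> np.ndarray:
        return np.stack(self.planes)


def _apply_flip(tile: np.ndarray, flip: str) -> np.ndarray:
    if "h" in flip:
        tile = tile[:, ::-1]
    if "v" in flip:
        tile = tile[::-1, :]
    return tile


def split_mosaic(frame: np.ndarray, layout: MultiplaneLayout) -> PlaneStack:
    """Crop the mosaic frame into depth-ordered planes (pure crop, no resampling)."""
    frame = np.asarray(frame, dtype=float)
    th, tw = layout.tile_shape
    planes: list[Optional[np.ndarray]] = [None] * layout.n_planes
    for tile_idx, (r0, c0) in enumerate(layout.offsets):
        if r0 < 0 or c0 < 0 or r0 + th > frame.shape[0] or c0 + tw > frame.shape[1]:
            raise ValueError(
                f"tile {tile_idx} crop [{r0}:{r0 + th}, {c0}:{c0 + tw}] "
                f"exceeds frame shape {frame.shape}"
            )
        tile = frame[r0 : r0 + th, c0 : c0 + tw].copy()
        if layout.flips is not None:
            tile = _apply_flip(tile, layout.flips[tile_idx])
        if layout.gains is not None:
            tile = tile * layout.gains[tile_idx]
        planes[layout.plane_order[tile_idx]] = tile
    return PlaneStack(planes=tuple(planes), z_spacing_um=layout.z_spacing_um)


def assemble_mosaic(
    stack: PlaneStack, layout: MultiplaneLayout, frame_shape: Optional[tuple[int, int]] = None
) -> np.ndarray:
    """Inverse of split_mosaic for non-overlapping layouts."""
    th, tw = layout.tile_shape
    if frame_shape is None:
        frame_shape = (layout.grid_rows * th, layout.grid_cols * tw)
    frame = np.zeros(frame_shape)
    for tile_idx, (r0, c0) in enumerate(layout.offsets):
        tile = np.asarray(stack.planes[layout.plane_order[tile_idx]], dtype=float)
        if layout.gains is not None:
            tile = tile / layout.gains[tile_idx]
        if layout.flips is not None:
            tile = _apply_flip(tile, layout.flips[tile_idx])
        frame[r0 : r0 + th, c0 : c0 + tw] = tile
    return frame


def reconstruct_stack(
    uniform_frame: np.ndarray,
    speckle_frame: np.ndarray,
    layout: MultiplaneLayout,
    params: HiLoParams = HiLoParams(),
    camera: Optional[CameraModel] = None,
    nlm: Optional[NLMParams] = None,
) -> PlaneStack:
    """Split both mosaics and run the HiLo reconstruction plane by plane.

    Each plane is reconstructed independently with the shared parameters;
    the output is bit-identical to reconstructing each split tile directly.
    Errors raised by a stage are re-raised with the plane index attached.
    """
    u_stack = split_mosaic(uniform_frame, layout)
    s_stack = split_mosaic(speckle_frame, layout)
    planes = []
    for z, (u, s) in enumerate(zip(u_stack.planes, s_stack.planes)):
        try:
            planes.append(reconstruct(ImagePair(u, s, camera), params, nlm))
        except Exception as exc:
            raise RuntimeError(f"reconstruction failed for plane {z}: {exc}") from exc
    return PlaneStack(planes=tuple(planes), z_spacing_um=layout.z_spacing_um)


@dataclass(frozen=True)
class DepthProjection:
    """Depth-coded color projection plus the plain maximum-intensity projection."""

    rgb: np.ndarray
    mip: np.ndarray
    argmax: np.ndarray


def depth_coded_projection(stack: PlaneStack, cmap: str = "turbo") -> DepthProjection:
    """MIP with hue encoding the depth of the brightest plane.

    Hue is assigned from the argmax plane index through a matplotlib
    colormap (ties resolved toward the shallower plane) and brightness from
    the MIP normalized to its maximum.
    """
    import matplotlib

    arr = stack.as_array()
    mip = arr.max(axis=0)
    # np.argmax returns the first (shallowest) index on ties
    arg = arr.argmax(axis=0)
    nz = stack.n_planes
    frac = arg / (nz - 1) if nz > 1 else np.zeros_like(arg, dtype=float)
    colors = matplotlib.colormaps[cmap](frac)[..., :3]
    peak = mip.max()
    brightness = mip / peak if peak > 0 else np.zeros_like(mip)
    return DepthProjection(rgb=colors * brightness[..., None], mip=mip, argmax=arg)
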