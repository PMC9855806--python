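"""Heme-centric coordinate frame, voxelization, and occlusion masks.

Every heme-binding pocket is expressed in a local frame built from the
porphyrin: the xy-plane is the least-squares plane of the four methine
carbons (CHA, CHB, CHC, CHD), the x-axis is the in-plane projection of the
CHA->CHC vector, the z-axis is the plane normal oriented so that
CHA->CHB->CHC->CHD winds counterclockwise seen from +z, and the origin is
the methine barycenter.  Host-protein heavy atoms are then binned into a
cubic grid of binary occupancy voxels with one channel per element
(C, N, O, S).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atoms import AtomRecord, CHANNEL_ELEMENTS, METHINE_NAMES, vdw_radius
from .sites import HemeInstance, SiteSample

DEFAULT_EDGE = 24.0  # angstrom, inclusion-cube edge
DEFAULT_VOXEL = 1.0  # angstrom, voxel edge


@dataclass
class HemeFrame:
    """Rigid transform from world coordinates into the heme frame.

    ``axes`` rows are the x, y, z unit vectors (orthonormal, right-handed);
    ``origin`` is the methine barycenter in world coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed")

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.origin) @ self.axes.T

    def to_world(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.axes + self.origin


def compute_heme_frame(heme: HemeInstance) -> HemeFrame:
    """Build the porphyrin reference frame from the four methine carbons.

    Raises ``ValueError`` when the methines are degenerate (collinear or
    coincident) or CHA and CHC coincide in the plane.
    """
    try:
        pts = np.stack([heme.atom(n).coords for n in METHINE_NAMES])
    except KeyError as exc:
        raise ValueError(f"methine atom {exc} missing from heme") from exc
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, svals, vt = np.linalg.svd(centered)
    if svals[0] < 1e-9 or svals[1] < 1e-9 * svals[0]:
        raise ValueError("methine carbons are degenerate (collinear)")
    normal = vt[2]

    cha, _, chc, _ = pts
    x_raw = chc - cha
    x_in = x_raw - (x_raw @ normal) * normal
    nrm = np.linalg.norm(x_in)
    if nrm < 1e-9:
        raise ValueError("CHA->CHC vector is degenerate in the plane")
    x = x_in / nrm

    # fix the normal's sign so the methine sequence winds counterclockwise
    proj = centered - np.outer(centered @ normal, normal)
    winding = sum(
        np.cross(proj[i], proj[(i + 1) % 4]) @ normal for i in range(4)
    )
    z = normal if winding > 0 else -normal
    y = np.cross(z, x)
    return HemeFrame(origin=origin, axes=np.stack([x, y, z]))


@dataclass
class VoxelGrid:
    """Binary occupancy grid: (4, n, n, n) with channel order C, N, O, S."""

    values: np.ndarray
    edge: float = DEFAULT_EDGE
    voxel: float = DEFAULT_VOXEL
    channels: tuple[str, ...] = CHANNEL_ELEMENTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 4 or self.values.shape[0] != len(self.channels):
            raise ValueError(f"expected ({len(self.channels)}, n, n, n) values")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def voxel_centers_1d(self) -> np.ndarray:
        """Center coordinate of each voxel along one axis, in frame Å."""
        return -self.edge / 2 + (np.arange(self.n) + 0.5) * self.voxel

    def occupied_count(self) -> int:
        return int(self.values.sum())


def grid_points_per_edge(edge: float, voxel: float) -> int:
    n = int(round(edge / voxel))
    if n < 1:
        raise ValueError("edge/voxel must be >= 1")
    return n


def voxelize_site(
    site: SiteSample | Sequence[AtomRecord],
    frame: HemeFrame,
    edge: float = DEFAULT_EDGE,
    voxel: float = DEFAULT_VOXEL,
    mode: str = "center",
) -> VoxelGrid:
    """Voxelize host-protein heavy atoms in the heme frame.

    ``mode="center"`` marks a voxel occupied when an atom center falls into
    its half-open cube [low, high); ``mode="vdw"`` marks every voxel whose
    cube intersects the atom's van-der-Waals sphere.  Atoms outside the
    inclusion cube or with elements other than C/N/O/S contribute nothing.
    """
    atoms = site.protein_atoms if isinstance(site, SiteSample) else list(site)
    n = grid_points_per_edge(edge, voxel)
    values = np.zeros((len(CHANNEL_ELEMENTS), n, n, n), dtype=np.uint8)
    half = edge / 2.0
    if atoms:
        coords = frame.to_frame(np.stack([a.coords for a in atoms]))
        elements = [a.element for a in atoms]
        for ci, el in enumerate(CHANNEL_ELEMENTS):
            sel = [i for i, e in enumerate(elements) if e == el]
            if not sel:
                continue
            pts = coords[sel]
            if mode == "center":
                idx = np.floor((pts + half) / voxel).astype(int)
                ok = np.all((idx >= 0) & (idx < n), axis=1)
                # guard against centers exactly on the upper face
                ok &= np.all(pts < half, axis=1) & np.all(pts >= -half, axis=1)
                for i, j, k in idx[ok]:
                    values[ci, i, j, k] = 1
            elif mode == "vdw":
                r = vdw_radius(el)
                for p in pts:
                    lo = np.maximum(np.floor((p - r + half) / voxel).astype(int), 0)
                    hi = np.minimum(np.floor((p + r + half) / voxel).astype(int), n - 1)
                    if np.any(lo > hi):
                        continue
                    ii, jj, kk = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
                    gi, gj, gk = np.meshgrid(ii, jj, kk, indexing="ij")
                    lows = np.stack([gi, gj, gk], axis=-1) * voxel - half
                    highs = lows + voxel
                    nearest = np.clip(p, lows, highs)
                    d2 = np.sum((nearest - p) ** 2, axis=-1)
                    hit = d2 <= r * r
                    values[ci, gi[hit], gj[hit], gk[hit]] = 1
            else:
                raise ValueError(f"unknown voxelization mode {mode!r}")
    return VoxelGrid(values=values, edge=edge, voxel=voxel)


def region_keep_mask(
    n: int, edge: float, voxel: float, mode: str, r: float
) -> np.ndarray:
    """Boolean (n, n, n) mask of voxels that keep their information.

    Membership is decided by voxel-center coordinates.  ``outside`` keeps
    the inner cube of half-edge ``edge/2 - r``; ``inside`` keeps everything
    at Chebyshev distance >= ``r`` from the grid center.
    """
    if not 0 <= r < edge / 2:
        raise ValueError(f"r must satisfy 0 <= r < {edge / 2}, got {r}")
    c = -edge / 2 + (np.arange(n) + 0.5) * voxel
    cheb = np.maximum.reduce(
        np.meshgrid(np.abs(c), np.abs(c), np.abs(c), indexing="ij")
    )
    if mode == "outside":
        return cheb <= edge / 2 - r
    if mode == "inside":
        return cheb >= r
    raise ValueError(f"mode must be 'outside' or 'inside', got {mode!r}")


def discard_region(grid: VoxelGrid, mode: str, r: float) -> VoxelGrid:
    """Zero voxels outside (or inside) the occlusion cube of parameter r.

    ``r = 0`` returns an identical grid in both modes.  Channel structure is
    preserved; the input grid is not modified.
    """
    keep = region_keep_mask(grid.n, grid.edge, grid.voxel, mode, r)
    values = grid.values * keep[None].astype(np.uint8)
    return VoxelGrid(values=values, edge=grid.edge, voxel=grid.voxel, channels=grid.channels)
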