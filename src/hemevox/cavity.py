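"""Cavity bit-vectors and their group dispersion statistic.

The binding cavity of each site is sampled on a fixed 1-angstrom lattice of
points within 8.5 angstrom of the heme iron, expressed in the heme frame so
that the i-th lattice point corresponds across proteins without any
superposition.  A point scores 0 when it lies within the van-der-Waals
radius (plus optional padding) of any host-protein heavy atom, 1 otherwise
(cavity).  No isolated-point cleanup is applied.

For a group I of samples with cavity vectors v_i the dispersion is

    N_I   = |I|
    mu_I  = (1 / N_I) sum_i v_i
    d_I   = (1 / N_I) sum_i || v_i - mu_I ||     (L2 norm),

the mean distance from the barycenter; 0 exactly when all vectors agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .atoms import coords_array, vdw_radius
from .sites import SiteSample
from .voxel import HemeFrame

DEFAULT_RADIUS = 8.5  # angstrom, inclusion sphere around the iron
DEFAULT_SPACING = 1.0  # angstrom, lattice spacing


def cavity_grid_offsets(radius: float = DEFAULT_RADIUS, spacing: float = DEFAULT_SPACING) -> np.ndarray:
    """Lattice offsets (in frame coordinates, angstrom) within the sphere.

    Integer multiples of ``spacing`` enumerated in lexicographic (x, y, z)
    order over the bounding cube, kept when their norm is <= radius.  The
    enumeration is identical for every sample, which is what makes cavity
    vectors comparable element-wise.
    """
    kmax = int(np.floor(radius / spacing))
    axis = np.arange(-kmax, kmax + 1)
    pts = np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T * spacing
    keep = np.linalg.norm(pts, axis=1) <= radius
    return pts[keep]


@dataclass
class CavityVector:
    """Binary cavity fingerprint of one site on the shared lattice."""

    values: np.ndarray  # (L,) uint8; 1 = cavity, 0 = protein-occluded
    radius: float = DEFAULT_RADIUS
    spacing: float = DEFAULT_SPACING
    site_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 1:
            raise ValueError("cavity vector must be one-dimensional")


def cavity_vector(
    site: SiteSample,
    frame: HemeFrame,
    radius: float = DEFAULT_RADIUS,
    spacing: float = DEFAULT_SPACING,
    padding: float = 0.0,
) -> CavityVector:
    """Compute the cavity bit-vector of a site.

    The lattice is anchored on the iron atom; occlusion uses per-element
    van-der-Waals radii plus ``padding``.  With no protein atoms every
    point is cavity.
    """
    iron = site.heme.iron
    if iron is None:
        raise ValueError("site heme has no iron atom")
    offsets = cavity_grid_offsets(radius, spacing)
    # world position of each lattice point: iron + offset expressed in frame axes
    points = iron.coords[None, :] + offsets @ frame.axes
    values = np.ones(len(offsets), dtype=np.uint8)
    if site.protein_atoms:
        atom_xyz = coords_array(site.protein_atoms)
        radii = np.array([vdw_radius(a.element) + padding for a in site.protein_atoms])
        d = cdist(points, atom_xyz)
        occluded = (d <= radii[None, :]).any(axis=1)
        values[occluded] = 0
    return CavityVector(values=values, radius=radius, spacing=spacing, site_id=site.site_id)


@dataclass
class CavityGroupStats:
    """Dispersion of a group of cavity vectors (see module docstring)."""

    n: int
    mean_vector: np.ndarray
    distances: np.ndarray  # per-sample || v_i - mu ||

    @property
    def d_bar(self) -> float:
        return float(self.distances.mean())

    @property
    def d_sd(self) -> float:
        return float(self.distances.std())


def group_dispersion(vectors: Sequence[CavityVector | np.ndarray]) -> CavityGroupStats:
    """Mean distance from the barycenter for a group of cavity vectors."""
    if len(vectors) == 0:
        raise ValueError("group must contain at least one cavity vector")
    arrs = [v.values if isinstance(v, CavityVector) else np.asarray(v) for v in vectors]
    lengths = {a.shape for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"cavity vectors have mismatched lengths: {lengths}")
    mat = np.stack(arrs).astype(float)
    mu = mat.mean(axis=0)
    dist = np.linalg.norm(mat - mu, axis=1)
    return CavityGroupStats(n=len(arrs), mean_vector=mu, distances=dist)


def group_table(groups: dict[str, Sequence[CavityVector]]):
    """Per-group dispersion table (group, sample number, d_bar, sd)."""
    import pandas as pd

    rows = []
    for name, vecs in groups.items():
        stats = group_dispersion(list(vecs))
        rows.append(
            {"group": name, "n": stats.n, "d_bar": stats.d_bar, "d_sd": stats.d_sd}
        )
    return pd.DataFrame(rows)
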