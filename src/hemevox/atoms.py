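"""Atom records and element constants shared across the package.

Coordinates are Cartesian, in angstroms, as read from the ``atom_site``
category of PDBx/mmCIF files.  Only heavy atoms are represented; hydrogens
are discarded at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Elements that get a voxel channel, in fixed channel order.
CHANNEL_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")

#: Van der Waals radii (angstrom) used for cavity occlusion and the
#: vdW-overlap voxelization variant.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW_RADIUS: float = 1.70

#: Chemical-component identifiers of the heme variants considered.
HEME_COMPOUNDS: frozenset[str] = frozenset({"HEM", "HEA", "HEB", "HEC", "HEO"})

#: The four methine bridge carbons defining the porphyrin reference plane.
METHINE_NAMES: tuple[str, str, str, str] = ("CHA", "CHB", "CHC", "CHD")

#: The 25 heavy atoms of the Fe-porphyrin skeleton: the iron, the four
#: pyrrole nitrogens, the sixteen pyrrole carbons and the four methines.
SKELETON_NAMES: frozenset[str] = frozenset(
    ["FE", "NA", "NB", "NC", "ND", *METHINE_NAMES]
    + [f"C{i}{ring}" for ring in "ABCD" for i in range(1, 5)]
)

assert len(SKELETON_NAMES) == 25


@dataclass
class AtomRecord:
    """One heavy atom from a structure file.

    Parameters
    ----------
    atom_name : str
        Atom identifier within its residue (e.g. ``CA``, ``FE``, ``NE2``).
    element : str
        Element symbol; ``C``/``N``/``O``/``S``/``Fe`` or anything else
        verbatim.
    coords : array-like of shape (3,)
        Cartesian coordinates in angstrom.  Must be finite.
    occupancy : float
        Crystallographic occupancy in [0, 1].
    altloc_id : str
        Alternate-location identifier, empty when the atom has none.
    residue_name, residue_seq, chain_id
        Residue-level provenance.
    is_polymer : bool
        True for atoms belonging to polymer (amino-acid) residues.
    """

    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc_id: str = ""
    residue_name: str = ""
    residue_seq: int = 0
    chain_id: str = ""
    is_polymer: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element, with a carbon-like fallback."""
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


def coords_array(atoms) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) array (empty -> (0, 3))."""
    if not atoms:
        return np.zeros((0, 3))
    return np.stack([a.coords for a in atoms])
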