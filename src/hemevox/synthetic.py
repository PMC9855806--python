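"""Synthetic heme-binding sites with class-distinctive pocket geometry.

Real heme pockets differ between functional classes in where the protein
crowds the cofactor: oxygen binders keep an open distal site above the
iron, oxidoreductases pack polar residues into the distal pocket, and
electron-transport proteins bury the heme edge-on with protein on both
axial faces.  The generator emulates exactly that kind of *geometric*
signal -- an idealized planar Fe-porphyrin skeleton in a random pose, a
protein-like C/N/O/S atom cloud in a spherical shell around it, one axial
histidine nitrogen 2.1 angstrom below the iron, and a per-class motif
carving the cloud:

* ``OB-like``  -- an empty distal cone above the porphyrin plane;
* ``OR-like``  -- a crowd of O/N atoms packed into the distal pocket;
* ``ET-like``  -- both axial cones cleared and atoms concentrated into an
  equatorial band (edge-on burial);
* ``OBOR-like`` -- a narrower open cone plus moderate distal crowding.

``motif_strength`` scales every motif; at 0 all classes share one
distribution, so any classifier must fall back to chance.  Every site is
deterministic in (spec, seed).  Generated structures satisfy the
extraction filters by construction and are written in the same formats
(mmCIF plus annotation tables) the real pipeline consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atoms import AtomRecord, METHINE_NAMES
from .function import (
    AnnotationRecord,
    FunctionLabel,
    apply_manual_overrides,
    assign_function,
)
from .sites import HemeInstance, ResidueRef, SiteSample, write_site_cif
from .voxel import compute_heme_frame, voxelize_site

# idealized porphyrin radii (angstrom)
_R_N = 2.05  # pyrrole nitrogens
_R_C1 = 3.05  # alpha carbons
_R_C2 = 4.25  # beta carbons
_R_CH = 3.42  # methine bridges

_AXIAL_BOND = 2.1  # angstrom, Fe to proximal His NE2

_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

CLASS_NAMES = ("OB-like", "OR-like", "ET-like", "OBOR-like")

#: expected classification label per generator class
CLASS_LABELS = {"OB-like": "OB", "OR-like": "OR", "ET-like": "ET", "OBOR-like": "OB-OR"}


@dataclass(frozen=True)
class PocketClassSpec:
    """Geometry of one synthetic pocket class.

    ``shell_radii`` bounds the protein-like cloud (angstrom from the iron);
    ``element_mix`` gives C/N/O/S proportions; ``motif_strength`` in [0, 1]
    scales the class motif (0 erases all class differences);
    ``noise_sigma`` is isotropic positional jitter.
    """

    class_name: str
    n_atoms: int = 240
    shell_radii: tuple[float, float] = (6.0, 11.0)
    element_mix: tuple[float, float, float, float] = (0.62, 0.17, 0.19, 0.02)
    motif_strength: float = 1.0
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if self.n_atoms <= 0:
            raise ValueError("n_atoms must be positive")
        if self.shell_radii[0] >= self.shell_radii[1]:
            raise ValueError("shell inner radius must be below outer radius")
        if abs(sum(self.element_mix) - 1.0) > 1e-8:
            raise ValueError("element_mix must sum to 1")


def default_class_specs(
    classes: Sequence[str] = ("OB-like", "OR-like", "ET-like"),
    motif_strength: float = 1.0,
    seed: int = 0,
) -> list[PocketClassSpec]:
    return [
        PocketClassSpec(class_name=c, motif_strength=motif_strength, seed=seed)
        for c in classes
    ]


# ---------------------------------------------------------------------------
# porphyrin
# ---------------------------------------------------------------------------

def _porphyrin_local_atoms() -> list[tuple[str, str, np.ndarray]]:
    """(name, element, xyz) for the 25 skeleton atoms, planar, Fe at origin."""
    atoms: list[tuple[str, str, np.ndarray]] = [("FE", "Fe", np.zeros(3))]

    def polar(r: float, deg: float) -> np.ndarray:
        th = np.deg2rad(deg)
        return np.array([r * np.cos(th), r * np.sin(th), 0.0])

    methine_deg = {"CHA": 180.0, "CHB": 270.0, "CHC": 0.0, "CHD": 90.0}
    for name, deg in methine_deg.items():
        atoms.append((name, "C", polar(_R_CH, deg)))
    ring_deg = {"A": 225.0, "B": 315.0, "C": 45.0, "D": 135.0}
    for ring, deg in ring_deg.items():
        atoms.append((f"N{ring}", "N", polar(_R_N, deg)))
        atoms.append((f"C1{ring}", "C", polar(_R_C1, deg - 27.0)))
        atoms.append((f"C4{ring}", "C", polar(_R_C1, deg + 27.0)))
        atoms.append((f"C2{ring}", "C", polar(_R_C2, deg - 17.0)))
        atoms.append((f"C3{ring}", "C", polar(_R_C2, deg + 17.0)))
    return atoms


def make_porphyrin(
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    entry_id: str = "synthetic",
    chain_id: str = "X",
    residue_seq: int = 501,
) -> HemeInstance:
    """Idealized planar Fe-porphyrin skeleton under a proper rigid motion.

    The methine barycenter coincides with the iron at the (transformed)
    origin, and the CHA->CHC direction maps to the rotated +x axis, so
    the heme-frame construction recovers ``rotation`` exactly.
    """
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation must be proper (determinant +1), not a reflection")
    records = [
        AtomRecord(
            atom_name=name,
            element=el,
            coords=R @ xyz + t,
            residue_name="HEM",
            residue_seq=residue_seq,
            chain_id=chain_id,
            is_polymer=False,
        )
        for name, el, xyz in _porphyrin_local_atoms()
    ]
    return HemeInstance(compound_id="HEM", atoms=records, entry_id=entry_id)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# class motifs (all in local heme coordinates: porphyrin in z=0 plane)
# ---------------------------------------------------------------------------

def in_cone(p: np.ndarray, half_angle_deg: float, sign: int = +1) -> bool:
    """Is a local-frame point inside the axial cone about ``sign * z``?"""
    if half_angle_deg <= 0:
        return False
    r = np.linalg.norm(p)
    if r < 1e-12:
        return False
    cos_angle = sign * p[2] / r
    return cos_angle >= np.cos(np.deg2rad(half_angle_deg))


def _motif_params(spec: PocketClassSpec) -> dict:
    s = spec.motif_strength
    name = spec.class_name
    if name == "OB-like":
        return {"cone_up": 55.0 * s, "cone_down": 0.0, "crowd_frac": 0.0, "equatorial_frac": 0.0}
    if name == "OR-like":
        return {"cone_up": 0.0, "cone_down": 0.0, "crowd_frac": 0.35 * s,
                "crowd_center": np.array([0.0, 0.0, 4.5]), "crowd_radius": 2.2,
                "equatorial_frac": 0.0}
    if name == "ET-like":
        return {"cone_up": 35.0 * s, "cone_down": 35.0 * s, "crowd_frac": 0.0,
                "equatorial_frac": 0.5 * s}
    # OBOR-like: narrower open cone, with the polar crowd displaced off the
    # cone axis so the two motifs coexist
    return {"cone_up": 30.0 * s, "cone_down": 0.0, "crowd_frac": 0.20 * s,
            "crowd_center": np.array([3.2, 0.0, 3.2]), "crowd_radius": 1.8,
            "equatorial_frac": 0.0}


def _sample_shell(rng: np.random.Generator, inner: float, outer: float) -> np.ndarray:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    radius = (inner**3 + rng.random() * (outer**3 - inner**3)) ** (1.0 / 3.0)
    return u * radius


@dataclass
class SyntheticSite:
    """A generated site plus its ground truth and provenance."""

    site: SiteSample
    label: FunctionLabel
    class_name: str
    spec: PocketClassSpec
    seed: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def entry_id(self) -> str:
        return self.site.entry_id


def generate_site(spec: PocketClassSpec, seed: int, entry_id: str | None = None) -> SyntheticSite:
    """Generate one labelled synthetic site, deterministic in (spec, seed)."""
    rng = np.random.default_rng([spec.seed, seed, 1723])
    params = _motif_params(spec)
    inner, outer = spec.shell_radii

    R = random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    entry_id = entry_id or f"SYN{seed:05d}"
    heme = make_porphyrin(R, t, entry_id=entry_id, chain_id="X")

    def violates(p: np.ndarray) -> bool:
        return in_cone(p, params["cone_up"], +1) or in_cone(p, params.get("cone_down", 0.0), -1)

    n = spec.n_atoms
    n_crowd = int(round(params.get("crowd_frac", 0.0) * n))
    n_equatorial = int(round(params.get("equatorial_frac", 0.0) * n))
    n_base = n - n_crowd - n_equatorial

    local_pts: list[np.ndarray] = []
    elements: list[str] = []
    base_elements = rng.choice(list("CNOS"), size=n, p=spec.element_mix)
    for i in range(n_base):
        for _ in range(1000):
            p = _sample_shell(rng, inner, outer) + rng.normal(0, spec.noise_sigma, 3)
            if not violates(p):
                break
        else:  # pragma: no cover - motif never covers the whole shell
            raise RuntimeError("could not place atom outside motif region")
        local_pts.append(p)
        elements.append(base_elements[i])
    for i in range(n_equatorial):
        for _ in range(1000):
            u = rng.uniform(0, 2 * np.pi)
            radius = rng.uniform(7.0, 10.0)
            z = rng.uniform(-2.0, 2.0)
            p = np.array([radius * np.cos(u), radius * np.sin(u), z])
            p = p + rng.normal(0, spec.noise_sigma, 3)
            if not violates(p):
                break
        else:  # pragma: no cover
            raise RuntimeError("equatorial band conflicts with motif cones")
        local_pts.append(p)
        elements.append(base_elements[n_base + i])
    for i in range(n_crowd):
        center, cr = params["crowd_center"], params["crowd_radius"]
        for _ in range(1000):
            p = center + rng.normal(0, cr / 2.0, 3)
            # keep crowd atoms clear of the iron coordination sphere
            if (
                np.linalg.norm(p - center) <= cr
                and np.linalg.norm(p) >= 3.3
                and not violates(p)
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError("crowd region conflicts with motif cones")
        local_pts.append(p)
        elements.append("O" if rng.random() < 0.65 else "N")

    # axial histidine nitrogen on the proximal (-z) face
    axial_local = np.array([0.0, 0.0, -_AXIAL_BOND])

    protein_atoms: list[AtomRecord] = []
    aa_choices = rng.choice(_AMINO_ACIDS, size=len(local_pts))
    for i, (p, el) in enumerate(zip(local_pts, elements)):
        protein_atoms.append(
            AtomRecord(
                atom_name=f"{el}1",
                element=el,
                coords=R @ p + t,
                residue_name=str(aa_choices[i]),
                residue_seq=i + 1,
                chain_id="A",
                is_polymer=True,
            )
        )
    axial_seq = len(local_pts) + 1
    protein_atoms.append(
        AtomRecord(
            atom_name="NE2",
            element="N",
            coords=R @ axial_local + t,
            residue_name="HIS",
            residue_seq=axial_seq,
            chain_id="A",
            is_polymer=True,
        )
    )

    site = SiteSample(
        heme=heme,
        protein_atoms=protein_atoms,
        axial_ligands=[ResidueRef("A", axial_seq, "HIS")],
        entry_id=entry_id,
        chain_ids=["A"],
    )
    label = _ground_truth_label(spec.class_name)
    return SyntheticSite(
        site=site, label=label, class_name=spec.class_name, spec=spec, seed=seed,
        rotation=R, translation=t,
    )


def _ground_truth_label(class_name: str) -> FunctionLabel:
    ann = class_annotation("?", class_name)
    label = assign_function([ann], axial_chains=["A"])
    return apply_manual_overrides(label, ann.description)


def class_annotation(entry_id: str, class_name: str) -> AnnotationRecord:
    """Annotation row whose cascade result reproduces the class label."""
    if class_name == "OB-like":
        return AnnotationRecord(entry_id, "A", go_terms=("oxygen binding",),
                                description="synthetic oxygen-binding globin pocket")
    if class_name == "OR-like":
        return AnnotationRecord(entry_id, "A", ec_numbers=("1.11.1.7",),
                                description="synthetic peroxidase pocket")
    if class_name == "ET-like":
        return AnnotationRecord(entry_id, "A", go_terms=("electron transfer activity",),
                                description="synthetic cytochrome pocket")
    if class_name == "OBOR-like":
        return AnnotationRecord(entry_id, "A", ec_numbers=("1.11.1.7",),
                                description="synthetic dehaloperoxidase pocket")
    raise ValueError(f"unknown class {class_name!r}")


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    sites: list[SyntheticSite]
    annotations: list[AnnotationRecord]
    labels: pd.DataFrame

    @property
    def class_names(self) -> list[str]:
        return [s.label.class_name for s in self.sites]


def generate_dataset(
    specs: Sequence[PocketClassSpec],
    n_per_class: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a labelled multi-class dataset.

    When ``out_dir`` is given, per-site mmCIF files plus ``annotations.csv``
    and ``labels.csv`` are written so the extraction and labelling modules
    can be exercised end to end on disk formats.
    """
    if len(specs) < 2:
        raise ValueError("need at least two pocket classes")
    if n_per_class < 5:
        warnings.warn("fewer than 5 samples per class cannot support 5-fold CV")
    master = np.random.default_rng(seed)
    sites: list[SyntheticSite] = []
    annotations: list[AnnotationRecord] = []
    rows = []
    for ci, spec in enumerate(specs):
        site_seeds = master.integers(2**31, size=n_per_class)
        for i, s in enumerate(site_seeds):
            entry_id = f"S{ci}{i:04d}"
            synth = generate_site(spec, int(s), entry_id=entry_id)
            sites.append(synth)
            annotations.append(class_annotation(entry_id, spec.class_name))
            rows.append(
                {
                    "entry_id": entry_id,
                    "site_id": synth.site.site_id,
                    "class": synth.label.class_name,
                    "functions": ";".join(sorted(synth.label.functions)),
                }
            )
    labels = pd.DataFrame(rows)
    dataset = SyntheticDataset(sites=sites, annotations=annotations, labels=labels)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for synth in sites:
            atoms = synth.site.heme.atoms + synth.site.protein_atoms
            write_site_cif(atoms, out / f"{synth.entry_id}.cif", entry_id=synth.entry_id)
        ann_rows = [
            {
                "entry_id": a.entry_id,
                "chain_id": a.chain_id,
                "ec": ";".join(a.ec_numbers),
                "go": ";".join(a.go_terms),
                "keywords": ";".join(a.keywords),
                "description": a.description,
            }
            for a in annotations
        ]
        pd.DataFrame(ann_rows).to_csv(out / "annotations.csv", index=False)
        labels.to_csv(out / "labels.csv", index=False)
    return dataset


def stack_voxels(
    sites: Sequence[SyntheticSite | SiteSample],
    edge: float = 24.0,
    voxel: float = 1.0,
) -> np.ndarray:
    """Voxelize sites in their own heme frames into one (m, 4, n, n, n) array."""
    grids = []
    for s in sites:
        sample = s.site if isinstance(s, SyntheticSite) else s
        frame = compute_heme_frame(sample.heme)
        grids.append(voxelize_site(sample, frame, edge=edge, voxel=voxel).values)
    return np.stack(grids)
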