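"""Extraction of heme-binding sites from structure files.

The pipeline reads PDBx/mmCIF files, resolves alternate locations by
occupancy, locates Fe-porphyrin cofactors, and applies four filters before a
site enters the dataset:

1. skeleton completeness -- all 25 heavy atoms of the Fe-porphyrin core
   must be present exactly once;
2. axial coordination -- at least one amino-acid residue or water must have
   an atom within 3.1 angstrom of the iron;
3. heme coverage -- the fraction of heme heavy atoms contacted by the host
   protein must not fall below a threshold (default 0.6), which screens out
   sites whose biological environment is incomplete in the asymmetric unit;
4. sequence redundancy -- a greedy filter drops chains whose global pairwise
   identity to an already-kept chain exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atoms import (
    AtomRecord,
    HEME_COMPOUNDS,
    SKELETON_NAMES,
    coords_array,
)

WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})

DEFAULT_AXIAL_CUTOFF = 3.1  # angstrom, Fe to ligand atom, inclusive
DEFAULT_CONTACT_CUTOFF = 5.0  # angstrom, heme atom to protein atom
DEFAULT_COVERAGE_MIN = 0.6


class ResidueRef(NamedTuple):
    """Lightweight reference to a residue or small molecule."""

    chain_id: str
    residue_seq: int
    residue_name: str


@dataclass
class HemeInstance:
    """One heme cofactor: its atoms and the iron centre."""

    compound_id: str
    atoms: list[AtomRecord]
    entry_id: str = ""

    def __post_init__(self) -> None:
        if self.compound_id not in HEME_COMPOUNDS:
            raise ValueError(f"unknown heme compound {self.compound_id!r}")

    @property
    def iron(self) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == "FE":
                return a
        return None

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return self.atoms[0].residue_key


@dataclass
class SiteSample:
    """A heme instance together with its host-protein environment.

    ``protein_atoms`` holds heavy atoms of polymer residues only; waters and
    other non-protein molecules live in ``nonprotein_atoms`` and are used
    solely for axial-ligand detection, never for voxelization.
    """

    heme: HemeInstance
    protein_atoms: list[AtomRecord]
    axial_ligands: list[ResidueRef] = field(default_factory=list)
    entry_id: str = ""
    chain_ids: list[str] = field(default_factory=list)
    nonprotein_atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def site_id(self) -> str:
        ch, seq, name = self.heme.residue_key
        return f"{self.entry_id}_{ch}{seq}_{name}"


# ---------------------------------------------------------------------------
# altloc / occupancy selection
# ---------------------------------------------------------------------------

def _altloc_rank(atom: AtomRecord) -> tuple[float, str]:
    # Largest occupancy wins; on ties the lexicographically smallest altloc
    # wins, which reduces to "keep altloc A" for the common A/B 0.5 case.
    return (-atom.occupancy, atom.altloc_id)


def resolve_altlocs(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Keep one record per (chain, residue, atom name).

    Among duplicates the atom with the largest occupancy is selected; at
    equal occupancy (e.g. two 0.5 conformers) the smallest alternate-location
    identifier wins.  Idempotent, order-preserving on first occurrence.
    """
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for a in atoms:
        key = (a.chain_id, a.residue_seq, a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif _altloc_rank(a) < _altloc_rank(cur):
            best[key] = a
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def check_skeleton_complete(heme: HemeInstance) -> bool:
    """True iff each of the 25 skeleton atom names occurs exactly once."""
    counts: dict[str, int] = {}
    for a in heme.atoms:
        counts[a.atom_name] = counts.get(a.atom_name, 0) + 1
    return all(counts.get(name, 0) == 1 for name in SKELETON_NAMES)


def find_axial_ligands(
    site: SiteSample, cutoff: float = DEFAULT_AXIAL_CUTOFF
) -> list[ResidueRef]:
    """Residues or molecules with >= 1 atom within ``cutoff`` of the iron.

    The boundary is inclusive.  The heme's own atoms never count.  Returns
    an empty list when nothing coordinates the iron.
    """
    iron = site.heme.iron
    if iron is None:
        return []
    found: list[ResidueRef] = []
    seen: set[tuple[str, int, str]] = set()
    heme_key = site.heme.residue_key
    for a in site.protein_atoms + site.nonprotein_atoms:
        key = a.residue_key
        if key == heme_key or key in seen:
            continue
        if np.linalg.norm(a.coords - iron.coords) <= cutoff:
            seen.add(key)
            found.append(ResidueRef(*key))
    return found


def is_valid_axial_ligand(ref: ResidueRef) -> bool:
    """Amino-acid residues and waters qualify as axial ligands."""
    if ref.residue_name in WATER_NAMES:
        return True
    import gemmi

    info = gemmi.find_tabulated_residue(ref.residue_name)
    return info is not None and info.is_amino_acid()


def compute_heme_coverage(
    site: SiteSample, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> float:
    """Fraction of heme heavy atoms with a host-protein atom within cutoff.

    This is a contact-based proxy for how much of the cofactor is buried by
    the protein; fully exposed hemes (e.g. from a mismatched asymmetric
    unit) score low.  Monotone non-decreasing in ``contact_cutoff``.
    """
    if not site.protein_atoms or not site.heme.atoms:
        return 0.0
    tree = cKDTree(coords_array(site.protein_atoms))
    dists, _ = tree.query(coords_array(site.heme.atoms), k=1)
    return float(np.mean(dists <= contact_cutoff))


# ---------------------------------------------------------------------------
# sequence redundancy
# ---------------------------------------------------------------------------

_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in percent.

    Identity is the number of identical aligned positions divided by the
    length of the shorter sequence, times 100.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 100.0
    aln = _aligner().align(a, b)[0]
    identities = aln.counts().identities
    return 100.0 * identities / min(len(a), len(b))


def filter_redundant_chains(
    sequences: Sequence[tuple[str, str]], identity_threshold: float
) -> list[str]:
    """Greedy redundancy filter over (id, sequence) pairs in input order.

    A sequence is dropped when its pairwise identity to any already-kept
    sequence exceeds ``identity_threshold`` (percent).  Returns the kept ids
    in input order; the kept set never contains a pair above the threshold.
    """
    kept: list[tuple[str, str]] = []
    for sid, seq in sequences:
        if all(pairwise_identity(seq, ks) <= identity_threshold for _, ks in kept):
            kept.append((sid, seq))
    return [sid for sid, _ in kept]


# ---------------------------------------------------------------------------
# mmCIF I/O (gemmi-backed)
# ---------------------------------------------------------------------------

_ONE_LETTER_CACHE: dict[str, str] = {}


def _one_letter(residue_name: str) -> str:
    code = _ONE_LETTER_CACHE.get(residue_name)
    if code is None:
        import gemmi

        info = gemmi.find_tabulated_residue(residue_name)
        code = info.one_letter_code.upper() if info else "X"
        if not code.isalpha():
            code = "X"
        _ONE_LETTER_CACHE[residue_name] = code
    return code


def read_structure_atoms(path: str | Path, model_num: int = 1) -> tuple[str, list[AtomRecord]]:
    """Parse one mmCIF (or PDB) file into heavy-atom records.

    Only the requested model is read (the first one when the numbering does
    not match); hydrogens are discarded; occupancies are clamped to [0, 1].
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    model = st[0]
    for m in st:
        if getattr(m, "num", None) == model_num:
            model = m
            break
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_poly = bool(info is not None and info.is_amino_acid())
            for atom in res:
                el = atom.element.name
                if el in ("H", "D"):
                    continue
                alt = atom.altloc if atom.altloc and atom.altloc != "\x00" else ""
                records.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=el,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=float(min(max(atom.occ, 0.0), 1.0)),
                        altloc_id=alt,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain_id=chain.name,
                        is_polymer=is_poly,
                    )
                )
    return st.name or Path(path).stem, records


def write_site_cif(atoms: Sequence[AtomRecord], path: str | Path, entry_id: str = "site") -> None:
    """Write atom records to a minimal mmCIF file."""
    import gemmi

    st = gemmi.Structure()
    st.name = entry_id
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for a in atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == a.residue_seq and last.name == a.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, " ")
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coords)
        atom.occ = a.occupancy
        if a.altloc_id:
            atom.altloc = a.altloc_id
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def chain_sequences(atoms: Sequence[AtomRecord]) -> dict[str, str]:
    """One-letter sequences of the polymer chains, in residue order."""
    seqs: dict[str, list[str]] = {}
    seen: set[tuple[str, int, str]] = set()
    for a in atoms:
        if not a.is_polymer:
            continue
        key = a.residue_key
        if key in seen:
            continue
        seen.add(key)
        seqs.setdefault(a.chain_id, []).append(_one_letter(a.residue_name))
    return {ch: "".join(letters) for ch, letters in seqs.items()}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def find_hemes(atoms: Sequence[AtomRecord], entry_id: str = "") -> list[HemeInstance]:
    """Group heme-compound atoms into cofactor instances."""
    groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
    order: list[tuple[str, int, str]] = []
    for a in atoms:
        if a.residue_name in HEME_COMPOUNDS:
            key = a.residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
    return [
        HemeInstance(compound_id=key[2], atoms=groups[key], entry_id=entry_id)
        for key in order
    ]


@dataclass
class ExtractionResult:
    """Sites that passed all filters plus a per-candidate audit table."""

    sites: list[SiteSample]
    table: pd.DataFrame


def build_sites(entry_id: str, atoms: Sequence[AtomRecord]) -> list[SiteSample]:
    """Partition one entry's resolved atoms into per-heme site samples."""
    resolved = resolve_altlocs(atoms)
    hemes = find_hemes(resolved, entry_id)
    heme_keys = {h.residue_key for h in hemes}
    protein = [a for a in resolved if a.is_polymer]
    chain_ids = sorted({a.chain_id for a in protein})
    sites = []
    for heme in hemes:
        other = [
            a
            for a in resolved
            if not a.is_polymer and a.residue_key not in heme_keys
        ]
        # other hemes of the entry are non-protein molecules for this site
        other += [
            a
            for h in hemes
            if h.residue_key != heme.residue_key
            for a in h.atoms
        ]
        sites.append(
            SiteSample(
                heme=heme,
                protein_atoms=protein,
                entry_id=entry_id,
                chain_ids=chain_ids,
                nonprotein_atoms=other,
            )
        )
    return sites


def extract_dataset(
    entries: Iterable[tuple[str, Sequence[AtomRecord]]],
    axial_cutoff: float = DEFAULT_AXIAL_CUTOFF,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    identity_threshold: float | None = 99.99,
) -> ExtractionResult:
    """Run the full extraction cascade over parsed entries.

    Parameters mirror the command line: the axial-ligand cutoff (inclusive),
    the coverage contact cutoff and minimum (sites strictly below are
    dropped), and the greedy sequence-identity threshold in percent
    (``None`` disables the redundancy filter).
    """
    candidates: list[tuple[SiteSample, dict]] = []
    all_sequences: list[tuple[str, str]] = []
    for entry_id, atoms in entries:
        sites = build_sites(entry_id, atoms)
        for ch, seq in sorted(chain_sequences(atoms).items()):
            all_sequences.append((f"{entry_id}:{ch}", seq))
        for site in sites:
            complete = check_skeleton_complete(site.heme)
            axial: list[ResidueRef] = []
            axial_ok = False
            coverage = float("nan")
            coverage_ok = False
            if complete:
                axial = find_axial_ligands(site, cutoff=axial_cutoff)
                site.axial_ligands = axial
                axial_ok = any(is_valid_axial_ligand(r) for r in axial)
                coverage = compute_heme_coverage(site, contact_cutoff=contact_cutoff)
                coverage_ok = coverage >= coverage_min
            row = {
                "site_id": site.site_id,
                "entry_id": entry_id,
                "compound_id": site.heme.compound_id,
                "skeleton_complete": complete,
                "axial_ligands": ";".join(
                    f"{r.chain_id}{r.residue_seq}{r.residue_name}" for r in axial
                ),
                "axial_ok": axial_ok,
                "coverage": coverage,
                "coverage_ok": coverage_ok,
            }
            candidates.append((site, row))

    kept_chains: set[str] | None = None
    if identity_threshold is not None:
        kept_chains = set(filter_redundant_chains(all_sequences, identity_threshold))

    kept_sites: list[SiteSample] = []
    rows = []
    for site, row in candidates:
        if kept_chains is None:
            redundant_ok = True
        else:
            redundant_ok = all(
                f"{site.entry_id}:{ch}" in kept_chains for ch in site.chain_ids
            )
        row["nonredundant"] = redundant_ok
        passed = (
            row["skeleton_complete"]
            and row["axial_ok"]
            and row["coverage_ok"]
            and redundant_ok
        )
        row["kept"] = passed
        rows.append(row)
        if passed:
            kept_sites.append(site)
    return ExtractionResult(sites=kept_sites, table=pd.DataFrame(rows))
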