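"""Site extraction: altloc selection, skeleton, axial ligands, coverage,
sequence redundancy and mmCIF round trips."""

from __future__ import annotations

import numpy as np
import pytest

import hemevox as hv
from hemevox.sites import (
    build_sites,
    chain_sequences,
    pairwise_identity,
    read_structure_atoms,
    write_site_cif,
)

from conftest import make_toy_site


def _atom(name="CA", occ=1.0, alt="", seq=1, chain="A", coords=(0, 0, 0), element="C"):
    return hv.AtomRecord(
        atom_name=name, element=element, coords=np.array(coords, float),
        occupancy=occ, altloc_id=alt, residue_name="ALA", residue_seq=seq,
        chain_id=chain, is_polymer=True,
    )


class TestResolveAltlocs:
    def test_largest_occupancy_wins(self):
        a = _atom(occ=0.7, alt="B")
        b = _atom(occ=0.3, alt="A")
        out = hv.resolve_altlocs([a, b])
        assert out == [a]

    def test_no_altlocs_identity(self):
        atoms = [_atom(name=n) for n in ("N", "CA", "C", "O")]
        assert hv.resolve_altlocs(atoms) == atoms

    def test_half_occupancy_prefers_altloc_a(self):
        a = _atom(occ=0.5, alt="B", coords=(1, 0, 0))
        b = _atom(occ=0.5, alt="A", coords=(2, 0, 0))
        out = hv.resolve_altlocs([a, b])
        assert out == [b]

    def test_equal_occupancy_tie_break_smallest_altloc(self):
        # tie at a non-0.5 occupancy: deterministic, no exception
        a = _atom(occ=0.4, alt="C")
        b = _atom(occ=0.4, alt="B")
        out = hv.resolve_altlocs([a, b])
        assert out == [b]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        atoms = [
            _atom(name=f"A{i % 5}", seq=i % 3, occ=float(rng.choice([0.3, 0.5, 1.0])),
                  alt=str(rng.choice(["", "A", "B"])))
            for i in range(40)
        ]
        once = hv.resolve_altlocs(atoms)
        assert hv.resolve_altlocs(once) == once

    def test_distinct_atoms_untouched(self):
        atoms = [_atom(name="CA", seq=1), _atom(name="CA", seq=2), _atom(name="CB", seq=1)]
        assert len(hv.resolve_altlocs(atoms)) == 3


class TestSkeleton:
    def test_complete_porphyrin(self):
        assert hv.check_skeleton_complete(hv.make_porphyrin())

    def test_missing_methine(self):
        heme = hv.make_porphyrin()
        heme.atoms = [a for a in heme.atoms if a.atom_name != "CHA"]
        assert not hv.check_skeleton_complete(heme)

    def test_duplicate_and_missing(self):
        heme = hv.make_porphyrin()
        chb = heme.atom("CHB")
        heme.atoms = [a for a in heme.atoms if a.atom_name != "CHC"] + [chb]
        assert len(heme.atoms) == 25
        assert not hv.check_skeleton_complete(heme)

    def test_invariant_under_reordering_and_rigid_motion(self):
        rng = np.random.default_rng(3)
        from hemevox.synthetic import random_rotation

        heme = hv.make_porphyrin(random_rotation(rng), rng.uniform(-9, 9, 3))
        rng.shuffle(heme.atoms)
        assert hv.check_skeleton_complete(heme)


class TestAxialLigands:
    def _site_with_atom_at(self, dist):
        heme = hv.make_porphyrin()
        atom = hv.AtomRecord(
            atom_name="NE2", element="N", coords=np.array([0.0, 0.0, dist]),
            residue_name="HIS", residue_seq=9, chain_id="A", is_polymer=True,
        )
        return hv.SiteSample(heme=heme, protein_atoms=[atom], entry_id="T")

    def test_inside_cutoff(self):
        refs = hv.find_axial_ligands(self._site_with_atom_at(2.1))
        assert refs == [hv.ResidueRef("A", 9, "HIS")]

    def test_outside_cutoff(self):
        assert hv.find_axial_ligands(self._site_with_atom_at(3.2)) == []

    def test_boundary_inclusive(self):
        # brute-force check of the boundary convention: exactly 3.1 A counts
        site = self._site_with_atom_at(3.1)
        iron = site.heme.iron
        d = np.linalg.norm(site.protein_atoms[0].coords - iron.coords)
        assert d == pytest.approx(3.1)
        assert hv.find_axial_ligands(site, cutoff=3.1) == [hv.ResidueRef("A", 9, "HIS")]

    def test_water_counts_but_heme_does_not(self):
        heme = hv.make_porphyrin()
        water = hv.AtomRecord(
            atom_name="O", element="O", coords=np.array([0.0, 0.0, 2.4]),
            residue_name="HOH", residue_seq=301, chain_id="W", is_polymer=False,
        )
        site = hv.SiteSample(heme=heme, protein_atoms=[], nonprotein_atoms=[water], entry_id="T")
        assert hv.find_axial_ligands(site) == [hv.ResidueRef("W", 301, "HOH")]


class TestCoverage:
    def test_empty_environment(self):
        site = hv.SiteSample(heme=hv.make_porphyrin(), protein_atoms=[], entry_id="T")
        assert hv.compute_heme_coverage(site) == 0.0

    def test_full_burial(self):
        heme = hv.make_porphyrin()
        atoms = [
            hv.AtomRecord(atom_name="C1", element="C", coords=a.coords + [0, 0, 3.0],
                          residue_name="GLY", residue_seq=i + 1, chain_id="A", is_polymer=True)
            for i, a in enumerate(heme.atoms)
        ]
        site = hv.SiteSample(heme=heme, protein_atoms=atoms, entry_id="T")
        assert hv.compute_heme_coverage(site, contact_cutoff=5.0) == 1.0

    def test_fifteen_of_twentyfive_is_0_6(self):
        # protein atoms placed exactly on 15 skeleton atoms; with a tight
        # cutoff no other heme atom is within reach (min heme-atom spacing
        # exceeds it), so coverage is exactly 15/25
        heme = hv.make_porphyrin()
        chosen = heme.atoms[:15]
        atoms = [
            hv.AtomRecord(atom_name="C1", element="C", coords=a.coords.copy(),
                          residue_name="GLY", residue_seq=i + 1, chain_id="A", is_polymer=True)
            for i, a in enumerate(chosen)
        ]
        site = hv.SiteSample(heme=heme, protein_atoms=atoms, entry_id="T")
        assert hv.compute_heme_coverage(site, contact_cutoff=0.5) == pytest.approx(0.6)

    def test_monotone_in_cutoff(self):
        site = make_toy_site(seed=5)
        values = [hv.compute_heme_coverage(site, c) for c in (1.0, 2.0, 4.0, 6.0, 10.0)]
        assert values == sorted(values)


class TestRedundancyFilter:
    def test_exact_duplicate_dropped(self):
        kept = hv.filter_redundant_chains([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL")], 99.99)
        assert kept == ["a"]

    def test_dissimilar_kept(self):
        kept = hv.filter_redundant_chains([("a", "ACDEFGHIKL"), ("b", "PQRSTVWYMN")], 99.99)
        assert kept == ["a", "b"]

    def test_low_threshold_keeps_one_of_related_triple(self):
        s1 = "ACDEFGHIKL"
        s2 = s1
        s3 = "ACDPQRSTVW"  # shares only the ACD prefix with s1
        assert pairwise_identity(s1, s2) == pytest.approx(100.0)
        assert pairwise_identity(s1, s3) == pytest.approx(30.0)
        assert pairwise_identity(s2, s3) == pytest.approx(30.0)
        kept = hv.filter_redundant_chains([("a", s1), ("b", s2), ("c", s3)], 25.00)
        assert kept == ["a"]

    def test_kept_set_never_exceeds_threshold(self):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = []
        base = rng.choice(alphabet, size=30)
        for i in range(8):
            s = base.copy()
            n_mut = rng.integers(0, 30)
            pos = rng.choice(30, size=n_mut, replace=False)
            s[pos] = rng.choice(alphabet, size=n_mut)
            seqs.append((f"s{i}", "".join(s)))
        for threshold in (40.0, 80.0, 99.99):
            kept = hv.filter_redundant_chains(seqs, threshold)
            kept_seqs = dict(seqs)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert pairwise_identity(kept_seqs[a], kept_seqs[b]) <= threshold

    def test_empty_input(self):
        assert hv.filter_redundant_chains([], 99.99) == []


class TestStructureIO:
    def test_cif_round_trip(self, tmp_path):
        site = make_toy_site(seed=2, n_atoms=20)
        atoms = site.heme.atoms + site.protein_atoms
        path = tmp_path / "toy.cif"
        write_site_cif(atoms, path, entry_id="TOY2")
        entry_id, back = read_structure_atoms(path)
        assert entry_id == "TOY2"
        assert len(back) == len(atoms)
        orig = {(a.chain_id, a.residue_seq, a.atom_name): a for a in atoms}
        for a in back:
            ref = orig[(a.chain_id, a.residue_seq, a.atom_name)]
            assert np.allclose(a.coords, ref.coords, atol=1e-3)
            assert a.element == ref.element
            assert a.is_polymer == ref.is_polymer

    def test_build_sites_partitions_atoms(self, tmp_path):
        site = make_toy_site(seed=3, n_atoms=15)
        water = hv.AtomRecord(atom_name="O", element="O", coords=np.array([9.0, 9, 9]),
                              residue_name="HOH", residue_seq=500, chain_id="W")
        atoms = site.heme.atoms + site.protein_atoms + [water]
        sites = build_sites("T3", atoms)
        assert len(sites) == 1
        s = sites[0]
        assert len(s.protein_atoms) == 15
        assert [a.residue_name for a in s.nonprotein_atoms] == ["HOH"]
        assert hv.check_skeleton_complete(s.heme)

    def test_chain_sequences(self):
        site = make_toy_site(seed=4, n_atoms=6)
        seqs = chain_sequences(site.protein_atoms)
        assert list(seqs) == ["A"]
        assert seqs["A"] == "GGGGGG"


class TestAltlocProperties:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["N", "CA", "C"]), st.integers(1, 3),
                              st.sampled_from([0.3, 0.5, 0.7, 1.0]),
                              st.sampled_from(["", "A", "B", "C"])), max_size=20))
    def test_idempotent_and_unique_keys(self, records):
        atoms = [_atom(name=n, seq=s, occ=o, alt=a) for n, s, o, a in records]
        once = hv.resolve_altlocs(atoms)
        assert hv.resolve_altlocs(once) == once
        keys = [(a.chain_id, a.residue_seq, a.atom_name) for a in once]
        assert len(keys) == len(set(keys))
        # selected occupancy is maximal within each duplicate group
        for a in once:
            group = [b for b in atoms if (b.chain_id, b.residue_seq, b.atom_name)
                     == (a.chain_id, a.residue_seq, a.atom_name)]
            assert a.occupancy == max(b.occupancy for b in group)
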