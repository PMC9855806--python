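"""Shared fixtures: toy sites, small synthetic datasets, tiny CV runs."""

from __future__ import annotations

import numpy as np
import pytest

import hemevox as hv
from hemevox.model import TrainConfig, cross_validate


def make_toy_site(
    seed: int = 0,
    n_atoms: int = 60,
    spread: float = 10.0,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> hv.SiteSample:
    """A porphyrin plus a random unstructured atom cloud (no class motif)."""
    rng = np.random.default_rng(seed)
    heme = hv.make_porphyrin(rotation, translation)
    R = np.eye(3) if rotation is None else rotation
    t = np.zeros(3) if translation is None else translation
    elements = rng.choice(list("CNOS"), size=n_atoms, p=[0.6, 0.17, 0.18, 0.05])
    atoms = []
    for i in range(n_atoms):
        local = rng.uniform(-spread, spread, 3)
        atoms.append(
            hv.AtomRecord(
                atom_name=f"{elements[i]}1",
                element=str(elements[i]),
                coords=R @ local + t,
                residue_name="GLY",
                residue_seq=i + 1,
                chain_id="A",
                is_polymer=True,
            )
        )
    return hv.SiteSample(heme=heme, protein_atoms=atoms, entry_id=f"TOY{seed}", chain_ids=["A"])


@pytest.fixture(scope="session")
def toy_site() -> hv.SiteSample:
    return make_toy_site(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """3-class synthetic dataset, 8 sites per class, coarse voxels."""
    specs = hv.default_class_specs(("OB-like", "OR-like", "ET-like"), seed=0)
    ds = hv.generate_dataset(specs, n_per_class=8, seed=0)
    X = hv.stack_voxels(ds.sites, edge=24.0, voxel=3.0)
    return ds, X


@pytest.fixture(scope="session")
def tiny_cv_run(small_dataset):
    """A fast cross-validation run with narrow channels (plumbing tests)."""
    ds, X = small_dataset
    run = cross_validate(
        X,
        ds.class_names,
        scheme="three-label",
        config=TrainConfig(epochs=2, seed=0),
        conv_channels=(6, 8, 8),
    )
    return run, X
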