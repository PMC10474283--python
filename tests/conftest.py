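"""Shared fixtures: small synthetic structures and ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from hingescape import Ensemble, Structure
from hingescape.synthetic import HingeEnsembleSpec, make_hinge_ensemble, hinge_topology


def make_random_structure(rng: np.random.Generator, n_atoms: int = 30,
                          atoms_per_residue: int = 3) -> Structure:
    """A random protein-like structure: ALA chain, C/N/O atoms, spread ~20 Å."""
    elements = ["N", "C", "O"]
    names = ["N", "CA", "O"]
    return Structure(
        serial=np.arange(1, n_atoms + 1),
        atom_name=[names[i % atoms_per_residue] for i in range(n_atoms)],
        element=[elements[i % atoms_per_residue] for i in range(n_atoms)],
        residue_name=["ALA"] * n_atoms,
        residue_id=[1 + i // atoms_per_residue for i in range(n_atoms)],
        chain_id=["A"] * n_atoms,
        coords=rng.uniform(-10.0, 10.0, size=(n_atoms, 3)),
    )


def make_random_ensemble(rng: np.random.Generator, n_frames: int = 5,
                         n_atoms: int = 30) -> Ensemble:
    top = make_random_structure(rng, n_atoms)
    coords = top.coords[None, :, :] + rng.normal(0, 1.0, size=(n_frames, n_atoms, 3))
    return Ensemble(topology=top, coords=coords,
                    times=np.arange(n_frames, dtype=float))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture(scope="session")
def hinge_top():
    return hinge_topology()


@pytest.fixture(scope="session")
def small_hinge():
    """300-frame two-state hinge ensemble with ground truth (study defaults
    otherwise: 85°/118°, weights 0.7/0.3, 3° spread, 0.3 Å noise)."""
    spec = HingeEnsembleSpec(n_frames=300, seed=11)
    return make_hinge_ensemble(spec)
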