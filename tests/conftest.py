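import numpy as np
import pytest

from kinetree.ligand_tree import (
    build_template,
    build_tree,
    bundled_phosphines,
    canonicalize,
    encode_graph,
)
from kinetree.synthetic import GenerativeTruth, generate_ligand_set, generate_reaction_dataset
from kinetree.training import build_dataset


@pytest.fixture(scope="session")
def phosphines():
    """The nine bundled reference phosphine trees, canonicalized."""
    return [canonicalize(t) for t in bundled_phosphines()]


@pytest.fixture(scope="session")
def phosphine_template(phosphines):
    return build_template(phosphines)


@pytest.fixture(scope="session")
def small_graphs(phosphines, phosphine_template):
    return [encode_graph(t, phosphine_template) for t in phosphines]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 ligands x 10 substrates, noiseless: exactly solvable toy."""
    ligands = generate_ligand_set(2, branching_law="minimal", seed=0)
    truth = GenerativeTruth(noise_sd=0.0)
    subs = [("NH2", "para"), ("OMe", "para"), ("Me", "para"), ("H", "para"),
            ("F", "para"), ("Cl", "para"), ("CF3", "para"), ("CN", "para"),
            ("NO2", "para"), ("Cl", "meta")]
    synth = generate_reaction_dataset(ligands, substrates=subs, truth=truth, seed=0)
    return build_dataset(synth.reactions, ligands), synth


@pytest.fixture(scope="session")
def factorial_dataset():
    """17 x 20 synthetic design with the default generator settings."""
    ligands = generate_ligand_set(17, seed=11)
    synth = generate_reaction_dataset(ligands, seed=12)
    return build_dataset(synth.reactions, ligands), synth


def make_pme3():
    return build_tree(["methyl", "methyl", "methyl"], name="PMe3")


def make_pet3():
    return build_tree(["ethyl", "ethyl", "ethyl"], name="PEt3")
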