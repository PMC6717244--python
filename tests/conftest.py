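"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xtalface.structure import Atom, Chain, Residue, Structure
from xtalface.synthetic import DatasetSpec, make_labeled_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def single_atom_structure(element="C", coord=(0.0, 0.0, 0.0)):
    return Structure([Chain("A", [Residue(
        "ALA", 1, "", [Atom("CA", element, np.asarray(coord, float))])])])


def make_residue(name, number, center, icode="", with_cb=True):
    """A compact residue with full main chain around ``center``."""
    c = np.asarray(center, float)
    atoms = [
        Atom("N", "N", c + [-1.2, -0.6, 0.0]),
        Atom("CA", "C", c.copy()),
        Atom("C", "C", c + [1.2, -0.6, 0.3]),
        Atom("O", "O", c + [1.2, -1.8, 0.3]),
    ]
    if with_cb and name != "GLY":
        atoms.append(Atom("CB", "C", c + [0.0, 1.53, 0.0]))
    return Residue(name, number, icode, atoms)


@pytest.fixture(scope="session")
def default_dataset():
    """The default end-to-end synthetic dataset: 20 biological interfaces
    with planted contact-column couplings and 20 crystallographic ones
    without (60-residue chains, 1500-sequence alignments)."""
    dataset, manifest = make_labeled_dataset(DatasetSpec(seed=11))
    return dataset, manifest
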