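import numpy as np
import pytest
from hypothesis import settings

# reproducible property tests: derive examples from the test body, not a
# per-run random seed or an example database
settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")

from ppmoens.io_formats import ATOMIC_MASSES, Conformer, PPMOSequence
from ppmoens.synthetic_data import GeneratorConfig, gen_ensemble


def make_conformer(positions, names=None, elements=None, residue_indices=None,
                   residue_kinds=None, masses=None):
    """Minimal conformer from raw arrays, defaulting to single-residue C atoms."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    elements = np.array(elements if elements is not None else ["C"] * n)
    names = np.array(names if names is not None else [f"C{i}" for i in range(n)])
    residue_indices = np.array(residue_indices if residue_indices is not None
                               else [1] * n)
    residue_kinds = np.array(residue_kinds if residue_kinds is not None
                             else ["nucleotide"] * n)
    if masses is None:
        masses = np.array([ATOMIC_MASSES[e.capitalize()] for e in elements])
    return Conformer(elements=elements, names=names,
                     residue_indices=residue_indices,
                     residue_kinds=residue_kinds,
                     positions=positions, masses=np.asarray(masses, float))


def hexagon_ring(center, rotation, radius=1.39):
    """Six-membered ring (C2 first) in a given frame: rotation is a 3x3
    matrix mapping the local xy-plane template to world coordinates."""
    ang = np.radians(60.0 * np.arange(6))
    local = radius * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    return np.asarray(center) + local @ np.asarray(rotation).T


RING_NAMES = ["C2", "N3", "C4", "C5", "C6", "N1"]


def ring_conformer(centers, rotations):
    """Conformer of bare nucleotide rings (one residue each, plus a P atom
    placed 5 A below each ring so end-to-end metrics work)."""
    names, elements, res, kinds, pos = [], [], [], [], []
    for i, (c, R) in enumerate(zip(centers, rotations), start=1):
        ring = hexagon_ring(c, R)
        names += ["P"] + RING_NAMES
        elements += ["P"] + [n[0] for n in RING_NAMES]
        res += [i] * 7
        kinds += ["nucleotide"] * 7
        pos += [np.asarray(c) + [0, 0, -5.0]] + list(ring)
    return make_conformer(pos, names=names, elements=elements,
                          residue_indices=res, residue_kinds=kinds)


@pytest.fixture
def small_planted():
    """Small ensemble with 1 planted pair and 2 planted stacks."""
    cfg = GeneratorConfig(seed=11, n_conformers=4, n_nucleotides=10,
                          n_peptide_residues=3, planted_stacks=2,
                          planted_pairs=1)
    return gen_ensemble(cfg)


@pytest.fixture
def sequence_10_3():
    return PPMOSequence.from_strings("ACGTACGTAC", "GRR")
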