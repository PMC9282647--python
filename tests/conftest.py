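import numpy as np
import pytest

from hergsift.structures_io import ComplexModel, LigandAtom, LigandPose
from hergsift.synthetic_data import SIDECHAIN_ATOM, ToyComplexSpec, make_toy_receptor

RESIDUE_POOL = sorted(SIDECHAIN_ATOM) + ["GLY"]
ELEMENT_POOL = ["C", "N", "O", "S"]


def random_complex(rng: np.random.Generator) -> ComplexModel:
    """A random small tetramer-ish receptor with a random nearby ligand.

    Residue types, chain count, ligand elements/charges/H-counts and atom
    positions are all randomized so the fingerprint detectors are exercised
    across their whole decision surface.
    """
    n_chains = int(rng.integers(1, 5))
    n_res = int(rng.integers(2, 6))
    names = rng.choice(RESIDUE_POOL, size=n_res, replace=True)
    spec = ToyComplexSpec(
        n_chains=n_chains,
        residues_per_chain=tuple(
            (550 + i, str(names[i])) for i in range(n_res)
        ),
        placements=(),
        ring_radius_A=float(rng.uniform(6.0, 12.0)),
        rise_per_residue_A=float(rng.uniform(3.0, 6.0)),
    )
    receptor = make_toy_receptor(spec)
    n_lig = int(rng.integers(1, 6))
    atoms = []
    for _ in range(n_lig):
        # near the pore axis, spanning inside/outside contact and H-bond range
        xyz = tuple(rng.uniform([-6, -6, -3], [6, 6, n_res * 6.0]))
        elem = str(rng.choice(ELEMENT_POOL))
        charge = int(rng.choice([0, 0, 0, 1, -1]))
        n_h = int(rng.integers(0, 3))
        atoms.append(LigandAtom(elem, xyz, charge, n_h))
    pose = LigandPose("rand", tuple(atoms), float(rng.normal(-7, 1)))
    return ComplexModel(receptor, pose)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
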