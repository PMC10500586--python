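import numpy as np
import pytest

import ensemblevs as ev


@pytest.fixture(scope="session")
def toy_structure():
    """12-residue toy receptor with ligand and waters."""
    spec = ev.ToyReceptorSpec(n_residues=12, include_waters=True)
    return ev.generate_reference_structure(spec, seed=2)


@pytest.fixture(scope="session")
def two_state_traj():
    """200-frame trajectory with planted 75/25 substates, 5 A apart."""
    spec = ev.ToyReceptorSpec(n_residues=24, include_waters=False)
    s = ev.generate_reference_structure(spec, seed=1)
    planted = ev.PlantedStructure(
        substates=ev.make_substates(s, [0.75, 0.25], separation=5.0, seed=1),
        correlation_blocks=ev.two_block_partition(s),
        block_coupling=0.9,
        noise_sd=0.1,
        ligand_block=1,
    )
    return ev.generate_trajectory(s, planted, 200, seed=3)


@pytest.fixture(scope="session")
def block_traj():
    """Single-substate trajectory with two planted correlation blocks."""
    spec = ev.ToyReceptorSpec(n_residues=24, include_waters=False, anchor_residue=18)
    s = ev.generate_reference_structure(spec, seed=1)
    planted = ev.PlantedStructure(
        substates=[(s.coords.copy(), 1.0)],
        correlation_blocks=ev.two_block_partition(s),
        block_coupling=0.9,
        noise_sd=0.1,
        ligand_block=1,
    )
    return ev.generate_trajectory(s, planted, 300, seed=7)


def rigid_transform(coords, seed=0):
    """Random proper rotation + translation applied to a coordinate array."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    return coords @ q.T + t
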