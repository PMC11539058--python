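"""Shared fixtures: the packaged condition table, toy trajectories, and
hand-built structures used across the descriptor tests."""

import numpy as np
import pytest

from aggkin import synthgen
from aggkin.trajio import AtomRecord, ELEMENT_MASSES, Trajectory, VDW_RADII


def make_atom(serial, name, element, res_name, res_index, chain="A"):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=res_name,
        residue_index=res_index, chain_id=chain,
        mass=ELEMENT_MASSES[element], vdw_radius=VDW_RADII[element],
    )


def ca_chain_trajectory(positions_per_frame, times=None):
    """Trajectory of CA-only residues from a list of (n_atoms, 3) frames."""
    frames = np.asarray(positions_per_frame, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    topo = [make_atom(i + 1, "CA", "C", "GLY", i + 1) for i in range(n)]
    return Trajectory(topology=topo, coordinates=frames, times=times)


@pytest.fixture(scope="session")
def condition_table49():
    return synthgen.condition_table_fixture()


@pytest.fixture(scope="session")
def condition_frame(condition_table49):
    return condition_table49.to_frame()


@pytest.fixture
def helix_trajectory():
    spec = synthgen.TrajectorySpec(n_residues=10, n_frames=20,
                                   sigma_profile=0.2, seed=11)
    return synthgen.synth_trajectory(spec)


@pytest.fixture
def static_trajectory():
    spec = synthgen.TrajectorySpec(n_residues=8, n_frames=25,
                                   sigma_profile=0.0, seed=0)
    return synthgen.synth_trajectory(spec)
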