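import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from complexdyn.states import extract_features
from complexdyn.structure_io import Structure
from complexdyn.synthetic import build_toy_complex, preset, simulate_trajectory

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_structure(coords, elements=None, chains=None, res_seqs=None,
                   names=None, res_names=None):
    """Small helper to assemble ad-hoc structures in tests."""
    coords = np.asarray(coords, float)
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array(names if names is not None else ["CA"] * n,
                           dtype=object),
        element=np.array(elements if elements is not None else ["C"] * n,
                         dtype=object),
        res_name=np.array(res_names if res_names is not None else ["GLY"] * n,
                          dtype=object),
        res_seq=np.array(res_seqs if res_seqs is not None
                         else np.arange(1, n + 1)),
        chain_id=np.array(chains if chains is not None else ["A"] * n,
                          dtype=object),
        coords=coords,
    )


@pytest.fixture(scope="session")
def three_state_run():
    """5000-frame three-state trajectory with ground truth (shared)."""
    spec = preset("three-state", seed=11, n_frames=5000)
    toy = build_toy_complex(spec)
    traj, sidecar = simulate_trajectory(toy)
    return toy, traj, sidecar


@pytest.fixture(scope="session")
def three_state_features(three_state_run):
    toy, traj, _ = three_state_run
    return extract_features(
        traj,
        toy.domains["L"],
        (toy.domains["G1"], toy.domains["G2"]),
        (toy.domains["R1"], toy.domains["R2"]),
    )


@pytest.fixture(scope="session")
def single_state_run():
    """2000-frame single-state run without monitors (pure designed noise)."""
    spec = preset("single-state", seed=3, n_frames=2000)
    spec.hbond_pairs = []
    toy = build_toy_complex(spec)
    traj, sidecar = simulate_trajectory(toy)
    return toy, traj, sidecar


@pytest.fixture(scope="session")
def occupancy_run():
    """1000-frame run keeping the designed 40% H-bond monitor."""
    spec = preset("single-state", seed=5, n_frames=1000)
    toy = build_toy_complex(spec)
    traj, sidecar = simulate_trajectory(toy)
    return toy, traj, sidecar


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Three-atom single-chain fixture file."""
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.50"
        "           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.60"
        "           C\n"
        "ATOM      3  C   ALA A   1      10.729   6.768  -4.123  1.00  0.70"
        "           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
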