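import numpy as np
import pytest

from aquabridge.contacts import ContactCriteria
from aquabridge.synthetic import (
    GroundTruth,
    SceneLayout,
    generate_contact_trajectory,
    synthetic_4n6h_pocket,
)
from aquabridge.topology import Frame, Topology, assign_roles


@pytest.fixture(scope="session")
def pocket_model():
    return synthetic_4n6h_pocket()


@pytest.fixture(scope="session")
def criteria():
    return ContactCriteria()


@pytest.fixture(scope="session")
def sim_manifest(tmp_path_factory):
    """Small geometric trajectory set with known mixture and water swaps."""
    truth = GroundTruth(
        k_on=8.4, k_off=1.6, p_bridge=0.875, water_swap_prob=0.5,
        seed=11, n_replicas=3, n_frames=300, dt_ns=0.1,
    )
    outdir = tmp_path_factory.mktemp("sim")
    manifest = generate_contact_trajectory(truth, outdir)
    manifest["truth_obj"] = truth
    manifest["layout"] = SceneLayout()
    return manifest


def make_random_system(rng, n_atoms=None, with_box=True):
    """Random small system for oracle-equivalence checks.

    Atoms are drawn from a pool of standard residues (so the built-in
    role tables apply), waters, and a declared ligand; coordinates fall
    in a box comparable to the cutoffs so periodicity matters.
    """
    pool = [
        # residue templates: (resname, [(name, element), ...])
        ("ASP", [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")]),
        ("SER", [("CB", "C"), ("OG", "O")]),
        ("ARG", [("CD", "C"), ("NE", "N"), ("NH1", "N"), ("NH2", "N")]),
        ("VAL", [("CB", "C"), ("CG1", "C"), ("CG2", "C")]),
        ("SER", [("CB", "C"), ("OG", "O"), ("HG", "H")]),  # with hydrogen
        ("HOH", [("O", "O")]),
        ("HOH", [("O", "O")]),
        ("LIG", [("N1", "N"), ("C1", "C"), ("O1", "O")]),
    ]
    n_res = int(rng.integers(4, 9))
    chosen = [pool[i] for i in rng.integers(0, len(pool), n_res)]
    names, elements, resids, resnames, chains = [], [], [], [], []
    for ri, (resname, atoms) in enumerate(chosen):
        for name, el in atoms:
            names.append(name)
            elements.append(el)
            resids.append(ri + 1)
            resnames.append(resname)
            chains.append("A")
    n = len(names)
    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        is_water=np.array([r == "HOH" for r in resnames], dtype=bool),
    )
    assign_roles(
        top,
        {"LIG": {"N1": ["donor", "cation"], "O1": ["donor", "acceptor"],
                 "C1": ["hydrophobic"]}},
    )
    box_edge = 12.0
    coords = rng.uniform(0.0, box_edge, size=(n, 3))
    # keep hydrogens close to the preceding heavy atom so the covalent
    # search finds them
    for i in range(n):
        if elements[i] == "H" and i > 0:
            coords[i] = coords[i - 1] + rng.uniform(-0.5, 0.5, 3) * 0.9
    box = np.eye(3) * box_edge if with_box else None
    frame = Frame(index=0, time_ns=0.0, coords=coords, box=box)
    # split atoms into two groups
    perm = rng.permutation(n)
    half = n // 2
    group_a = np.sort(perm[:half])
    group_b = np.sort(perm[half:])
    return top, frame, group_a, group_b
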