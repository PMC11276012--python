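"""Synthetic systems with known ground truth for every analysis stage.

Real binding-pocket trajectories of a GPCR–ligand complex are
cluster-scale objects; the statistical questions this package answers
(contact classification, occupancy, correlation times, water exchange)
only need geometry that crosses or respects the contact cutoffs on a
known schedule.  The generator therefore emits a minimal scene — a rigid
receptor fragment containing a focal aspartate (the sodium-pocket
2.50-position acid), a serine pocket residue, a hydrophobic valine, a
three-atom ligand warhead (guanidinium-like nitrogen, carbon, hydroxyl
oxygen) and a handful of single-oxygen waters — and drives the ligand
between three placements:

* **bound** — warhead nitrogen within salt-bridge range of the
  aspartate carboxylate (direct interaction);
* **unbound, bridged** — warhead ~5.6 Å away, with one water placed so
  that both hydrogen-bond legs to ligand and pocket are satisfied
  (water-mediated-only);
* **unbound, free** — ligand far from the pocket, waters in bulk
  (no polar contact).

Bound/unbound follows a two-state Markov chain with user-set on/off
rates, exactly discretised at the frame interval, so occupancy
k_on/(k_on+k_off) and relaxation time 1/(k_on+k_off) are exact ground
truth.  While a bridge persists, the identity of the bridging water is
swapped with a configured per-frame probability, emulating exchange with
bulk solvent that leaves the bridge itself intact.  Per-atom jitter is
kept small enough that no placement ever crosses a cutoff spuriously.

All randomness flows from one base seed; replica r uses
``default_rng(seed + r)``, so identical parameters give byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .topology import Frame, StructureModel, Topology, assign_roles
from .traj_io import write_structure, write_trajectory

__all__ = [
    "GroundTruth",
    "SceneLayout",
    "LIGAND_ROLES",
    "markov_states",
    "markov_indicator_series",
    "build_scene",
    "generate_frames",
    "generate_contact_trajectory",
    "build_scaffold",
    "generate_static_pair",
    "synthetic_4n6h_pocket",
]

#: Declared polar roles of the synthetic ligand (novel residues never get
#: roles by inference).
LIGAND_ROLES = {
    "LIG": {
        "N1": ["donor", "cation"],
        "O1": ["donor", "acceptor"],
        "C1": ["hydrophobic"],
    }
}


@dataclass
class GroundTruth:
    """Generator parameters and the statistics they imply."""

    k_on: float = 0.1            # per ns, unbound -> bound
    k_off: float = 0.1           # per ns, bound -> unbound
    p_bridge: float = 0.5        # P(water bridge | unbound frame)
    water_swap_prob: float = 0.0 # per-frame bridging-water identity swap
    seed: int = 0
    n_replicas: int = 8
    n_frames: int = 1000
    dt_ns: float = 0.1
    start_state: int | None = None  # None = draw from stationary distribution

    @property
    def occupancy(self) -> float:
        return self.k_on / (self.k_on + self.k_off)

    @property
    def relax_time_ns(self) -> float:
        return 1.0 / (self.k_on + self.k_off)

    @property
    def expected_fractions(self) -> tuple[float, float, float]:
        """(direct, water_mediated_only, none) stationary fractions."""
        p = self.occupancy
        return (p, (1 - p) * self.p_bridge, (1 - p) * (1 - self.p_bridge))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["occupancy"] = self.occupancy
        d["relax_time_ns"] = self.relax_time_ns
        d["expected_fractions"] = {
            "direct": self.expected_fractions[0],
            "water_mediated_only": self.expected_fractions[1],
            "no_polar_contact": self.expected_fractions[2],
        }
        return d


def markov_states(truth: GroundTruth, replica_id: int) -> np.ndarray:
    """Exact discrete sampling of the two-state chain at interval dt.

    Transition probabilities come from the matrix exponential of the
    two-state rate matrix, so the discrete chain's stationary occupancy
    and relaxation time match the continuous-time values at any dt.
    """
    lam = truth.k_on + truth.k_off
    if lam <= 0:
        if truth.start_state is None:
            raise ValueError("rates are zero: a start_state must be requested")
        return np.full(truth.n_frames, truth.start_state, dtype=np.int8)
    decay = np.exp(-lam * truth.dt_ns)
    pi_on = truth.occupancy
    p_off_to_on = pi_on * (1.0 - decay)
    p_on_to_off = (1.0 - pi_on) * (1.0 - decay)
    rng = np.random.default_rng(truth.seed + replica_id)
    states = np.empty(truth.n_frames, dtype=np.int8)
    if truth.start_state is None:
        state = int(rng.random() < pi_on)
    else:
        state = int(truth.start_state)
    u = rng.random(truth.n_frames)
    for i in range(truth.n_frames):
        states[i] = state
        if state == 1:
            if u[i] < p_on_to_off:
                state = 0
        else:
            if u[i] < p_off_to_on:
                state = 1
    return states


def markov_indicator_series(truth: GroundTruth, replica_id: int):
    """Indicator series of the bound state, bypassing geometry.

    The fast path for lifetime statistics: the same chain the geometric
    generator uses, exposed directly as an
    :class:`~aquabridge.lifetimes.IndicatorSeries`.
    """
    from .lifetimes import IndicatorSeries

    states = markov_states(truth, replica_id)
    times = np.arange(truth.n_frames) * truth.dt_ns
    return IndicatorSeries(
        replica_id=replica_id,
        times_ns=times,
        h=states,
        interaction_key="direct",
    )


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------


@dataclass
class SceneLayout:
    """Placement parameters of the synthetic pocket scene (Å)."""

    bound_distance_A: float = 3.0      # warhead N to carboxylate O when bound
    bridge_leg_A: float = 2.8          # each water-bridge leg
    unbound_distance_A: float = 12.0   # warhead N to carboxylate O when free
    jitter_A: float = 0.1              # uniform per-coordinate jitter amplitude
    n_waters: int = 5
    box_edge_A: float = 40.0

    def validate(self, criteria=None) -> None:
        from .contacts import ContactCriteria
        from .errors import ConfigError

        c = criteria or ContactCriteria()
        # worst-case distance change from jittering both endpoints
        slop = 2.0 * self.jitter_A * np.sqrt(3.0)
        if self.bound_distance_A + slop > c.salt_bridge_A:
            raise ConfigError("bound placement can cross the salt-bridge cutoff")
        if self.bridge_leg_A + slop > c.hbond_distance_A:
            raise ConfigError("bridge legs can cross the H-bond cutoff")
        bridged_sep = 2.0 * self.bridge_leg_A
        if bridged_sep - slop < c.salt_bridge_A:
            raise ConfigError("bridged placement can fall inside the direct cutoff")
        if self.unbound_distance_A - slop < c.salt_bridge_A:
            raise ConfigError("unbound placement can fall inside the direct cutoff")


# Rigid receptor fragment: ASP 95 (focal), SER 155 (pocket), VAL 217
# (hydrophobic profiling target).  The carboxylate oxygen OD1 sits at the
# origin and the ligand approaches along +x.
_RECEPTOR_ATOMS = [
    # name, element, resid, resname, xyz
    ("CB", "C", 95, "ASP", (-2.3, -1.0, 0.0)),
    ("CG", "C", 95, "ASP", (-0.9, -0.6, 0.0)),
    ("OD1", "O", 95, "ASP", (0.0, 0.0, 0.0)),
    ("OD2", "O", 95, "ASP", (-0.7, 0.9, 0.0)),
    ("CB", "C", 155, "SER", (1.0, 7.5, 0.0)),
    ("OG", "O", 155, "SER", (1.0, 6.1, 0.0)),
    ("CB", "C", 217, "VAL", (4.0, -4.0, 0.0)),
    ("CG1", "C", 217, "VAL", (5.2, -4.8, 0.0)),
    ("CG2", "C", 217, "VAL", (3.0, -5.0, 0.8)),
]

_LIGAND_ATOMS = [
    ("N1", "N", (0.0, 0.0, 0.0)),    # warhead guanidinium-like nitrogen
    ("C1", "C", (1.4, 0.0, 0.0)),
    ("O1", "O", (1.9, 1.3, 0.0)),
]


def build_scene(layout: SceneLayout = SceneLayout()) -> tuple[Topology, np.ndarray]:
    """Topology and base coordinates of the synthetic pocket scene.

    Returns the topology (roles assigned, waters flagged) and the
    coordinate array of the reference placement (ligand bound).
    """
    names, elements, resids, resnames, chains, coords = [], [], [], [], [], []
    for name, el, resid, resname, xyz in _RECEPTOR_ATOMS:
        names.append(name); elements.append(el); resids.append(resid)
        resnames.append(resname); chains.append("A"); coords.append(xyz)
    for name, el, xyz in _LIGAND_ATOMS:
        names.append(name); elements.append(el); resids.append(1)
        resnames.append("LIG"); chains.append("L")
        coords.append((xyz[0] + layout.bound_distance_A, xyz[1], xyz[2]))
    for w in range(layout.n_waters):
        names.append("O"); elements.append("O"); resids.append(500 + w)
        resnames.append("HOH"); chains.append("W")
        coords.append(_bulk_position(w, layout))
    resname_arr = np.array(resnames, dtype=object)
    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=resname_arr,
        chains=np.array(chains, dtype=object),
        is_water=np.array([r == "HOH" for r in resnames], dtype=bool),
    )
    assign_roles(top, LIGAND_ROLES)
    return top, np.array(coords, dtype=float)


def _bulk_position(w: int, layout: SceneLayout) -> tuple[float, float, float]:
    """Bulk slot for water w: a grid far from pocket and ligand."""
    return (18.0 + 4.0 * (w % 3), 18.0 + 4.0 * (w // 3), 15.0)


def generate_frames(
    truth: GroundTruth,
    replica_id: int,
    layout: SceneLayout = SceneLayout(),
) -> tuple[Topology, list[np.ndarray], dict]:
    """Coordinates for one replica, plus the per-frame ground-truth log.

    The log records for every frame the bound state, whether a bridge was
    placed, and the bridging water's residue number (or -1).
    """
    layout.validate()
    top, base = build_scene(layout)
    states = markov_states(truth, replica_id)
    # independent substreams so the chain is identical with or without
    # geometric decoration
    rng = np.random.default_rng(truth.seed + replica_id + 100_000)
    n_lig = len(_LIGAND_ATOMS)
    lig_slice = slice(len(_RECEPTOR_ATOMS), len(_RECEPTOR_ATOMS) + n_lig)
    water_start = len(_RECEPTOR_ATOMS) + n_lig

    frames: list[np.ndarray] = []
    log = {"state": [], "bridged": [], "bridge_water": []}
    current_water = 0
    prev_bridged = False
    for i in range(truth.n_frames):
        coords = base.copy()
        bound = bool(states[i])
        if bound:
            offset = layout.bound_distance_A
            bridged = False
        else:
            bridged = bool(rng.random() < truth.p_bridge)
            offset = (
                2.0 * layout.bridge_leg_A if bridged else layout.unbound_distance_A
            )
        for k, (_, _, xyz) in enumerate(_LIGAND_ATOMS):
            coords[lig_slice.start + k] = (xyz[0] + offset, xyz[1], xyz[2])
        if bridged:
            if prev_bridged and rng.random() < truth.water_swap_prob:
                choices = [w for w in range(layout.n_waters) if w != current_water]
                current_water = int(rng.choice(choices))
            elif not prev_bridged:
                current_water = int(rng.integers(layout.n_waters))
            coords[water_start + current_water] = (layout.bridge_leg_A, 0.0, 0.0)
        jitter = rng.uniform(-layout.jitter_A, layout.jitter_A, size=coords.shape)
        jitter[: len(_RECEPTOR_ATOMS)] = 0.0  # receptor is rigid
        coords += jitter
        frames.append(coords)
        log["state"].append(int(bound))
        log["bridged"].append(int(bridged))
        log["bridge_water"].append(500 + current_water if bridged else -1)
        prev_bridged = bridged
    return top, frames, log


def generate_contact_trajectory(
    truth: GroundTruth,
    outdir: str | Path,
    layout: SceneLayout = SceneLayout(),
) -> dict:
    """Write topology PDB, per-replica DCD files and a truth JSON.

    Returns a manifest dict with the paths and the ligand-role
    declaration needed to re-load the files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    box = np.eye(3) * layout.box_edge_A
    manifest: dict = {
        "topology": str(outdir / "topology.pdb"),
        "trajectories": [],
        "truth": str(outdir / "truth.json"),
        "ligand_roles": LIGAND_ROLES,
        "dt_ns": truth.dt_ns,
    }
    top = None
    logs = []
    for r in range(truth.n_replicas):
        top, frames, log = generate_frames(truth, r, layout)
        path = outdir / f"replica_{r:02d}.dcd"
        write_trajectory(frames, path, box=box)
        manifest["trajectories"].append(str(path))
        logs.append(log)
    model = StructureModel(
        topology=top,
        frame=Frame(index=0, time_ns=0.0, coords=build_scene(layout)[1], box=box),
    )
    write_structure(model, outdir / "topology.pdb")
    truth_payload = truth.as_dict()
    truth_payload["layout"] = asdict(layout)
    truth_payload["per_replica_log"] = logs
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Static structure pairs for superposition / displacement tests
# ---------------------------------------------------------------------------


def build_scaffold(n_residues: int = 8) -> StructureModel:
    """A small non-collinear poly-alanine-like scaffold (N, CA, C, O, CB)."""
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    names, elements, resids, resnames, chains, coords = [], [], [], [], [], []
    # residues along a gentle helix so no three CA are collinear
    for r in range(n_residues):
        angle = 1.7 * r
        ca = np.array([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * r])
        offsets = {
            "N": np.array([-1.2, 0.3, -0.4]),
            "CA": np.zeros(3),
            "C": np.array([1.1, 0.6, 0.3]),
            "O": np.array([1.4, 1.7, 0.1]),
            "CB": np.array([0.2, -1.4, 0.6]),
        }
        for name, off in offsets.items():
            names.append(name)
            elements.append(name[0])
            resids.append(r + 1)
            resnames.append("ALA")
            chains.append("A")
            coords.append(ca + off)
    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        is_water=np.zeros(len(names), dtype=bool),
    )
    assign_roles(top)
    return StructureModel(
        topology=top, frame=Frame(index=0, time_ns=0.0, coords=np.array(coords))
    )


def generate_static_pair(
    displacements: dict[int, np.ndarray] | None = None,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    n_residues: int = 8,
    outdir: str | Path | None = None,
) -> tuple[StructureModel, StructureModel, dict]:
    """Model pair: B = rigid_transform(A) plus per-residue displacements.

    ``displacements`` maps residue seq -> 3-vector added to every atom of
    that residue *after* the rigid transform, so the truth JSON's
    displacement magnitudes are exact post-superposition values.
    Optionally writes model_a.pdb / model_b.pdb / truth.json to outdir.
    """
    model_a = build_scaffold(n_residues)
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if abs(np.linalg.det(rot) - 1.0) > 1e-6:
        raise ValueError("rotation must be proper (det = +1)")
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)
    coords_b = model_a.frame.coords @ rot.T + trans
    displacements = displacements or {}
    truth_disp: dict[int, float] = {}
    top = model_a.topology
    for resid, vec in displacements.items():
        vec = np.asarray(vec, dtype=float)
        mask = top.resids == int(resid)
        if not mask.any():
            raise KeyError(f"residue {resid} not in scaffold")
        coords_b[mask] += vec
        truth_disp[int(resid)] = float(np.linalg.norm(vec))
    model_b = StructureModel(
        topology=top, frame=Frame(index=0, time_ns=0.0, coords=coords_b)
    )
    # rmsd implied over undisplaced residues after optimal superposition
    undisturbed = ~np.isin(top.resids, list(displacements.keys()))
    truth = {
        "displacement_magnitudes": truth_disp,
        "rmsd_undisplaced_selection": 0.0,
        "n_undisplaced_atoms": int(undisturbed.sum()),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_structure(model_a, outdir / "model_a.pdb")
        write_structure(model_b, outdir / "model_b.pdb")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return model_a, model_b, truth


# ---------------------------------------------------------------------------
# Synthetic stand-in for the inactive-state receptor pocket
# ---------------------------------------------------------------------------


def synthetic_4n6h_pocket() -> StructureModel:
    """SYNTHETIC stand-in for the inactive-state δOR–naltrindole pocket.

    This is *not* the deposited 4N6H coordinate set.  It is a minimal
    constructed model carrying the atoms the design measurement needs —
    the ligand's basic tertiary amine nitrogen (resname NTI, atom N1) and
    the sodium-pocket aspartate D95 carboxylate (OD1/OD2) — placed so
    that the amine-to-nearest-carboxylate-oxygen separation equals the
    published inactive-state measurement of 11.2 Å, plus surrounding
    pocket residues at plausible positions.  Use it to exercise the
    measurement machinery (BW resolution, atom specs, group-min
    distances); it carries no experimental coordinate information beyond
    that single published distance.
    """
    entries = [
        # chain, resid, resname, name, element, xyz
        ("A", 95, "ASP", "CB", "C", (-2.3, -1.0, 0.2)),
        ("A", 95, "ASP", "CG", "C", (-0.9, -0.6, 0.1)),
        ("A", 95, "ASP", "OD1", "O", (0.0, 0.0, 0.0)),
        ("A", 95, "ASP", "OD2", "O", (-0.7, 0.9, -0.3)),
        ("A", 131, "ASN", "ND2", "N", (2.1, 2.8, 1.0)),
        ("A", 131, "ASN", "OD1", "O", (2.9, 3.9, 0.4)),
        ("A", 155, "SER", "OG", "O", (1.0, -3.1, 1.2)),
        ("A", 310, "ASN", "ND2", "N", (-2.5, 2.4, 2.0)),
        ("A", 311, "SER", "OG", "O", (-3.4, 0.2, 2.6)),
        # NTI-like ligand: tertiary amine N1 exactly 11.2 Å from OD1 and
        # farther from OD2; a few carbons sketch the morphinan core.
        ("A", 401, "NTI", "N1", "N", (5.0, -10.023, 0.0)),
        ("A", 401, "NTI", "C9", "C", (5.9, -9.1, 0.7)),
        ("A", 401, "NTI", "C16", "C", (4.1, -9.2, -0.8)),
        ("A", 401, "NTI", "C14", "C", (6.0, -11.0, -0.6)),
        ("A", 401, "NTI", "O3", "O", (7.8, -12.5, 0.3)),
    ]
    names = np.array([e[3] for e in entries], dtype=object)
    top = Topology(
        names=names,
        elements=np.array([e[4] for e in entries], dtype=object),
        resids=np.array([e[1] for e in entries], dtype=int),
        resnames=np.array([e[2] for e in entries], dtype=object),
        chains=np.array([e[0] for e in entries], dtype=object),
        is_water=np.zeros(len(entries), dtype=bool),
    )
    assign_roles(top, {"NTI": {"N1": ["donor", "cation"], "O3": ["donor", "acceptor"]}})
    coords = np.array([e[5] for e in entries], dtype=float)
    return StructureModel(
        topology=top, frame=Frame(index=0, time_ns=0.0, coords=coords)
    )
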