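"""In-memory model of a molecular system: atoms, residues, polar roles.

The analysis layers work on three light containers:

``Topology``
    Static per-atom annotation: names, elements, residue membership, a
    water flag, and *polar roles* (hydrogen-bond donor/acceptor, formal
    cation/anion, hydrophobic).  Roles for the twenty standard amino
    acids and water come from built-in lookup tables; roles for novel
    ligands are never inferred and must be supplied explicitly.

``Frame``
    One time point: coordinates in Å plus an optional periodic box.

``StructureModel``
    A static structure = one Topology + one Frame (crystal or cryo-EM
    coordinates).

Units are Å and ns everywhere inside the package; converters live at the
I/O boundary (see :mod:`aquabridge.traj_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "StructureModel",
    "ROLE_NAMES",
    "WATER_RESNAMES",
    "assign_roles",
    "select_atoms",
    "parse_atom_spec",
]

ROLE_NAMES = ("donor", "acceptor", "cation", "anion", "hydrophobic")

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "TIP3", "TIP3P", "SOL", "SPC", "T3P"})

# ---------------------------------------------------------------------------
# Built-in polar-role dictionary for standard amino acids.
#
# Backbone: N is a donor (amide NH), O an acceptor, on every residue.
# Side chains follow the usual MD-analysis conventions: hydroxyls are both
# donor and acceptor; carboxylates are acceptors and formal anions;
# Lys/Arg nitrogens are donors and formal cations; His ring nitrogens are
# treated as both donor and acceptor (protonation unknown).
# Hydrophobic role is carried by every carbon atom (see assign_roles).
# ---------------------------------------------------------------------------

_BACKBONE_DONORS = {"N"}
_BACKBONE_ACCEPTORS = {"O", "OXT"}

_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
    "HID": {"ND1"},
    "HIE": {"NE2"},
    "HIP": {"ND1", "NE2"},
    "TRP": {"NE1"},
}

_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "HID": {"NE2"},
    "HIE": {"ND1"},
    "MET": {"SD"},
}

_CATIONS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIP": {"ND1", "NE2"},
}

_ANIONS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass
class Topology:
    """Per-atom static annotation of a molecular system.

    All array fields are aligned, length ``n_atoms``; ``atom_id`` is the
    zero-based position in file order.
    """

    names: np.ndarray          # str per atom
    elements: np.ndarray       # str per atom ("C", "N", "O", "H", ...)
    resids: np.ndarray         # int residue sequence numbers, file-verbatim
    resnames: np.ndarray       # str per atom
    chains: np.ndarray         # str per atom
    is_water: np.ndarray       # bool per atom
    roles: dict[str, np.ndarray] = field(default_factory=dict)  # role -> bool mask

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr_name in ("elements", "resids", "resnames", "chains", "is_water"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"topology field {arr_name!r} length mismatch")
        for role in ROLE_NAMES:
            self.roles.setdefault(role, np.zeros(n, dtype=bool))

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def role_mask(self, role: str) -> np.ndarray:
        if role not in ROLE_NAMES:
            raise KeyError(f"unknown role {role!r}; expected one of {ROLE_NAMES}")
        return self.roles[role]

    def residue_key(self) -> np.ndarray:
        """Structured (chain, resid) key per atom, for residue grouping."""
        return np.array(
            [f"{c}|{r}" for c, r in zip(self.chains, self.resids)], dtype=object
        )


@dataclass
class Frame:
    """Coordinates of one time point, in Å."""

    index: int
    time_ns: float
    coords: np.ndarray                 # (n_atoms, 3) float, Å
    box: np.ndarray | None = None      # (3, 3) row box vectors, Å; None = no PBC

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if self.time_ns < 0:
            raise ValueError("time_ns must be non-negative")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3, 3):
                raise ValueError("box must be 3x3")
            if abs(np.linalg.det(self.box)) < 1e-9:
                raise ValueError("box is singular")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class StructureModel:
    """A static structure: topology plus a single coordinate frame."""

    topology: Topology
    frame: Frame

    def __post_init__(self) -> None:
        if self.frame.n_atoms != self.topology.n_atoms:
            raise ValueError(
                f"frame has {self.frame.n_atoms} atoms, "
                f"topology has {self.topology.n_atoms}"
            )

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


def assign_roles(
    topology: Topology,
    ligand_roles: dict[str, dict[str, list[str]]] | None = None,
) -> Topology:
    """Fill the role masks of ``topology`` in place and return it.

    Standard amino acids and water use the built-in lookup tables; the
    hydrophobic role is assigned to every carbon atom.  Atoms of any
    other residue get roles only from ``ligand_roles``, a mapping
    ``{resname: {atom_name: [role, ...]}}`` supplied by the caller —
    roles of novel ligands are declared, never guessed.
    """
    n = topology.n_atoms
    masks = {role: np.zeros(n, dtype=bool) for role in ROLE_NAMES}
    ligand_roles = ligand_roles or {}

    for i in range(n):
        resname = str(topology.resnames[i]).upper()
        name = str(topology.names[i]).upper()
        element = str(topology.elements[i]).upper()

        if element == "C":
            masks["hydrophobic"][i] = True

        if topology.is_water[i]:
            # Water oxygen donates and accepts; hydrogens handled via the
            # attached-H search in the detectors.
            if element == "O":
                masks["donor"][i] = True
                masks["acceptor"][i] = True
            continue

        if resname in ligand_roles:
            for role in ligand_roles[resname].get(name, []):
                if role not in ROLE_NAMES:
                    raise ValueError(
                        f"unknown role {role!r} for {resname}:{name}; "
                        f"expected one of {ROLE_NAMES}"
                    )
                masks[role][i] = True
            continue

        # Standard amino-acid lookup.
        if name in _BACKBONE_DONORS:
            masks["donor"][i] = True
        if name in _BACKBONE_ACCEPTORS:
            masks["acceptor"][i] = True
        if name in _SIDECHAIN_DONORS.get(resname, ()):
            masks["donor"][i] = True
        if name in _SIDECHAIN_ACCEPTORS.get(resname, ()):
            masks["acceptor"][i] = True
        if name in _CATIONS.get(resname, ()):
            masks["cation"][i] = True
        if name in _ANIONS.get(resname, ()):
            masks["anion"][i] = True

    topology.roles = masks
    return topology


def select_atoms(
    topology: Topology,
    *,
    chain: str | None = None,
    resid: int | None = None,
    resname: str | None = None,
    names: list[str] | tuple[str, ...] | None = None,
    water: bool | None = None,
) -> np.ndarray:
    """Return atom indices matching all given criteria (AND semantics)."""
    mask = np.ones(topology.n_atoms, dtype=bool)
    if chain is not None:
        mask &= topology.chains == chain
    if resid is not None:
        mask &= topology.resids == int(resid)
    if resname is not None:
        mask &= np.char.upper(topology.resnames.astype(str)) == resname.upper()
    if names is not None:
        wanted = {n.upper() for n in names}
        mask &= np.array(
            [str(n).upper() in wanted for n in topology.names], dtype=bool
        )
    if water is not None:
        mask &= topology.is_water == water
    return np.flatnonzero(mask)


def parse_atom_spec(spec: str) -> dict:
    """Parse a textual atom spec into ``select_atoms`` keyword arguments.

    Two forms are accepted:

    ``chain:resid[:atomname]``   e.g. ``A:95:OD1`` or ``A:95``
    ``resname=XXX[:atomname]``   e.g. ``resname=NTI:N1``

    The atom name may be a comma-separated list (``A:95:OD1,OD2``).
    """
    spec = spec.strip()
    if spec.startswith("resname="):
        rest = spec[len("resname="):]
        parts = rest.split(":")
        out: dict = {"resname": parts[0]}
        if len(parts) > 1 and parts[1]:
            out["names"] = parts[1].split(",")
        return out
    parts = spec.split(":")
    if len(parts) < 2:
        raise ValueError(
            f"cannot parse atom spec {spec!r}; expected chain:resid[:atomname] "
            "or resname=XXX[:atomname]"
        )
    out = {"chain": parts[0], "resid": int(parts[1])}
    if len(parts) > 2 and parts[2]:
        out["names"] = parts[2].split(",")
    return out
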