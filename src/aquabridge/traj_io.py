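"""Reading and writing structures and trajectories.

Structures (PDB / mmCIF) are parsed with gemmi; trajectory frames (DCD /
XTC) are read with MDAnalysis coordinate readers, which convert lengths
to Å regardless of the on-disk unit convention (XTC stores nm).  Alternate
locations are resolved to the highest-occupancy conformer, ties broken
alphabetically by altloc code.

Everything downstream of this module works in Å and ns.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyModelError,
    ParseError,
    TopologyMismatchError,
    TruncationWarning,
)
from .topology import (
    Frame,
    StructureModel,
    Topology,
    WATER_RESNAMES,
    assign_roles,
)

__all__ = [
    "load_structure",
    "iter_frames",
    "write_structure",
    "write_trajectory",
    "write_tsv",
    "write_run_metadata",
]


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties alphabetical."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        key = atom.name
        prev = by_name.get(key)
        if prev is None:
            by_name[key] = atom
        elif atom.occ > prev.occ or (
            atom.occ == prev.occ and _altloc_sort(atom) < _altloc_sort(prev)
        ):
            # higher occupancy wins; ties go to the alphabetically
            # earlier altloc code
            by_name[key] = atom
    return list(by_name.values())


def _altloc_sort(atom: gemmi.Atom) -> str:
    return atom.altloc if atom.altloc else "\x00"


def load_structure(
    path: str | Path,
    fmt: str | None = None,
    ligand_roles: dict | None = None,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> StructureModel:
    """Load a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Structure file.  Format is inferred from the extension unless
        ``fmt`` ("pdb" or "mmcif") is given.
    ligand_roles
        Optional ``{resname: {atom_name: [role, ...]}}`` declaration of
        polar roles for non-standard residues.

    Coordinates are returned in Å with residue numbering preserved
    verbatim from the file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = st[0]

    names, elements, resids, resnames, chains, coords = [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            for atom in _resolve_altlocs(residue):
                names.append(atom.name)
                elements.append(atom.element.name)
                resids.append(residue.seqid.num)
                resnames.append(residue.name)
                chains.append(chain.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])

    if not names:
        raise EmptyModelError(f"{path}: zero atoms")

    resname_arr = np.array(resnames, dtype=object)
    topology = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=resname_arr,
        chains=np.array(chains, dtype=object),
        is_water=np.array(
            [str(r).upper() in water_resnames for r in resname_arr], dtype=bool
        ),
    )
    assign_roles(topology, ligand_roles)
    frame = Frame(index=0, time_ns=0.0, coords=np.array(coords, dtype=float))
    return StructureModel(topology=topology, frame=frame)


def _box_from_dimensions(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if dims.shape != (6,) or np.all(dims[:3] == 0):
        return None
    from MDAnalysis.lib.mdamath import triclinic_vectors

    return np.asarray(triclinic_vectors(dims), dtype=float)


def iter_frames(
    traj_path: str | Path,
    topology: Topology,
    stride: int = 1,
    dt_ns: float | None = None,
) -> Iterator[Frame]:
    """Iterate frames of a DCD or XTC trajectory as :class:`Frame` objects.

    ``frame.index`` reflects the position in the source file (so with
    stride 10 the yielded indices are 0, 10, 20, ...).  Frame times come
    from ``index * dt_ns`` when ``dt_ns`` is given; otherwise the file's
    embedded time stamps are used (converted ps -> ns), which for DCD are
    often meaningless — callers analysing lifetimes should pass ``dt_ns``.

    Raises :class:`TopologyMismatchError` on atom-count mismatch; a
    trajectory that ends mid-frame yields its complete frames and then
    emits :class:`TruncationWarning`.
    """
    traj_path = Path(traj_path)
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    suffix = traj_path.suffix.lower()
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    else:
        raise ValueError(f"unsupported trajectory format {suffix!r}")

    reader = Reader(str(traj_path))
    try:
        if reader.n_atoms != topology.n_atoms:
            raise TopologyMismatchError(
                f"{traj_path}: trajectory has {reader.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        truncated = False
        i = 0
        iterator = iter(reader)
        while True:
            try:
                ts = next(iterator)
            except StopIteration:
                break
            except (EOFError, OSError, IOError):
                truncated = True
                break
            if i % stride == 0:
                time_ns = (i * dt_ns) if dt_ns is not None else float(ts.time) / 1000.0
                yield Frame(
                    index=i,
                    time_ns=time_ns,
                    coords=np.array(ts.positions, dtype=float),
                    box=_box_from_dimensions(ts.dimensions),
                )
            i += 1
        if truncated:
            warnings.warn(
                f"{traj_path}: truncated trajectory; yielded {i} complete frames",
                TruncationWarning,
            )
    finally:
        reader.close()


def expected_frame_count(n_frames: int, stride: int) -> int:
    """Number of frames a strided iteration yields: ceil(N / stride)."""
    return math.ceil(n_frames / stride)


# ---------------------------------------------------------------------------
# Writers (fixtures and synthetic data)
# ---------------------------------------------------------------------------


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a PDB file (deterministic output)."""
    st = gemmi.Structure()
    st.name = "aquabridge"
    gmodel = gemmi.Model("1")
    top, frame = model.topology, model.frame
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(top.n_atoms):
        cname = str(top.chains[i]) or "A"
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
        chain = chain_map[cname]
        resid = int(top.resids[i])
        resname = str(top.resnames[i])
        if (
            len(chain) == 0
            or chain[-1].seqid.num != resid
            or chain[-1].name != resname
        ):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resid, " ")
            res.het_flag = "H" if (top.is_water[i] or resname not in _STD_RES) else "A"
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = str(top.names[i])
        atom.element = gemmi.Element(str(top.elements[i]))
        atom.pos = gemmi.Position(*frame.coords[i])
        atom.occ = 1.0
        res.add_atom(atom)
    for chain in chain_map.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    if frame.box is not None:
        a, b, c = (np.linalg.norm(frame.box[k]) for k in range(3))
        st.cell = gemmi.UnitCell(a, b, c, 90, 90, 90)
    st.setup_entities()
    st.write_pdb(str(path))


_STD_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_trajectory(
    coords_per_frame: Sequence[np.ndarray],
    path: str | Path,
    box: np.ndarray | None = None,
) -> None:
    """Write frames (each (n_atoms, 3), Å) as a DCD file.

    Output is byte-deterministic for identical input.
    """
    import MDAnalysis as mda

    coords_per_frame = [np.asarray(c, dtype=np.float32) for c in coords_per_frame]
    if not coords_per_frame:
        raise ValueError("no frames to write")
    n_atoms = coords_per_frame[0].shape[0]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    if box is not None:
        a, b, c = (float(np.linalg.norm(box[k])) for k in range(3))
        dims = [a, b, c, 90.0, 90.0, 90.0]
    else:
        dims = None
    with mda.Writer(str(path), n_atoms=n_atoms, remarks="aquabridge synthetic") as w:
        for frame_coords in coords_per_frame:
            u.atoms.positions = frame_coords
            if dims is not None:
                u.dimensions = dims
            w.write(u.atoms)


def write_tsv(path: str | Path, header: Sequence[str], rows) -> None:
    """Write rows as a TSV file with a header line (deterministic)."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_run_metadata(path: str | Path, metadata: dict) -> None:
    """Write a sidecar JSON of run metadata (inputs, cutoffs, seed, version)."""
    from . import __version__

    payload = dict(metadata)
    payload.setdefault("aquabridge_version", __version__)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
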