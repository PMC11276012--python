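"""Geometric contact detectors against constructed cases and brute force."""

import numpy as np
import pytest

from aquabridge.contacts import (
    ContactCategory,
    ContactCriteria,
    classify_frame,
    detect_hbonds,
    detect_hydrophobic_contacts,
    detect_salt_bridges,
    detect_water_bridges,
    min_distance,
)
from aquabridge.errors import EmptySelectionError
from aquabridge.topology import Frame, Topology, assign_roles

from .oracles import (
    brute_hbonds,
    brute_hydrophobic,
    brute_min_distance,
    brute_salt_bridges,
    brute_water_bridges,
)


def tiny_system(atoms, ligand_roles=None):
    """atoms: list of (name, element, resid, resname, chain, xyz)."""
    top = Topology(
        names=np.array([a[0] for a in atoms], dtype=object),
        elements=np.array([a[1] for a in atoms], dtype=object),
        resids=np.array([a[2] for a in atoms], dtype=int),
        resnames=np.array([a[3] for a in atoms], dtype=object),
        chains=np.array([a[4] for a in atoms], dtype=object),
        is_water=np.array([a[3] == "HOH" for a in atoms], dtype=bool),
    )
    assign_roles(top, ligand_roles)
    frame = Frame(
        index=0, time_ns=0.0, coords=np.array([a[5] for a in atoms], dtype=float)
    )
    return top, frame


class TestHBonds:
    def test_linear_hbond_detected_with_angle(self):
        top, frame = tiny_system(
            [
                ("OG", "O", 1, "SER", "A", (0.0, 0.0, 0.0)),
                ("HG", "H", 1, "SER", "A", (1.0, 0.0, 0.0)),
                ("O", "O", 2, "GLY", "A", (2.8, 0.0, 0.0)),
            ]
        )
        bonds = detect_hbonds(frame, top, np.array([0, 1]), np.array([2]))
        assert len(bonds) == 1
        assert bonds[0].distance_A == pytest.approx(2.8)
        assert bonds[0].angle_deg == pytest.approx(180.0)
        assert bonds[0].hydrogen_atom == 1

    def test_far_pair_rejected(self):
        top, frame = tiny_system(
            [
                ("OG", "O", 1, "SER", "A", (0.0, 0.0, 0.0)),
                ("O", "O", 2, "GLY", "A", (10.0, 0.0, 0.0)),
            ]
        )
        assert detect_hbonds(frame, top, np.array([0]), np.array([1])) == []

    def test_bent_geometry_rejected_by_angle(self):
        # acceptor 3.4 A away but D-H...A angle ~100 deg
        h = np.array([1.0, 0.0, 0.0])
        # place acceptor so the angle at H is 100 degrees
        ang = np.radians(100.0)
        direction = np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
        # distance donor-acceptor must be <= 3.5 to isolate the angle filter
        acc = h + 2.6 * direction
        top, frame = tiny_system(
            [
                ("OG", "O", 1, "SER", "A", (0.0, 0.0, 0.0)),
                ("HG", "H", 1, "SER", "A", tuple(h)),
                ("O", "O", 2, "GLY", "A", tuple(acc)),
            ]
        )
        d = np.linalg.norm(acc)
        assert d <= 3.5
        assert detect_hbonds(frame, top, np.array([0, 1]), np.array([2])) == []

    def test_heavy_atom_fallback_without_hydrogens(self):
        top, frame = tiny_system(
            [
                ("OG", "O", 1, "SER", "A", (0.0, 0.0, 0.0)),
                ("O", "O", 2, "GLY", "A", (3.4, 0.0, 0.0)),
            ]
        )
        bonds = detect_hbonds(frame, top, np.array([0]), np.array([1]))
        assert len(bonds) == 1
        assert bonds[0].hydrogen_atom is None and bonds[0].angle_deg is None

    def test_symmetric_in_group_order(self):
        top, frame = tiny_system(
            [
                ("OG", "O", 1, "SER", "A", (0.0, 0.0, 0.0)),
                ("O", "O", 2, "GLY", "A", (3.0, 0.0, 0.0)),
            ]
        )
        a, b = np.array([0]), np.array([1])
        fwd = detect_hbonds(frame, top, a, b)
        rev = detect_hbonds(frame, top, b, a)
        assert [(x.donor_atom, x.acceptor_atom) for x in fwd] == [
            (x.donor_atom, x.acceptor_atom) for x in rev
        ]

    def test_empty_selection_raises(self):
        top, frame = tiny_system(
            [("OG", "O", 1, "SER", "A", (0.0, 0.0, 0.0))]
        )
        with pytest.raises(EmptySelectionError):
            detect_hbonds(frame, top, np.array([], dtype=int), np.array([0]))


class TestSaltBridges:
    def setup_method(self):
        self.make = lambda d: tiny_system(
            [
                ("NH1", "N", 1, "ARG", "A", (0.0, 0.0, 0.0)),
                ("OD1", "O", 2, "ASP", "A", (d, 0.0, 0.0)),
            ]
        )

    def test_detected_at_3A(self):
        top, frame = self.make(3.0)
        sbs = detect_salt_bridges(frame, top, np.array([0]), np.array([1]))
        assert len(sbs) == 1
        assert sbs[0].distance_A == pytest.approx(3.0)

    def test_rejected_at_8A(self):
        top, frame = self.make(8.0)
        assert detect_salt_bridges(frame, top, np.array([0]), np.array([1])) == []

    def test_boundary_inclusive_at_cutoff(self):
        top, frame = self.make(4.0)
        assert (
            len(detect_salt_bridges(frame, top, np.array([0]), np.array([1]))) == 1
        )


class TestWaterBridges:
    def bridge_system(self, with_water=True, ligand_leg_only=False):
        atoms = [
            ("N1", "N", 1, "LIG", "L", (5.6, 0.0, 0.0)),
            ("OD1", "O", 95, "ASP", "A", (0.0, 0.0, 0.0)),
        ]
        if with_water:
            x = 2.8 if not ligand_leg_only else 9.0
            atoms.append(("O", "O", 500, "HOH", "W", (x, 0.0, 0.0)))
        if ligand_leg_only and with_water:
            # water close to ligand only
            atoms[-1] = ("O", "O", 500, "HOH", "W", (8.0, 0.0, 0.0))
        return tiny_system(
            atoms, ligand_roles={"LIG": {"N1": ["donor", "cation"]}}
        )

    def test_single_bridge_detected(self):
        top, frame = self.bridge_system()
        bridges = detect_water_bridges(
            frame, top, np.array([0]), np.array([1])
        )
        assert len(bridges) == 1
        b = bridges[0]
        assert (b.ligand_atom, b.water_residue, b.target_atom) == (0, 500, 1)

    def test_no_waters_warns_and_returns_empty(self):
        top, frame = self.bridge_system(with_water=False)
        with pytest.warns(UserWarning):
            assert (
                detect_water_bridges(frame, top, np.array([0]), np.array([1]))
                == []
            )

    def test_single_leg_is_not_a_bridge(self):
        top, frame = self.bridge_system(ligand_leg_only=True)
        assert (
            detect_water_bridges(frame, top, np.array([0]), np.array([1])) == []
        )


class TestClassification:
    def test_direct_wins_even_with_bridges(self):
        sentinel_direct = [object()]
        sentinel_bridge = [object()]
        assert (
            classify_frame(sentinel_direct, sentinel_bridge)
            is ContactCategory.DIRECT_INTERACTION
        )

    def test_bridge_only_is_water_mediated(self):
        assert (
            classify_frame([], [object()])
            is ContactCategory.WATER_MEDIATED_ONLY
        )

    def test_nothing_is_no_polar_contact(self):
        assert classify_frame([], []) is ContactCategory.NO_POLAR_CONTACT

    def test_direct_frames_invariant_to_water_removal(self, sim_manifest):
        """Stripping all waters never changes a DIRECT frame's category."""
        from aquabridge.synthetic import GroundTruth, generate_frames
        from aquabridge.topology import select_atoms

        truth = GroundTruth(seed=3, n_replicas=1, n_frames=60, dt_ns=0.1,
                            p_bridge=0.9)
        top, frames, log = generate_frames(truth, 0)
        lig = select_atoms(top, resname="LIG")
        focal = select_atoms(top, chain="A", resid=95)
        keep = ~top.is_water
        dry_top = Topology(
            names=top.names[keep], elements=top.elements[keep],
            resids=top.resids[keep], resnames=top.resnames[keep],
            chains=top.chains[keep], is_water=top.is_water[keep],
            roles={k: v[keep] for k, v in top.roles.items()},
        )
        remap = np.cumsum(keep) - 1
        dry_lig, dry_focal = remap[lig], remap[focal]
        checked = 0
        for coords in frames:
            frame = Frame(index=0, time_ns=0.0, coords=coords)
            direct = detect_hbonds(frame, top, lig, focal) + detect_salt_bridges(
                frame, top, lig, focal
            )
            bridges = detect_water_bridges(frame, top, lig, focal)
            if classify_frame(direct, bridges) is not ContactCategory.DIRECT_INTERACTION:
                continue
            dry_frame = Frame(index=0, time_ns=0.0, coords=coords[keep])
            dry_direct = detect_hbonds(
                dry_frame, dry_top, dry_lig, dry_focal
            ) + detect_salt_bridges(dry_frame, dry_top, dry_lig, dry_focal)
            with pytest.warns(UserWarning):
                dry_bridges = detect_water_bridges(
                    dry_frame, dry_top, dry_lig, dry_focal
                )
            assert (
                classify_frame(dry_direct, dry_bridges)
                is ContactCategory.DIRECT_INTERACTION
            )
            checked += 1
        assert checked > 0


class TestHydrophobic:
    def carbons(self, d):
        return tiny_system(
            [
                ("C1", "C", 1, "LIG", "L", (0.0, 0.0, 0.0)),
                ("CB", "C", 217, "VAL", "A", (d, 0.0, 0.0)),
            ],
            ligand_roles={"LIG": {"C1": ["hydrophobic"]}},
        )

    @pytest.mark.parametrize(
        "d,expected", [(4.0, 1), (10.0, 0), (4.5, 1)]
    )
    def test_cutoff_inclusive(self, d, expected):
        top, frame = self.carbons(d)
        out = detect_hydrophobic_contacts(
            frame, top, np.array([0]), [("A", 217)]
        )
        assert len(out) == expected
        if expected:
            assert out[0].min_distance_A == pytest.approx(d)
            assert out[0].residue_seq == 217


class TestMinDistance:
    def test_three_four_five(self):
        top, frame = tiny_system(
            [
                ("C1", "C", 1, "LIG", "L", (0.0, 0.0, 0.0)),
                ("C2", "C", 1, "LIG", "L", (3.0, 4.0, 0.0)),
            ]
        )
        assert min_distance(frame, top, np.array([0]), np.array([1])) == 5.0

    def test_minimum_image_in_cubic_box(self):
        top, frame = tiny_system(
            [
                ("C1", "C", 1, "LIG", "L", (0.5, 5.0, 5.0)),
                ("C2", "C", 1, "LIG", "L", (9.5, 5.0, 5.0)),
            ]
        )
        frame = Frame(index=0, time_ns=0.0, coords=frame.coords,
                      box=np.eye(3) * 10.0)
        assert min_distance(frame, top, np.array([0]), np.array([1])) == (
            pytest.approx(1.0)
        )

    def test_identical_selection_uses_distinct_pairs(self):
        top, frame = tiny_system(
            [
                ("C1", "C", 1, "LIG", "L", (0.0, 0.0, 0.0)),
                ("C2", "C", 1, "LIG", "L", (2.0, 0.0, 0.0)),
            ]
        )
        sel = np.array([0, 1])
        assert min_distance(frame, top, sel, sel) == pytest.approx(2.0)

    def test_empty_selection_raises(self):
        top, frame = tiny_system(
            [("C1", "C", 1, "LIG", "L", (0.0, 0.0, 0.0))]
        )
        with pytest.raises(EmptySelectionError):
            min_distance(frame, top, np.array([], dtype=int), np.array([0]))


class TestOracleEquivalence:
    """Vectorised detectors vs independent brute-force loops."""

    N_FRAMES = 200  # the acceptance suite runs 1000

    def test_all_detectors_match_brute_force(self, criteria):
        from .conftest import make_random_system

        rng = np.random.default_rng(2024)
        for trial in range(self.N_FRAMES):
            top, frame, ga, gb = make_random_system(rng)
            got_hb = {
                (b.donor_atom, b.acceptor_atom, round(b.distance_A, 9))
                for b in detect_hbonds(frame, top, ga, gb, criteria)
            }
            assert got_hb == brute_hbonds(frame, top, ga, gb, criteria)
            got_sb = {
                (b.cation_atom, b.anion_atom, round(b.distance_A, 9))
                for b in detect_salt_bridges(frame, top, ga, gb, criteria)
            }
            assert got_sb == brute_salt_bridges(frame, top, ga, gb, criteria)
            if top.is_water.any():
                got_wb = {
                    (b.ligand_atom, b.water_residue, b.target_atom)
                    for b in detect_water_bridges(frame, top, ga, gb, criteria)
                }
                assert got_wb == brute_water_bridges(frame, top, ga, gb, criteria)
            residue_set = sorted(
                {("A", int(r)) for r in top.resids[~top.is_water]}
            )
            got_hyd = {
                (c.residue_seq, round(c.min_distance_A, 9))
                for c in detect_hydrophobic_contacts(
                    frame, top, ga, residue_set, criteria=criteria
                )
            }
            assert got_hyd == brute_hydrophobic(frame, top, ga, residue_set, criteria)
            if ga.size and gb.size:
                got = min_distance(frame, top, ga, gb)
                want = brute_min_distance(
                    frame, ga, gb, [12.0, 12.0, 12.0]
                )
                assert got == pytest.approx(want, abs=1e-9)

    def test_loosening_cutoffs_is_monotone(self):
        from .conftest import make_random_system

        rng = np.random.default_rng(7)
        for _ in range(50):
            top, frame, ga, gb = make_random_system(rng)
            tight = ContactCriteria(hbond_distance_A=3.0, salt_bridge_A=3.5,
                                    hydrophobic_A=4.0)
            loose = ContactCriteria(hbond_distance_A=3.8, salt_bridge_A=4.5,
                                    hydrophobic_A=5.0)
            assert len(detect_hbonds(frame, top, ga, gb, loose)) >= len(
                detect_hbonds(frame, top, ga, gb, tight)
            )
            assert len(detect_salt_bridges(frame, top, ga, gb, loose)) >= len(
                detect_salt_bridges(frame, top, ga, gb, tight)
            )
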