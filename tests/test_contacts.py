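"""Salt bridges, hydrogen bonds, disulfides — geometric rules and the
brute-force enumeration oracle."""

import numpy as np
import pytest

from conftest import chain_with_disulfides
from idrg.contacts import (
    HBondCriteria,
    find_disulfides,
    find_hbonds,
    find_salt_bridges,
    summarize_contacts,
)
from idrg.fixtures import (
    ChainRecipe,
    DesignedContact,
    ResidueRecipe,
    ToyComplexRecipe,
    beta_bridge_recipe,
    make_toy_complex,
    salt_bridge_recipe,
)
from idrg.structure import Atom, Chain, ComplexPartition, Residue, StructureModel, partition_complex

# donor/acceptor atom sets used by the independent brute-force oracle
_DONORS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACCEPTORS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def brute_force_salt_bridges(model, segment_id, cutoff=4.0, include_termini=True):
    """Exhaustive all-pairs enumeration, written independently of the
    package's KD-tree path."""
    pairs = []
    atoms = []
    for chain in model.chains:
        std = [r for r in chain.residues if r.is_standard_aa]
        for res in std:
            for a in res.atoms:
                role = None
                if a.name in _DONORS.get(res.res_name, ()):
                    role = "D"
                elif a.name in _ACCEPTORS.get(res.res_name, ()):
                    role = "A"
                elif include_termini and res is std[0] and a.name == "N":
                    role = "D"
                elif include_termini and res is std[-1] and a.name in ("O", "OXT"):
                    role = "A"
                if role:
                    atoms.append((role, chain.chain_id, res.seq_id, a.name, a.coord))
    for r1, c1, s1, n1, x1 in atoms:
        for r2, c2, s2, n2, x2 in atoms:
            if r1 == "D" and r2 == "A" and (c1 == segment_id) != (c2 == segment_id):
                if np.linalg.norm(x1 - x2) < cutoff:
                    pairs.append(((c1, s1, n1), (c2, s2, n2)))
    return sorted(pairs)


def arg_glu_bidentate():
    """ARG guanidinium facing a GLU carboxylate so that both NH atoms are
    within 4 Å of both OE atoms — 4 atom-pair bridges."""
    return ToyComplexRecipe(
        name="toy_bidentate",
        chains=[
            ChainRecipe(
                "A",
                [
                    ResidueRecipe(
                        "ARG",
                        {
                            "N": (-3.0, 0.0, 0.0),
                            "CA": (-2.0, 0.0, 0.0),
                            "CZ": (-1.0, 0.0, 0.0),
                            "NH1": (0.0, 1.15, 0.0),
                            "NH2": (0.0, -1.15, 0.0),
                        },
                    )
                ],
            ),
            ChainRecipe(
                "B",
                [
                    ResidueRecipe(
                        "GLU",
                        {
                            "N": (6.0, 0.0, 0.0),
                            "CA": (5.0, 0.0, 0.0),
                            "CD": (4.0, 0.0, 0.0),
                            "OE1": (3.0, 1.1, 0.0),
                            "OE2": (3.0, -1.1, 0.0),
                        },
                    )
                ],
            ),
        ],
        contacts=[DesignedContact(("A", "1", "NH1"), ("B", "1", "OE1"), np.hypot(3.0, 0.05))],
    )


class TestSaltBridges:
    def test_single_designed_pair_detected(self):
        model = make_toy_complex(salt_bridge_recipe(3.9))
        bridges = find_salt_bridges(partition_complex(model, "A"))
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.9, abs=0.01)
        assert (bridges[0].donor.atom_name, bridges[0].acceptor.atom_name) == ("NZ", "OE1")

    def test_pair_beyond_cutoff_rejected(self):
        model = make_toy_complex(salt_bridge_recipe(4.05))
        assert find_salt_bridges(partition_complex(model, "A")) == []

    def test_bidentate_arg_glu_counts_four_atom_pairs(self):
        model = make_toy_complex(arg_glu_bidentate())
        part = partition_complex(model, "A")
        bridges = find_salt_bridges(part, include_termini=False)
        assert len(bridges) == 4
        ours = sorted(
            (
                (b.donor.chain_id, b.donor.seq_id, b.donor.atom_name),
                (b.acceptor.chain_id, b.acceptor.seq_id, b.acceptor.atom_name),
            )
            for b in bridges
        )
        assert ours == brute_force_salt_bridges(model, "A", include_termini=False)

    @pytest.mark.parametrize("distance", [2.8, 3.5, 3.99])
    def test_matches_brute_force_enumeration(self, distance):
        model = make_toy_complex(salt_bridge_recipe(distance))
        part = partition_complex(model, "A")
        ours = sorted(
            (
                (b.donor.chain_id, b.donor.seq_id, b.donor.atom_name),
                (b.acceptor.chain_id, b.acceptor.seq_id, b.acceptor.atom_name),
            )
            for b in find_salt_bridges(part)
        )
        assert ours == brute_force_salt_bridges(model, "A")

    def test_invariant_under_rigid_transformation(self):
        from scipy.spatial.transform import Rotation

        model = make_toy_complex(salt_bridge_recipe(3.5))
        n_before = len(find_salt_bridges(partition_complex(model, "A")))
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([13.0, -7.0, 42.0])
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.coord = atom.coord @ rot.T + shift
        assert len(find_salt_bridges(partition_complex(model, "A"))) == n_before

    def test_bridge_residues_lose_sasa_on_binding(self):
        from idrg.sasa import interface_map

        model = make_toy_complex(salt_bridge_recipe(3.5))
        part = partition_complex(model, "A")
        residues, _ = interface_map(part, n_points=240)
        interface_keys = {(r.chain_id, r.seq_id) for r in residues if r.dsasa > 0.1}
        for b in find_salt_bridges(part):
            assert (b.donor.chain_id, b.donor.seq_id) in interface_keys
            assert (b.acceptor.chain_id, b.acceptor.seq_id) in interface_keys


class TestHydrogenBonds:
    def _nh_oc_pair(self, d_da, bend_deg=0.0):
        """Backbone N-H donor on chain A facing a carbonyl O on chain B."""
        bend = np.deg2rad(bend_deg)
        acceptor_dir = np.array([np.cos(bend), np.sin(bend), 0.0])
        o_pos = tuple(np.array([0.0, 0.0, 0.0]) + d_da * acceptor_dir)
        return ToyComplexRecipe(
            name="toy_nh_oc",
            chains=[
                ChainRecipe(
                    "A",
                    [
                        ResidueRecipe("GLY", {"N": (-2.4, -1.0, 0.0), "CA": (-1.4, -1.0, 0.0), "C": (-0.7, 0.2, 0.0), "O": (-1.2, 1.3, 0.0)}),
                        ResidueRecipe("GLY", {"N": (0.0, 0.0, 0.0), "CA": (-0.4, -1.4, 0.0), "C": (-1.8, -1.9, 0.0), "O": (-2.8, -1.2, 0.0)}),
                    ],
                ),
                ChainRecipe(
                    "B",
                    [ResidueRecipe("GLY", {"N": (5.0, 3.0, 0.0), "CA": (4.0, 3.0, 0.0), "C": (3.3, 1.9, 0.0), "O": o_pos})],
                ),
            ],
        )

    def test_canonical_backbone_bond_found(self):
        model = make_toy_complex(self._nh_oc_pair(2.9))
        hbonds = find_hbonds(partition_complex(model, "A"))
        donors = [(h.donor.chain_id, h.donor.atom_name, h.acceptor.atom_name) for h in hbonds]
        assert ("A", "N", "O") in donors

    def test_long_distance_rejected(self):
        model = make_toy_complex(self._nh_oc_pair(4.2))
        hbonds = find_hbonds(partition_complex(model, "A"))
        assert not any(h.donor.chain_id == "A" and h.donor.atom_name == "N" for h in hbonds)

    def test_beta_bridge_matches_brute_force(self):
        from idrg.contacts import _collect_hb_atoms, _angle

        model = make_toy_complex(beta_bridge_recipe())
        part = partition_complex(model, "A")
        ours = {(h.donor.chain_id, h.donor.seq_id, h.donor.atom_name, h.acceptor.chain_id, h.acceptor.seq_id, h.acceptor.atom_name) for h in find_hbonds(part)}
        # exhaustive enumeration over every donor/acceptor pair
        crit = HBondCriteria()
        donors, acceptors = _collect_hb_atoms(model.chains)
        expected = set()
        for dref, dc, h, ante in donors:
            for aref, ac in acceptors:
                if (dref.chain_id == "A") == (aref.chain_id == "A"):
                    continue
                if np.linalg.norm(dc - ac) > crit.max_da:
                    continue
                if h is not None:
                    if _angle(dc, h, ac) < crit.min_dha_angle:
                        continue
                elif ante is not None and _angle(ante, dc, ac) < crit.min_fallback_angle:
                    continue
                expected.add((dref.chain_id, dref.seq_id, dref.atom_name, aref.chain_id, aref.seq_id, aref.atom_name))
        assert ours == expected
        assert len(ours) >= 1


class TestDisulfides:
    def test_canonical_bond_detected(self):
        chain = chain_with_disulfides(10, 1)
        bonds = find_disulfides(chain)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.04, abs=0.001)

    def test_long_sg_pair_rejected(self):
        chain = chain_with_disulfides(10, 1)
        for res in chain.residues:
            sg = res.atom("SG")
            if sg is not None and res.seq_id == "2":
                sg.coord = sg.coord + np.array([1.5, 0.0, 0.0])  # 3.54 Å apart
        assert find_disulfides(chain) == []

    def test_greedy_pairing_on_cys_cluster(self):
        # three clustered CYS: only the nearest pair bonds
        residues = []
        for i, x in enumerate([0.0, 2.04, 4.3]):
            residues.append(
                Residue("A", str(i + 1), "CYS", [Atom("CA", "C", np.array([x, 3.0, 0.0])), Atom("SG", "S", np.array([x, 0.0, 0.0]))], True)
            )
        chain = Chain("A", residues)
        bonds = find_disulfides(chain)
        # enumerate all pairings: {1-2}, {2-3} are feasible; greedy takes 1-2
        assert len(bonds) == 1
        assert {bonds[0].sg_a.seq_id, bonds[0].sg_b.seq_id} == {"1", "2"}


class TestContactSummary:
    def test_per_100_normalization(self):
        bridges = [object()] * 6
        s = summarize_contacts(bridges, [], 1250.0)
        assert s.salt_bridges_per_100 == pytest.approx(0.48)

    def test_reference_scale_arithmetic(self):
        s = summarize_contacts([], [object()] * 12, 1411.1)
        assert s.hbonds_per_100 == pytest.approx(12 / 14.111, abs=1e-4)

    def test_zero_contacts(self):
        s = summarize_contacts([], [], 500.0)
        assert s.n_salt_bridges == 0 and s.hbonds_per_100 == 0.0

    def test_zero_area_with_contacts_raises(self):
        with pytest.raises(ValueError):
            summarize_contacts([object()], [], 0.0)
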