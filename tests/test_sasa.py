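"""Shrake–Rupley SASA oracles, Gly-X-Gly references, and interface
core/rim classification."""

import numpy as np
import pytest

from conftest import single_atom_chain
from idrg.builder import build_peptide
from idrg.fixtures import (
    buried_leucine_recipe,
    make_toy_complex,
    salt_bridge_recipe,
    separated_pair_recipe,
)
from idrg.sasa import (
    RadiiTable,
    composition_profile,
    enrichment,
    fibonacci_sphere,
    interface_map,
    reference_gxg,
    shrake_rupley,
)
from idrg.structure import Chain, ComplexPartition, partition_complex

RT17 = RadiiTable(overrides={("GLY", "CA"): 1.7})


class TestShrakeRupley:
    def test_isolated_sphere_analytic(self):
        res = shrake_rupley(single_atom_chain(), RT17, probe=1.4, n_points=960)
        analytic = 4 * np.pi * 3.1**2
        assert res.total == pytest.approx(analytic, rel=0.005)

    def test_two_sphere_burial_matches_cap_formula(self):
        # equal spheres R = 3.1 at center distance 3.0: each loses a cap
        # of area 2πRh with h = R − d/2 = 1.6
        a = single_atom_chain(coord=(0, 0, 0), chain_id="A")
        b = single_atom_chain(coord=(3.0, 0, 0), chain_id="B")
        res = shrake_rupley([a, b], RT17, probe=1.4, n_points=960)
        cap = 2 * np.pi * 3.1 * 1.6
        expected_each = 4 * np.pi * 3.1**2 - cap
        assert cap == pytest.approx(31.16, abs=0.01)
        for sasa in res.atom_sasa:
            assert sasa == pytest.approx(expected_each, rel=0.01)

    def test_point_count_convergence(self):
        chain = build_peptide(["ALA", "GLU", "TRP", "LYS", "SER"] * 10)
        lo = shrake_rupley(chain, n_points=480).total
        hi = shrake_rupley(chain, n_points=960).total
        assert abs(hi - lo) / hi < 0.003

    def test_matches_independent_implementation(self):
        """< 2% total-SASA deviation from a separate Shrake–Rupley code."""
        import biotite.structure as struc

        chain = build_peptide(["MET", "PHE", "GLY", "ASP", "ARG", "TYR", "VAL", "ASN"])
        mine = shrake_rupley(chain, n_points=960)
        atoms = [(r, a) for r in chain.residues for a in r.atoms]
        arr = struc.AtomArray(len(atoms))
        for i, (r, a) in enumerate(atoms):
            arr.coord[i] = a.coord
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.res_id[i] = int(r.seq_id)
            arr.res_name[i] = r.res_name
            arr.chain_id[i] = "A"
        ref = np.nansum(struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="ProtOr"))
        assert abs(mine.total - ref) / ref < 0.02

    def test_unknown_atom_raises(self):
        chain = single_atom_chain()
        chain.residues[0].atoms[0].name = "Q1"
        chain.residues[0].atoms[0].element = "XX"
        chain.residues[0].res_name = "LIG"
        with pytest.raises(KeyError, match="radius"):
            shrake_rupley(chain, RadiiTable(), n_points=96)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            shrake_rupley(single_atom_chain(), RT17, n_points=10)
        with pytest.raises(ValueError):
            shrake_rupley(single_atom_chain(), RT17, probe=-1.0)

    def test_fibonacci_points_unit_norm(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestIonRadii:
    def test_charmm_ion_radii(self):
        rt = RadiiTable()
        assert rt.radius("ZN", "ZN", "ZN") == pytest.approx(1.09)
        assert rt.radius("NA", "NA", "NA") == pytest.approx(1.36375)
        assert rt.radius("CA", "CA", "CA") == pytest.approx(1.367)


class TestReferenceGxg:
    def test_self_normalization_is_unity(self, gxg_reference):
        chain = build_peptide(["GLY", "TRP", "GLY"])
        res = shrake_rupley(chain, n_points=240)
        rsasa = res.residue_sasa[("A", "2")] / gxg_reference["TRP"]
        assert rsasa == pytest.approx(1.0, abs=1e-9)

    def test_size_ordering(self, gxg_reference):
        assert gxg_reference["TRP"] > gxg_reference["PHE"] > gxg_reference["ALA"] > gxg_reference["GLY"]

    def test_covers_all_twenty(self, gxg_reference):
        assert len(gxg_reference) == 20
        assert all(v > 0 for v in gxg_reference.values())

    def test_against_independent_sasa_on_same_tripeptides(self, gxg_reference):
        import biotite.structure as struc

        for res_name in ("GLY", "LEU", "ARG", "TRP"):
            chain = build_peptide(["GLY", res_name, "GLY"])
            atoms = [(r, a) for r in chain.residues for a in r.atoms]
            arr = struc.AtomArray(len(atoms))
            for i, (r, a) in enumerate(atoms):
                arr.coord[i] = a.coord
                arr.atom_name[i] = a.name
                arr.element[i] = a.element
                arr.res_id[i] = int(r.seq_id)
                arr.res_name[i] = r.res_name
                arr.chain_id[i] = "A"
            per_atom = struc.sasa(arr, probe_radius=1.4, point_number=240, vdw_radii="ProtOr")
            ref_central = np.nansum(per_atom[arr.res_id == 2])
            assert gxg_reference[res_name] == pytest.approx(ref_central, rel=0.15)


class TestInterfaceMap:
    def test_distant_chains_have_no_interface(self):
        model = make_toy_complex(separated_pair_recipe(20.0))
        residues, summary = interface_map(partition_complex(model, "A"), n_points=240)
        assert summary.interface_area == pytest.approx(0.0, abs=0.05)
        assert all(r.region == "none" for r in residues)

    def test_contact_pair_buries_area(self):
        model = make_toy_complex(salt_bridge_recipe(3.5))
        residues, summary = interface_map(partition_complex(model, "A"), n_points=240)
        assert summary.interface_area > 10
        touching = [r for r in residues if r.region != "none"]
        assert {r.res_name for r in touching} == {"LYS", "GLU"}

    def test_fully_buried_leucine_is_core(self):
        model = make_toy_complex(buried_leucine_recipe())
        residues, _ = interface_map(partition_complex(model, "A"), n_points=240)
        leu = next(r for r in residues if r.res_name == "LEU")
        assert leu.rsasa_bound <= 0.25
        assert leu.rsasa_free > 0.25
        assert leu.region == "core"

    def test_burial_never_negative(self):
        model = make_toy_complex(buried_leucine_recipe())
        residues, _ = interface_map(partition_complex(model, "A"), n_points=240)
        assert all(r.dsasa >= -0.01 for r in residues)

    def test_region_partition_disjoint_and_complete(self):
        model = make_toy_complex(buried_leucine_recipe())
        residues, summary = interface_map(partition_complex(model, "A"), n_points=240)
        interface = [r for r in residues if r.dsasa > 0.1]
        assert all(r.region in ("core", "rim", "support") for r in interface)
        n_counted = sum(
            summary.region_counts[side][reg] for side in ("segment", "partner") for reg in ("core", "rim", "support")
        )
        assert n_counted == len(interface)

    def test_interface_area_symmetric_under_side_swap(self):
        model = make_toy_complex(salt_bridge_recipe(3.5))
        _, s_ab = interface_map(partition_complex(model, "A"), n_points=240)
        _, s_ba = interface_map(partition_complex(model, "B"), n_points=240)
        assert s_ab.interface_area == pytest.approx(s_ba.interface_area, abs=1e-9)


class TestComposition:
    def test_counting(self):
        profile = composition_profile(["ALA"] * 4 + ["GLY"] * 6)
        assert profile["A"] == pytest.approx(0.4)
        assert profile["G"] == pytest.approx(0.6)
        assert sum(profile.values()) == pytest.approx(1.0)

    def test_flexibility_ordering(self):
        profile = composition_profile(["ALA", "GLY"])
        keys = list(profile)
        assert keys[0] == "W" and keys[-1] == "K" and len(keys) == 20

    def test_self_enrichment_is_zero(self):
        p = composition_profile(["LYS", "GLU", "LEU"])
        assert all(v == pytest.approx(0.0) for v in enrichment(p, p).values())

    def test_averaged_vs_pooled_differ_on_unequal_complexes(self):
        # complex 1: 1 ALA of 1 residue; complex 2: 1 ALA + 9 GLY.
        # pooled: A = 2/11; per-complex averaged: (1 + 0.1)/2 = 0.55
        pooled = composition_profile(["ALA"] + ["ALA"] + ["GLY"] * 9)
        per_complex = [composition_profile(["ALA"]), composition_profile(["ALA"] + ["GLY"] * 9)]
        averaged_a = np.mean([p["A"] for p in per_complex])
        assert pooled["A"] == pytest.approx(2 / 11)
        assert averaged_a == pytest.approx(0.55)
        assert abs(averaged_a - pooled["A"]) > 0.3

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            composition_profile([])
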