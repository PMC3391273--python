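"""Descriptor panel: SASA, H-bonds, salt bridges, dihedrals, census, NCPR."""

import numpy as np
import pytest

from enmfold import synthetic_data as sd
from enmfold.enm_core import build_kirchhoff, pseudo_inverse
from enmfold.stability_metrics import (
    ResidueClassScheme,
    classify_glycines,
    count_hbonds,
    count_salt_bridges,
    buried_hydrophilic_report,
    dihedral,
    hot_spots,
    ncpr,
    residue_census,
    sasa,
)
from enmfold.structure_io import CaModel, DomainMap, Residue, parse_pdb, write_pdb


def _translate(model, offset):
    offset = np.asarray(offset, dtype=float)
    residues = [
        Residue(
            chain_id=r.chain_id,
            seq_number=r.seq_number + 1000,
            insertion_code=r.insertion_code,
            name=r.name,
            ca_coord=r.ca_coord + offset,
            bfactor_exp=r.bfactor_exp,
            atoms=tuple((n, e, c + offset) for n, e, c in r.atoms),
        )
        for r in model.residues
    ]
    return residues


class TestResidueClassScheme:
    def test_partition_of_standard_residues(self):
        scheme = ResidueClassScheme()
        from enmfold.structure_io import STANDARD_RESIDUES

        classes = {name: scheme.classify(name) for name in STANDARD_RESIDUES}
        assert set(classes.values()) == {"hydrophilic", "hydrophobic", "other"}
        assert sum(v == "hydrophilic" for v in classes.values()) == 7
        assert sum(v == "hydrophobic" for v in classes.values()) == 7


class TestSasa:
    def test_isolated_alanine_close_to_dense_reference(self, helix_fa_12):
        iso = CaModel(residues=[helix_fa_12.residues[5]], source_id="iso")
        coarse = sasa(iso, n_points=960).total
        dense = sasa(iso, n_points=5000).total
        assert coarse == pytest.approx(dense, rel=0.05)

    def test_additivity_of_far_separated_copies(self, helix_fa_12):
        single = sasa(helix_fa_12).total
        doubled_model = CaModel(
            residues=list(helix_fa_12.residues)
            + _translate(helix_fa_12, [500.0, 0, 0]),
            source_id="two_copies",
        )
        assert sasa(doubled_model).total == pytest.approx(2 * single, rel=1e-6)

    def test_rotation_invariance(self, helix_fa_12):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [31, -72, 115], degrees=True).as_matrix()
        rotated = CaModel(
            residues=[
                Residue(
                    chain_id=r.chain_id,
                    seq_number=r.seq_number,
                    insertion_code=r.insertion_code,
                    name=r.name,
                    ca_coord=rot @ r.ca_coord,
                    bfactor_exp=r.bfactor_exp,
                    atoms=tuple((n, e, rot @ c) for n, e, c in r.atoms),
                )
                for r in helix_fa_12.residues
            ],
            source_id="rot",
        )
        # same sphere-point set, rotated atoms: small residual quadrature
        # differences only
        assert sasa(rotated).total == pytest.approx(
            sasa(helix_fa_12).total, rel=0.02
        )

    def test_smaller_probe_gives_smaller_area(self, helix_fa_12):
        assert (
            sasa(helix_fa_12, probe_radius=0.01).total
            < sasa(helix_fa_12, probe_radius=1.4).total
        )

    def test_class_split_sums_to_total(self, helix_fa_12):
        res = sasa(helix_fa_12)
        total_by_class = sum(v for v, _ in res.by_class.values())
        assert total_by_class == pytest.approx(res.total, rel=1e-9)


class TestHBonds:
    def test_helix_ladder_i_to_i_plus_4(self, helix_fa_12):
        total, bb, sc, bonds = count_hbonds(helix_fa_12)
        assert sc == 0
        donors = {(b.donor_index, b.acceptor_index) for b in bonds}
        # every interior turn: donor i -> acceptor i-4 for i = 4..11
        assert donors == {(i, i - 4) for i in range(4, 12)}
        for b in bonds:
            assert b.distance <= 3.0
            assert b.angle >= 150.0

    def test_no_polar_partners_in_range(self):
        model = sd.make_charged_pair(10.0)
        total, _, _, _ = count_hbonds(model)
        assert total == 0

    def test_spatial_index_equals_brute_force(self, helix_fa_12):
        fast = count_hbonds(helix_fa_12, use_spatial_index=True)
        slow = count_hbonds(helix_fa_12, use_spatial_index=False)
        assert fast[:3] == slow[:3]
        assert fast[3] == slow[3]

    def test_one_bond_per_donor(self, helix_fa_12):
        _, _, _, bonds = count_hbonds(helix_fa_12)
        donors = [(b.donor_index, b.donor_atom) for b in bonds]
        assert len(donors) == len(set(donors))


class TestSaltBridges:
    def test_pair_within_cutoff(self):
        n, bridges = count_salt_bridges(sd.make_charged_pair(3.2))
        assert n == 1
        assert bridges[0].min_distance == pytest.approx(3.2, abs=1e-6)

    def test_pair_beyond_cutoff(self):
        assert count_salt_bridges(sd.make_charged_pair(3.8))[0] == 0

    def test_threshold_step_function(self):
        for d in np.arange(2.5, 4.51, 0.25):
            expected = 1 if d <= 3.5 else 0
            assert count_salt_bridges(sd.make_charged_pair(float(d)))[0] == expected

    def test_spatial_index_equals_brute_force(self, rng):
        # scatter several charged pairs into one model
        residues = []
        for k in range(6):
            pair = sd.make_charged_pair(float(2.8 + 0.3 * k))
            offset = rng.uniform(-20, 20, size=3)
            for r in pair.residues:
                residues.append(
                    Residue(
                        chain_id="A",
                        seq_number=len(residues) + 1,
                        insertion_code="",
                        name=r.name,
                        ca_coord=r.ca_coord + offset,
                        bfactor_exp=0.0,
                        atoms=tuple(
                            (n, e, c + offset) for n, e, c in r.atoms
                        ),
                    )
                )
        model = CaModel(residues=residues, source_id="soup")
        fast_n, fast = count_salt_bridges(model, use_spatial_index=True)
        slow_n, slow = count_salt_bridges(model, use_spatial_index=False)
        assert fast_n == slow_n
        assert fast == slow


class TestGlycineClassification:
    def _gly_model(self, phi, psi):
        ncac = sd._build_backbone(3, phi, psi)
        residues = []
        for i, (n, ca, c) in enumerate(ncac):
            residues.append(
                Residue(
                    chain_id="A",
                    seq_number=i + 1,
                    insertion_code="",
                    name="GLY" if i == 1 else "ALA",
                    ca_coord=np.asarray(ca),
                    bfactor_exp=0.0,
                    atoms=(
                        ("N", "N", np.asarray(n)),
                        ("CA", "C", np.asarray(ca)),
                        ("C", "C", np.asarray(c)),
                    ),
                )
            )
        return CaModel(residues=residues, source_id="gly")

    @pytest.mark.parametrize(
        "phi,expected",
        [(71.15, "phi+"), (-92.62, "phi-"), (82.59, "phi+"), (-70.78, "phi-")],
    )
    def test_sign_classification(self, phi, expected):
        table = classify_glycines(self._gly_model(phi, -120.0))
        assert len(table) == 1
        assert table["phi"].iloc[0] == pytest.approx(phi, abs=1e-6)
        assert table["cls"].iloc[0] == expected

    def test_phi_zero_is_phi_plus(self):
        # exactly planar cis geometry: phi is exactly 0.0
        prev = Residue(
            chain_id="A", seq_number=1, insertion_code="", name="ALA",
            ca_coord=np.array([-1.0, 2.0, 0.0]), bfactor_exp=0.0,
            atoms=(("CA", "C", np.array([-1.0, 2.0, 0.0])),
                   ("C", "C", np.array([0.0, 1.0, 0.0]))),
        )
        gly = Residue(
            chain_id="A", seq_number=2, insertion_code="", name="GLY",
            ca_coord=np.array([1.0, 0.0, 0.0]), bfactor_exp=0.0,
            atoms=(("N", "N", np.array([0.0, 0.0, 0.0])),
                   ("CA", "C", np.array([1.0, 0.0, 0.0])),
                   ("C", "C", np.array([1.0, 1.0, 0.0]))),
        )
        model = CaModel(residues=[prev, gly], source_id="cis")
        table = classify_glycines(model)
        assert table["phi"].iloc[0] == 0.0
        assert table["cls"].iloc[0] == "phi+"

    def test_terminal_glycine_undefined(self):
        model = self._gly_model(60.0, -45.0)
        # make the FIRST residue the glycine: no preceding C
        renamed = CaModel(
            residues=[
                Residue(
                    chain_id=r.chain_id,
                    seq_number=r.seq_number,
                    insertion_code=r.insertion_code,
                    name="GLY" if i == 0 else "ALA",
                    ca_coord=r.ca_coord,
                    bfactor_exp=r.bfactor_exp,
                    atoms=r.atoms,
                )
                for i, r in enumerate(model.residues)
            ],
            source_id="tgly",
        )
        table = classify_glycines(renamed)
        assert table["cls"].iloc[0] == "undefined"

    def test_dihedral_convention(self):
        # trans (180 deg) four-point reference
        p = [np.array(v, float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert dihedral(*p) == pytest.approx(180.0)


class TestCensusAndNCPR:
    def test_census_counts_and_fractions(self, path_chain_10):
        for i in (2, 7):
            object.__setattr__(path_chain_10.residues[i], "name", "PRO")
        dm = DomainMap({"N": [(1, 5)], "C": [(6, 10)]})
        table, total, frac = residue_census(path_chain_10, dm, "PRO")
        assert total == 2
        assert frac == pytest.approx(0.2)
        as_dict = dict(zip(table["domain"], table["count"]))
        assert as_dict == {"N": 1, "C": 1}
        assert table["fraction"].tolist() == pytest.approx([0.2, 0.2])
        for i in (2, 7):
            object.__setattr__(path_chain_10.residues[i], "name", "ALA")

    def test_empty_domain_zero(self, globule_50):
        dm = DomainMap({"N": [(1, 40)], "C": [(41, 50)]})
        table, _, _ = residue_census(globule_50, dm, "TRP")
        assert (table["count"] == 0).all()

    def test_ncpr_excludes_sequence_neighbors(self, path_chain_10):
        dm = DomainMap({"N": [(1, 10)]})
        table = ncpr(path_chain_10, dm, cutoff=7.0)
        # collinear 3.8 A chain: only |i-j|=1 pairs are within 7 A
        assert table["contacts"].iloc[0] == 0
        assert table["ncpr"].iloc[0] == 0.0

    def test_ncpr_two_far_residues(self):
        model = sd.make_path_chain(2, spacing=8.0)
        table = ncpr(model, DomainMap({"N": [(1, 2)]}))
        assert table["contacts"].iloc[0] == 0

    def test_ncpr_invariant_under_renumbering(self, globule_50):
        dm1 = DomainMap({"N": [(1, 25)], "C": [(26, 50)]})
        renumbered = CaModel(
            residues=[
                Residue(
                    chain_id=r.chain_id,
                    seq_number=r.seq_number + 100,
                    insertion_code=r.insertion_code,
                    name=r.name,
                    ca_coord=r.ca_coord,
                    bfactor_exp=r.bfactor_exp,
                )
                for r in globule_50.residues
            ],
            source_id="renum",
        )
        dm2 = DomainMap({"N": [(101, 125)], "C": [(126, 150)]})
        t1 = ncpr(globule_50, dm1)
        t2 = ncpr(renumbered, dm2)
        assert t1["contacts"].tolist() == t2["contacts"].tolist()
        assert t1["ncpr"].tolist() == t2["ncpr"].tolist()


class TestBuriedHydrophilic:
    def test_fully_exposed_has_no_buried(self):
        model = sd.make_charged_pair(3.2)
        res = sasa(model)
        _, _, _, bonds = count_hbonds(model)
        report = buried_hydrophilic_report(model, res, bonds)
        assert report["n_buried"] == 0
        assert report["ratio"] == 0.0

    def test_caged_asn_is_buried_with_table_capacity(self):
        # ASN side chain enclosed in a dense cage of alanine CB spheres
        asn = Residue(
            chain_id="A", seq_number=1, insertion_code="", name="ASN",
            ca_coord=np.zeros(3), bfactor_exp=0.0,
            atoms=(
                ("N", "N", np.array([-1.46, 0.0, 0.0])),
                ("CA", "C", np.array([0.0, 0.0, 0.0])),
                ("C", "C", np.array([0.9, 1.2, 0.0])),
                ("O", "O", np.array([0.4, 2.3, 0.0])),
                ("CB", "C", np.array([0.8, -1.2, 0.3])),
                ("CG", "C", np.array([2.2, -1.1, 0.3])),
                ("OD1", "O", np.array([2.9, -1.9, 0.9])),
                ("ND2", "N", np.array([2.7, -0.1, -0.3])),
            ),
        )
        cage = []
        k = 2
        for x in range(-2, 3):
            for y in range(-2, 3):
                for z in range(-2, 3):
                    pos = np.array([1.2 + 3.2 * x, -0.8 + 3.2 * y, 0.2 + 3.2 * z])
                    if np.linalg.norm(pos - np.array([1.8, -1.0, 0.2])) < 3.0:
                        continue  # leave room for the side chain itself
                    cage.append(
                        Residue(
                            chain_id="A", seq_number=k, insertion_code="",
                            name="ALA", ca_coord=pos, bfactor_exp=0.0,
                            atoms=(("CB", "C", pos),),
                        )
                    )
                    k += 1
        model = CaModel(residues=[asn] + cage, source_id="caged_asn")
        res = sasa(model)
        report = buried_hydrophilic_report(model, res, hbond_list=[])
        assert report["n_buried"] == 1
        assert report["max_capacity"] == 4  # ASN table capacity
        assert report["actual_hbonds"] == 0
        assert report["ratio"] == 0.0


class TestHotSpots:
    def test_uniform_ring_has_no_spots(self):
        t = 2 * np.pi * np.arange(12) / 12
        ring = np.stack([8.0 * np.cos(t), 8.0 * np.sin(t), np.zeros(12)], axis=1)
        residues = [
            Residue(chain_id="A", seq_number=i + 1, insertion_code="",
                    name="ALA", ca_coord=ring[i], bfactor_exp=1.0 + 0.01 * i)
            for i in range(12)
        ]
        model = CaModel(residues=residues, source_id="ring")
        spec, _ = pseudo_inverse(build_kirchhoff(model))
        report = hot_spots(model, spec, calibration_scale=1.0, n_fast=3)
        # all residues equivalent: either all or none exceed a threshold
        assert len(set(report.classes)) == 1

    def test_uncalibrated_scale_refused(self, globule_50):
        spec, _ = pseudo_inverse(build_kirchhoff(globule_50))
        with pytest.raises(ValueError, match="fit gamma|calibrated"):
            hot_spots(globule_50, spec, calibration_scale=None)

    def test_thresholds_respected(self, globule_50):
        spec, _ = pseudo_inverse(build_kirchhoff(globule_50))
        report = hot_spots(globule_50, spec, calibration_scale=0.05, n_fast=10)
        for sf, cls in zip(report.sf, report.classes):
            if cls == "hot":
                assert sf > 0.03
            elif cls == "warm":
                assert 0.01 < sf <= 0.03
            else:
                assert sf <= 0.01
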