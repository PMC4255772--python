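"""Structural parsing, geometry, ASA and the four-class residue assignment."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import ifacevol as iv
from ifacevol.structclass import (
    MAX_ASA,
    Residue3D,
    SiteClass,
    compute_residue_asa,
    classify_sites,
    labels_to_dataframe,
    read_labels_tsv,
    write_pdb,
)


def _res(chain, num, coords, elements=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return Residue3D(
        chain_id=chain,
        seq_number=num,
        res_name="GLY",
        coords=coords,
        elements=elements or ("C",) * len(coords),
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


class TestParseStructure:
    def test_chains_residues_and_heme(self, pdb_fixture):
        cx = iv.parse_structure(pdb_fixture, {"A": "mt", "B": "nuclear"})
        assert list(cx.chains) == ["A", "B"]
        assert [r.seq_number for r in cx.chains["A"]] == [1, 2]
        assert len(cx.chains["B"]) == 1
        # heme routed to hetero groups, water dropped
        assert list(cx.hetero_groups) == ["HEM/A/901"]
        assert cx.heme_groups()

    def test_altloc_resolved_to_highest_occupancy(self, pdb_fixture):
        cx = iv.parse_structure(pdb_fixture, {"A": "mt", "B": "nuclear"})
        res1 = cx.chains["A"][0]
        # N + one CA kept (altloc B at x=1.5, occupancy 0.6); H dropped
        assert res1.coords.shape == (2, 3)
        assert 1.5 in res1.coords[:, 0]
        assert 1.0 not in res1.coords[:, 0]

    def test_missing_chain_in_encoding_is_error(self, pdb_fixture):
        with pytest.raises(ValueError, match="absent|encoding"):
            iv.parse_structure(pdb_fixture, {"A": "mt", "Z": "nuclear"})

    def test_chain_filter_restricts(self, pdb_fixture):
        cx = iv.parse_structure(
            pdb_fixture, {"A": "mt", "B": "nuclear"}, chain_filter={"A"}
        )
        assert list(cx.chains) == ["A"]

    def test_pdb_roundtrip(self, toy_complex, tmp_path):
        cx, _ = toy_complex
        path = tmp_path / "toy.pdb"
        write_pdb(cx, path)
        back = iv.parse_structure(path, cx.encoding)
        assert set(back.chains) == set(cx.chains)
        for cid in cx.chains:
            assert len(back.chains[cid]) == len(cx.chains[cid])
            np.testing.assert_allclose(
                np.vstack([r.coords for r in back.chains[cid]]),
                np.vstack([r.coords for r in cx.chains[cid]]),
                atol=1e-3,
            )
        assert back.heme_groups()


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


class TestResidueDistance:
    def test_shared_coordinate_is_zero(self):
        r1 = _res("A", 1, [[0, 0, 0], [5, 5, 5]])
        r2 = _res("B", 1, [[0, 0, 0]])
        assert iv.residue_min_distance(r1, r2) == 0.0

    def test_analytic_single_atoms(self):
        assert iv.residue_min_distance(
            _res("A", 1, [[0, 0, 0]]), _res("B", 1, [[3, 0, 0]])
        ) == pytest.approx(3.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            c1, c2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) + 2
            expected = min(
                math.dist(a, b) for a in c1.tolist() for b in c2.tolist()
            )
            got = iv.residue_min_distance(_res("A", 1, c1), _res("B", 1, c2))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        r1, r2 = _res("A", 1, rng.normal(size=(4, 3))), _res("B", 1, rng.normal(size=(3, 3)))
        assert iv.residue_min_distance(r1, r2) == iv.residue_min_distance(r2, r1)


class TestContacts:
    def test_separated_chains_have_no_partners(self):
        cx = iv.ComplexStructure(
            chains={
                "A": [_res("A", 1, [[0, 0, 0]])],
                "B": [_res("B", 1, [[0, 10, 0]])],
            },
            encoding={"A": "mt", "B": "nuclear"},
        )
        partners = iv.build_contact_labels(cx, cutoff=4.0)
        assert all(not p for p in partners.values())

    def test_planted_contacts_recovered_exactly(self, toy_complex):
        cx, truth = toy_complex
        partners = iv.build_contact_labels(cx, cutoff=4.0)
        for key, cls in truth.site_classes.items():
            is_contact = cls in (SiteClass.MT_NU_CONTACT, SiteClass.MT_MT_CONTACT)
            assert bool(partners[key]) == is_contact, key

    def test_contact_symmetry(self, toy_complex):
        cx, _ = toy_complex
        partners = iv.build_contact_labels(cx, cutoff=4.0)
        chain_has_partner = {}
        for (chain, _, _), pset in partners.items():
            for other in pset:
                chain_has_partner.setdefault(chain, set()).add(other)
        for chain, others in chain_has_partner.items():
            for other in others:
                assert chain in chain_has_partner.get(other, set())

    @pytest.mark.parametrize("c1,c2", [(3.0, 4.0), (4.0, 6.0), (6.0, 12.0)])
    def test_partner_sets_monotone_in_cutoff(self, toy_complex, c1, c2):
        cx, _ = toy_complex
        small = iv.build_contact_labels(cx, cutoff=c1)
        large = iv.build_contact_labels(cx, cutoff=c2)
        for key in small:
            assert small[key] <= large[key]

    def test_hetero_groups_never_partner(self, toy_complex):
        cx, _ = toy_complex
        # place a residue right next to the heme: still no partner
        probe = _res("A", 999, cx.hetero_groups["HEM/Z/901"][0] + [0.5, 0, 0])
        cx2 = iv.ComplexStructure(
            chains={**cx.chains, "A": cx.chains["A"] + [probe]},
            hetero_groups=cx.hetero_groups,
            encoding=cx.encoding,
        )
        partners = iv.build_contact_labels(cx2, cutoff=4.0)
        assert partners[probe.key] == set()


# ---------------------------------------------------------------------------
# ASA
# ---------------------------------------------------------------------------


class TestASA:
    PROBE = 1.4
    R_C = 1.70  # carbon vdW

    def test_single_atom_closed_form(self):
        asa = compute_residue_asa([_res("A", 1, [[0, 0, 0]])], self.PROBE, 960)
        expected = 4 * math.pi * (self.R_C + self.PROBE) ** 2
        assert asa[("A", 1, "")] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_atoms_are_additive(self):
        res = [_res("A", 1, [[0, 0, 0]]), _res("A", 2, [[50, 0, 0]])]
        asa = compute_residue_asa(res, self.PROBE, 960)
        expected = 4 * math.pi * (self.R_C + self.PROBE) ** 2
        assert asa[("A", 1, "")] == pytest.approx(expected, rel=1e-9)
        assert asa[("A", 2, "")] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_overlapping_atoms_match_spherical_cap_formula(self, d):
        # closed form: accessible area of sphere 1 of radius R excluding the
        # cap hidden inside the neighbour's extended sphere
        R = self.R_C + self.PROBE
        res = [_res("A", 1, [[0, 0, 0]]), _res("A", 2, [[d, 0, 0]])]
        asa = compute_residue_asa(res, self.PROBE, 2000)
        if d >= 2 * R:
            expected = 4 * math.pi * R**2
        else:
            cos_theta = d / (2 * R)  # equal radii: cap boundary at half-distance
            cap = 2 * math.pi * R**2 * (1 - cos_theta)
            expected = 4 * math.pi * R**2 - cap
        assert asa[("A", 1, "")] == pytest.approx(expected, rel=0.02)

    def test_agrees_with_biopython_shrake_rupley(self, toy_complex, tmp_path):
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        cx, _ = toy_complex
        path = tmp_path / "toy.pdb"
        write_pdb(cx, path)
        structure = PDBParser(QUIET=True).get_structure("t", str(path))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960)
        sr.compute(structure[0], level="R")
        ours = compute_residue_asa(cx, 1.4, 960)
        for chain in structure[0]:
            for res in chain:
                if res.id[0].strip():
                    continue
                key = (chain.id, res.id[1], res.id[2].strip())
                assert ours[key] == pytest.approx(res.sasa, abs=3.0), key

    def test_nonpositive_probe_is_error(self):
        with pytest.raises(ValueError):
            compute_residue_asa([_res("A", 1, [[0, 0, 0]])], probe_radius=0.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassification:
    def test_planted_classes_and_interface_recovered(self, toy_complex, toy_labels):
        _, truth = toy_complex
        assert len(toy_labels) == len(truth.site_classes)
        for lab in toy_labels:
            assert lab.site_class == truth.site_classes[lab.key], lab.key
            assert lab.interface == truth.interface[lab.key], lab.key

    def test_classes_partition_the_residue_set(self, toy_complex, toy_labels):
        cx, _ = toy_complex
        keys = [lab.key for lab in toy_labels]
        assert len(keys) == len(set(keys))
        expected = {r.key for c in cx.mt_chains() for r in cx.chains[c]}
        assert set(keys) == expected
        for lab in toy_labels:
            assert lab.site_class in SiteClass
            assert (lab.interface is not None) == (
                lab.site_class == SiteClass.EXPOSED_NONCONTACT
            )
            assert bool(lab.partners) == (
                lab.site_class in (SiteClass.MT_NU_CONTACT, SiteClass.MT_MT_CONTACT)
            )

    def test_delta_asa_nonnegative(self, toy_labels):
        assert all(lab.delta_asa >= 0 for lab in toy_labels)

    def test_zero_delta_asa_means_noninterface(self):
        r = _res("A", 1, [[0, 0, 0]])
        asa_val = 4 * math.pi * (1.7 + 1.4) ** 2
        labels = classify_sites(
            iv.ComplexStructure(chains={"A": [r]}, encoding={"A": "mt"}),
            {r.key: asa_val},
            {r.key: asa_val},
            {r.key: set()},
        )
        assert labels[0].site_class == SiteClass.EXPOSED_NONCONTACT
        assert labels[0].interface is False

    def test_missing_asa_is_error(self):
        r = _res("A", 1, [[0, 0, 0]])
        cx = iv.ComplexStructure(chains={"A": [r]}, encoding={"A": "mt"})
        with pytest.raises(ValueError, match="missing an ASA"):
            classify_sites(cx, {}, {r.key: 1.0}, {r.key: set()})

    def test_negative_delta_asa_is_error(self):
        r = _res("A", 1, [[0, 0, 0]])
        cx = iv.ComplexStructure(chains={"A": [r]}, encoding={"A": "mt"})
        with pytest.raises(ValueError, match="ΔASA"):
            classify_sites(cx, {r.key: 1.0}, {r.key: 5.0}, {r.key: set()})

    def test_mixed_partners_take_nuclear_precedence(self):
        # one mt residue contacting both a nuclear and an mt chain
        a = _res("A", 1, [[0, 0, 0]])
        b = _res("B", 1, [[0, 3.0, 0]])
        c = _res("C", 1, [[0, -3.0, 0]])
        cx = iv.ComplexStructure(
            chains={"A": [a], "B": [b], "C": [c]},
            encoding={"A": "mt", "B": "mt", "C": "nuclear"},
        )
        labels = iv.classify_complex(cx, classify_chains=["A"], sphere_points=120)
        assert labels[0].site_class == SiteClass.MT_NU_CONTACT
        assert labels[0].partners == {"B", "C"}

    def test_labels_tsv_roundtrip(self, toy_labels, tmp_path):
        df = labels_to_dataframe(toy_labels)
        path = tmp_path / "labels.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_labels_tsv(path)
        assert list(back["site_class"]) == list(df["site_class"])
        assert list(back["resnum"]) == list(df["resnum"])


# ---------------------------------------------------------------------------
# heme distances
# ---------------------------------------------------------------------------


class TestHemeDistances:
    def test_coincident_atom_is_zero(self, toy_complex):
        cx, _ = toy_complex
        heme_xyz = cx.hetero_groups["HEM/Z/901"]
        probe = _res("A", 999, heme_xyz[0])
        cx2 = iv.ComplexStructure(
            chains={"A": cx.chains["A"] + [probe]},
            hetero_groups=cx.hetero_groups,
            encoding={"A": "mt"},
        )
        d = iv.heme_min_distances(cx2, "A")
        assert d[probe.key] == 0.0

    def test_known_offset(self):
        cx = iv.ComplexStructure(
            chains={"A": [_res("A", 1, [[0, 0, 0]])]},
            hetero_groups={"HEM/Z/1": np.array([[3.0, 4.0, 0.0]])},
            encoding={"A": "mt"},
        )
        assert iv.heme_min_distances(cx, "A")[("A", 1, "")] == pytest.approx(5.0)

    def test_matches_bruteforce_over_groups(self):
        rng = np.random.default_rng(17)
        res = [_res("A", i + 1, rng.normal(size=(3, 3)) * 5) for i in range(10)]
        hemes = {f"HEM/Z/{i}": rng.normal(size=(4, 3)) * 5 for i in range(3)}
        cx = iv.ComplexStructure(chains={"A": res}, hetero_groups=hemes, encoding={"A": "mt"})
        d = iv.heme_min_distances(cx, "A")
        all_heme = np.vstack(list(hemes.values()))
        for r in res:
            assert d[r.key] == pytest.approx(cdist(r.coords, all_heme).min())

    def test_no_hemes_is_error(self):
        cx = iv.ComplexStructure(
            chains={"A": [_res("A", 1, [[0, 0, 0]])]}, encoding={"A": "mt"}
        )
        with pytest.raises(ValueError, match="heme"):
            iv.heme_min_distances(cx, "A")
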