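"""Pharmacophore checks, pose ranking, filters, fingerprints, clustering,
site geometry, solubility and the lead-selection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys

from startriage.panel import AssayPanel
from startriage.screen import (
    CompoundRecord,
    DockedPose,
    LeadCriteria,
    PharmacophoreModel,
    PharmacophorePoint,
    SiteDefinition,
    check_pharmacophore,
    cluster_library,
    correlate_solubility_effects,
    load_allosteric_site,
    load_flag_patterns,
    parse_residue_list,
    property_filter,
    rank_poses,
    sar_by_catalogue,
    select_leads,
    site_residue_count,
    solubility_from_lcms,
    substructure_flags,
    tanimoto,
    centroid_distance,
)

FOUR_POINT_MODEL = PharmacophoreModel(
    points=(
        PharmacophorePoint("HBA", (0.0, 0.0, 0.0), 1.5),
        PharmacophorePoint("hydrophobic", (3.0, 0.0, 0.0), 2.0),
        PharmacophorePoint("hydrophobic", (0.0, 3.0, 0.0), 2.0),
        PharmacophorePoint("hydrophobic", (0.0, 0.0, 3.0), 2.0),
    ),
    mandatory_count=4,
)


class TestPharmacophore:
    def test_features_at_centers_pass(self):
        pose = DockedPose("c1", -20.0, 20, tuple(
            (p.feature_type, p.center) for p in FOUR_POINT_MODEL.points))
        count, passed = check_pharmacophore(pose, FOUR_POINT_MODEL)
        assert (count, passed) == (4, True)

    def test_one_displaced_feature_fails_mandatory_four(self):
        feats = [(p.feature_type, p.center) for p in FOUR_POINT_MODEL.points[:-1]]
        feats.append(("hydrophobic", (0.0, 0.0, 9.0)))  # beyond its 2 A radius
        pose = DockedPose("c1", -20.0, 20, tuple(feats))
        count, passed = check_pharmacophore(pose, FOUR_POINT_MODEL)
        assert (count, passed) == (3, False)

    def test_type_mismatch_does_not_satisfy(self):
        pose = DockedPose("c1", -20.0, 20, (("hydrophobic", (0.0, 0.0, 0.0)),))
        model = PharmacophoreModel(
            points=(PharmacophorePoint("HBA", (0.0, 0.0, 0.0), 2.0),), mandatory_count=1)
        assert check_pharmacophore(pose, model) == (0, False)

    def test_empty_model_refused(self):
        pose = DockedPose("c1", -20.0, 20)
        with pytest.raises(ValueError):
            check_pharmacophore(pose, PharmacophoreModel(points=(), mandatory_count=0))

    def test_random_poses_match_brute_force_oracle(self, rng):
        for _ in range(1000):
            feats = tuple(
                (rng.choice(["HBA", "hydrophobic"]), tuple(rng.uniform(-4, 4, 3)))
                for _ in range(rng.integers(1, 6))
            )
            pose = DockedPose("x", -20.0, 10, feats)
            count, _ = check_pharmacophore(pose, FOUR_POINT_MODEL)
            # oracle: all-pairs distance check
            expected = 0
            for p in FOUR_POINT_MODEL.points:
                for ftype, xyz in feats:
                    d = np.sqrt(sum((a - b) ** 2 for a, b in zip(xyz, p.center)))
                    if ftype == p.feature_type and d <= p.radius:
                        expected += 1
                        break
            assert count == expected


class TestRankPoses:
    def test_score_cutoff_is_strict(self):
        poses = [DockedPose("a", -18.5, 20), DockedPose("b", -17.0, 20),
                 DockedPose("c", -18.0, 20)]
        kept = rank_poses(poses)
        assert [p.compound_id for p in kept] == ["a"]

    def test_normalized_score_arithmetic(self):
        assert DockedPose("a", -20.0, 25).normalized_score == pytest.approx(-0.8)

    def test_order_invariant_with_stable_tie_break(self):
        poses = [DockedPose("b", -20.0, 20), DockedPose("a", -20.0, 20),
                 DockedPose("c", -30.0, 20)]
        fwd = [p.compound_id for p in rank_poses(poses)]
        rev = [p.compound_id for p in rank_poses(poses[::-1])]
        assert fwd == rev == ["c", "a", "b"]


class TestPropertyFilter:
    def test_druglike_compound_passes(self):
        rec = CompoundRecord.from_smiles("aspirin", "CC(=O)Oc1ccccc1C(=O)O")
        assert property_filter(rec).passed

    def test_oversized_compound_fails_on_mw(self):
        rec = CompoundRecord.from_smiles("big", "C" * 60)
        result = property_filter(rec)
        assert not result.passed and "MW" in result.failed_rules

    def test_missing_descriptor_reported_unevaluated(self):
        rec = CompoundRecord(id="x", smiles="C", descriptors={"MW": 16.0})
        result = property_filter(rec, rules={"MW": (0, 500), "TPSA": (0, 140)},
                                 optional=("TPSA",))
        assert result.passed and result.unevaluated == ("TPSA",)

    def test_library_filter_equals_per_rule_conjunction(self):
        smiles = ["c1ccccc1", "CCO", "CC(=O)Oc1ccccc1C(=O)O",
                  "C" * 60, "O=C(O)" + "C" * 30, "c1ccc2ccccc2c1"]
        records = [CompoundRecord.from_smiles(str(i), s) for i, s in enumerate(smiles)]
        from startriage.screen import DEFAULT_PROPERTY_RULES
        for rec in records:
            expected = all(
                lo <= rec.descriptors[name] <= hi
                for name, (lo, hi) in DEFAULT_PROPERTY_RULES.items()
            )
            assert property_filter(rec).passed == expected


class TestSubstructureFlags:
    def test_benzene_unflagged(self):
        assert substructure_flags("c1ccccc1") == []

    def test_nitrobenzene_flagged(self):
        assert "nitro_aromatic" in substructure_flags("O=[N+]([O-])c1ccccc1")

    def test_unparsable_structure_raises(self):
        with pytest.raises(ValueError, match="unparsable"):
            substructure_flags("not-a-smiles")

    def test_library_counts_equal_naive_scan(self):
        smiles = ["c1ccccc1", "O=[N+]([O-])c1ccccc1", "CC=O", "CCCl",
                  "O=C1C=CC(=O)C=C1", "c1ccc(O)c(O)c1", "CCO"]
        patterns = load_flag_patterns()
        for s in smiles:
            mol = Chem.MolFromSmiles(s)
            expected = [
                name for name, _cls, smarts in patterns
                if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))
            ]
            assert substructure_flags(s) == expected


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        fp = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool)) == 0.0

    def test_half_overlap(self):
        a = np.array([1, 1, 1, 1, 0, 0], bool)
        b = np.array([1, 1, 0, 0, 0, 0], bool)
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero(self):
        z = np.zeros(8, bool)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch_refused(self):
        with pytest.raises(ValueError, match="lengths"):
            tanimoto(np.ones(4, bool), np.ones(5, bool))

    @settings(max_examples=100, derandomize=True)
    @given(hst.lists(hst.booleans(), min_size=8, max_size=8),
           hst.lists(hst.booleans(), min_size=8, max_size=8))
    def test_symmetric_and_bounded(self, a, b):
        fa, fb = np.array(a), np.array(b)
        s = tanimoto(fa, fb)
        assert s == tanimoto(fb, fa)
        assert 0.0 <= s <= 1.0

    def test_matches_rdkit_on_maccs_keys(self):
        # independent cross-check of our bit arithmetic against RDKit
        mols = [Chem.MolFromSmiles(s) for s in
                ("CC(=O)Oc1ccccc1C(=O)O", "c1ccccc1", "CCO", "c1ccc2ccccc2c1")]
        rd_fps = [MACCSkeys.GenMACCSKeys(m) for m in mols]
        records = [CompoundRecord.from_smiles(str(i), Chem.MolToSmiles(m))
                   for i, m in enumerate(mols)]
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                ours = tanimoto(records[i].fingerprint, records[j].fingerprint)
                theirs = DataStructs.TanimotoSimilarity(rd_fps[i], rd_fps[j])
                assert ours == pytest.approx(theirs, abs=1e-12)


def _reference_leader_clustering(fps, threshold):
    """Naive re-derivation of leader clustering for the oracle check."""
    n = len(fps)
    sim = [[tanimoto(fps[i], fps[j]) for j in range(n)] for i in range(n)]
    counts = [sum(1 for j in range(n) if sim[i][j] >= threshold) for i in range(n)]
    labels = [-1] * n
    cluster = 0
    remaining = list(range(n))
    while remaining:
        leader = sorted(remaining, key=lambda i: (-counts[i], i))[0]
        members = [i for i in remaining if sim[leader][i] >= threshold]
        for i in members:
            labels[i] = cluster
        remaining = [i for i in remaining if i not in members]
        cluster += 1
    return labels


class TestClustering:
    def test_identical_fingerprints_one_cluster(self):
        fps = [np.array([1, 0, 1, 0], bool)] * 5
        assert cluster_library(fps).n_clusters == 1

    def test_disjoint_blocks_two_clusters(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([0, 0, 1, 1], bool)
        result = cluster_library([a, a, b, b], threshold=0.5)
        assert result.n_clusters == 2
        assert result.labels[0] == result.labels[1] != result.labels[2]

    def test_matches_exhaustive_reference_on_random_library(self, rng):
        fps = [rng.random(32) < 0.3 for _ in range(50)]
        result = cluster_library(fps, threshold=0.5)
        assert list(result.labels) == _reference_leader_clustering(fps, 0.5)

    def test_empty_library_refused(self):
        with pytest.raises(ValueError):
            cluster_library([])


class TestSarByCatalogue:
    def test_hit_itself_retrieved_at_unit_similarity(self):
        hit = np.array([1, 0, 1, 1], bool)
        out = sar_by_catalogue([hit], [np.array([0, 1, 0, 0], bool), hit], 0.7)
        assert out == [(1, 1.0)]

    def test_impossible_cutoff_returns_empty(self):
        hit = np.array([1, 0, 1, 1], bool)
        assert sar_by_catalogue([hit], [hit], similarity_cutoff=1.01) == []

    def test_matches_brute_force_scan(self, rng):
        hits = [rng.random(24) < 0.4 for _ in range(3)]
        lib = [rng.random(24) < 0.4 for _ in range(40)]
        cutoff = 0.4
        got = sar_by_catalogue(hits, lib, cutoff)
        expected = sorted(
            ((i, max(tanimoto(fp, h) for h in hits)) for i, fp in enumerate(lib)
             if max(tanimoto(fp, h) for h in hits) >= cutoff),
            key=lambda t: (-t[1], t[0]),
        )
        assert got == expected


class TestSiteGeometry:
    def test_packaged_site_has_18_residues(self):
        assert site_residue_count(load_allosteric_site()) == 18

    def test_prose_list_parsing(self):
        site = parse_residue_list("Gly107, Pro108, Thr109 and also Val367.")
        assert site.residues == ("Gly107", "Pro108", "Thr109", "Val367")

    def test_identical_sites_zero_distance(self):
        site = SiteDefinition(("Thr109",), {"Thr109": (1.0, 2.0, 3.0)})
        assert centroid_distance(site, site) == 0.0

    def test_three_four_five_triangle(self):
        a = SiteDefinition(("A1",), {"A1": (0.0, 0.0, 0.0)})
        b = SiteDefinition(("B1",), {"B1": (3.0, 4.0, 0.0)})
        assert centroid_distance(a, b) == pytest.approx(5.0)

    def test_distance_without_coordinates_refused(self):
        bare = SiteDefinition(("Thr109",))
        with pytest.raises(ValueError, match="coordinates"):
            centroid_distance(bare, bare)


class TestSolubility:
    def test_equal_areas_recover_standard_concentration(self):
        assert solubility_from_lcms(100, 100, 5, 5, 1, 10.0) == pytest.approx(10.0)

    def test_half_area_halves_solubility(self):
        assert solubility_from_lcms(50, 100, 5, 5, 1, 10.0) == pytest.approx(5.0)

    def test_dilution_factor_scales_linearly(self):
        assert solubility_from_lcms(100, 100, 5, 5, 10, 10.0) == pytest.approx(100.0)

    def test_zero_standard_area_refused(self):
        with pytest.raises(ValueError):
            solubility_from_lcms(100, 0, 5, 5, 1, 10.0)


class TestSelectLeads:
    def test_packaged_panel_yields_printed_lead_list(self, table1):
        assert select_leads(table1).leads == ("A49", "A55", "A71", "B29", "B31")

    def test_empty_panel_yields_empty_list(self, table1):
        empty = AssayPanel(table=table1.table.iloc[0:0])
        sel = select_leads(empty)
        assert sel.leads == () and len(sel.audit) == 0

    def test_failed_binding_criterion_appears_in_audit(self, table1):
        # A34 passes activity and stability but has KB 178 uM and no ITC Kd
        row = table1.table[table1.table["compound"] == "A34"]
        sel = select_leads(AssayPanel(table=row))
        assert sel.leads == ()
        assert "binding" in sel.audit.iloc[0]["failed_criteria"]

    def test_audit_consistency(self, table1):
        sel = select_leads(table1)
        for _, row in sel.audit.iterrows():
            if row["is_lead"]:
                assert row["failed_criteria"] == ""
            else:
                assert len(row["failed_criteria"]) > 0

    def test_activity_floor_excludes_near_total_inhibitor(self, table1):
        # B49 (2.6% residual activity) passes every other criterion
        no_floor = LeadCriteria(activity_floor_pct=0.0)
        assert "B49" in select_leads(table1, no_floor).leads
        assert "B49" not in select_leads(table1).leads


class TestCorrelation:
    def test_perfectly_monotone_rho_one(self):
        df = pd.DataFrame({"sol": [1, 2, 3, 4, 5, 6.0],
                           "effect": [10, 20, 30, 40, 50, 60.0]})
        rho, p = correlate_solubility_effects(df, "sol", ["effect"], 200, seed=1)["effect"]
        assert rho == pytest.approx(1.0)

    def test_anti_monotone_rho_minus_one(self):
        df = pd.DataFrame({"sol": [1, 2, 3, 4, 5, 6.0],
                           "effect": [60, 50, 40, 30, 20, 10.0]})
        rho, _ = correlate_solubility_effects(df, "sol", ["effect"], 200, seed=1)["effect"]
        assert rho == pytest.approx(-1.0)

    def test_constant_column_reported_undefined(self):
        df = pd.DataFrame({"sol": [1, 2, 3, 4, 5.0], "effect": [7.0] * 5})
        assert correlate_solubility_effects(df, "sol", ["effect"], 100, seed=1)["effect"] \
            == (None, None)

    def test_permutation_p_agrees_with_exhaustive_enumeration(self, rng):
        from itertools import permutations
        from scipy import stats as sps
        sol = np.array([1.0, 2, 3, 4, 5, 6])
        eff = np.array([2.0, 1, 4, 3, 6, 5])
        df = pd.DataFrame({"sol": sol, "effect": eff})
        rho_obs = sps.spearmanr(sol, eff).statistic
        exact = np.mean([
            abs(sps.spearmanr(sol, perm).statistic) >= abs(rho_obs) - 1e-12
            for perm in permutations(eff)
        ])
        _, p = correlate_solubility_effects(df, "sol", ["effect"], 10_000, seed=3)["effect"]
        # Monte Carlo estimate vs exact enumeration over 6! orderings
        assert p == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 10_000) + 2e-4)
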