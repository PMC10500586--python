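"""MM-GBSA bookkeeping, stars, cascade, selectivity deltas, scaffolds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ensemblevs as ev
from ensemblevs import datasets
from ensemblevs.core import ConfigurationError, InputError
from ensemblevs.screening import (
    DrugLikenessRules,
    EnergyComponents,
    ReferenceCompound,
    apply_filter_cascade,
    count_violation_stars,
    mmgbsa_total,
    round_half_away,
    scaffold_clusters,
    selectivity_deltas,
    survivors,
)


class TestMmgbsa:
    def test_reference_ligand_component_sum(self):
        # the published crystal-ligand row: VDW -57.0, ELE 18.5, SUR -51.7
        ec = EnergyComponents(vdw=-57.0, gbele=18.5, sur=-51.7)
        assert mmgbsa_total(ec) == pytest.approx(-90.2)

    def test_state_energy_difference(self):
        ec = EnergyComponents(e_complex=-100.0, e_receptor=-60.0, e_ligand=-30.0)
        assert mmgbsa_total(ec) == pytest.approx(-10.0)

    def test_all_zero_components(self):
        assert mmgbsa_total(EnergyComponents(vdw=0.0, gbele=0.0, sur=0.0)) == 0.0

    def test_consistent_dual_representation_accepted(self):
        ec = EnergyComponents(e_complex=-10.0, e_receptor=-4.0, e_ligand=-2.0,
                              vdw=-3.0, sur=-2.0, gbele=1.0)
        assert mmgbsa_total(ec) == pytest.approx(-4.0)

    def test_inconsistent_representations_rejected(self):
        ec = EnergyComponents(e_complex=-10.0, e_receptor=-4.0, e_ligand=-2.0,
                              vdw=-3.0, sur=-2.0, gbele=2.0)
        with pytest.raises(InputError):
            mmgbsa_total(ec)

    def test_neither_representation_rejected(self):
        with pytest.raises(InputError):
            mmgbsa_total(EnergyComponents())

    def test_generated_tables_agree_between_routes(self):
        t = ev.generate_screening_table(ev.ScreeningTableSpec(n_compounds=20, seed=4))
        for _, row in t.iterrows():
            ec = EnergyComponents(vdw=row.vdw, sur=row.sur, gbele=row.gbele,
                                  conf_receptor=row.conf_receptor,
                                  conf_ligand=row.conf_ligand)
            assert mmgbsa_total(ec) == pytest.approx(row.mmgbsa_total, abs=1e-9)


class TestStars:
    def test_in_range_compound_has_zero_stars(self):
        assert count_violation_stars(dict(mw=400, hbd=2, hba=5, logp=3)) == 0

    def test_two_violations_two_stars(self):
        assert count_violation_stars(dict(mw=600, hbd=2, hba=5, logp=6)) == 2

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_per_property_range_check(self, seed):
        rng = np.random.default_rng(seed)
        rec = dict(mw=rng.uniform(100, 900), hbd=int(rng.integers(0, 12)),
                   hba=int(rng.integers(0, 20)), logp=rng.uniform(-2, 9))
        rules = DrugLikenessRules()
        expected = sum(
            not (lo <= rec[k] <= hi) for k, (lo, hi) in rules.ranges.items()
        )
        assert count_violation_stars(rec, rules) == expected


class TestCascade:
    def test_published_compound_survives_all_gates(self):
        t = datasets.load_top8_screening()
        row = t[t.compound_id == "ZINC000020559278"]
        out = apply_filter_cascade(row, datasets.reference_compound())
        assert bool(out["survives"].iloc[0])

    def test_weaker_docking_than_reference_fails_first_gate(self):
        t = datasets.load_top8_screening().head(2).copy()
        t.loc[t.index[1], "docking_score"] = -8.0  # worse than -8.6
        out = apply_filter_cascade(t, datasets.reference_compound())
        assert out["first_failure"].iloc[1] == "docking"
        assert not out["survives"].iloc[1]

    def test_reference_passes_its_own_cutoffs(self):
        t = datasets.load_top8_screening()
        ref_row = t[t.compound_id == datasets.REFERENCE_ID]
        out = apply_filter_cascade(ref_row, datasets.reference_compound())
        assert bool(out["survives"].iloc[0])  # equality passes

    def test_survivor_count_matches_per_gate_evaluation(self):
        spec = ev.ScreeningTableSpec(n_compounds=200, seed=11)
        t = ev.generate_screening_table(spec)
        ref = ReferenceCompound("ref", spec.docking_cutoff, spec.mmgbsa_cutoff)
        out = apply_filter_cascade(t, ref)
        rules = DrugLikenessRules()
        expected = 0
        for _, r in t.iterrows():
            ok = (
                r.docking_score <= spec.docking_cutoff
                and count_violation_stars(r, rules) <= rules.max_stars
                and r.mmgbsa_total <= spec.mmgbsa_cutoff
                and r.gi_absorption == "high"
                and r.bbb_permeant == "yes"
                and r.pains_alerts == 0 and r.brenk_alerts == 0
            )
            expected += ok
        assert int(out["survives"].sum()) == expected

    def test_gate_order_changes_labels_not_survivors(self):
        spec = ev.ScreeningTableSpec(n_compounds=100, seed=13)
        t = ev.generate_screening_table(spec)
        ref = ReferenceCompound("ref", spec.docking_cutoff, spec.mmgbsa_cutoff)
        a = apply_filter_cascade(t, ref)
        b = apply_filter_cascade(
            t, ref, gate_order=("alerts", "bbb", "gi", "mmgbsa", "stars", "docking")
        )
        assert a["survives"].equals(b["survives"])
        assert set(survivors(a)["compound_id"]) == set(survivors(b)["compound_id"])

    def test_missing_reference_rejected(self):
        t = datasets.load_top8_screening()
        with pytest.raises(ConfigurationError):
            apply_filter_cascade(t, ReferenceCompound("r", float("nan"), -90.2))


class TestSelectivity:
    def test_crystal_ligand_deltas_relative_to_native_receptor(self):
        sel = selectivity_deltas(datasets.load_selectivity_scores())
        dpi = sel.per_compound.set_index("compound_id").loc["DPI-287"]
        assert dpi["dor_cc_delta"] == pytest.approx(0.0)
        assert dpi["kor_cc_delta"] == pytest.approx(3.2)
        assert dpi["mor_cc_delta"] == pytest.approx(4.7)
        mp = sel.per_compound.set_index("compound_id").loc["MP1104"]
        assert mp["kor_cc_delta"] == pytest.approx(0.0)
        assert mp["dor_cc_delta"] == pytest.approx(1.9)

    def test_identical_scores_give_zero_deltas(self):
        t = pd.DataFrame(
            [dict(compound_id="X", original_score=-7.0,
                  dor_cc=-7.0, kor_cc=-7.0, mor_cc=-7.0)]
        )
        sel = selectivity_deltas(t)
        row = sel.per_compound.iloc[0]
        assert all(row[f"{c}_delta"] == 0.0 for c in ("dor_cc", "kor_cc", "mor_cc"))

    def test_published_column_average(self):
        sel = selectivity_deltas(datasets.load_selectivity_scores())
        assert sel.score_averages["dor_cc"] == pytest.approx(-7.8)

    def test_translation_behaviour(self):
        base = dict(compound_id="X", original_score=-9.0,
                    dor_cc=-8.0, kor_cc=-7.0, mor_cc=-6.0)
        a = selectivity_deltas(pd.DataFrame([base]))
        shifted_all = {**base, "original_score": -8.0, "dor_cc": -7.0,
                       "kor_cc": -6.0, "mor_cc": -5.0}
        b = selectivity_deltas(pd.DataFrame([shifted_all]))
        pd.testing.assert_series_equal(
            a.per_compound.filter(like="_delta").iloc[0],
            b.per_compound.filter(like="_delta").iloc[0],
        )
        shifted_scores_only = {**base, "dor_cc": -7.0, "kor_cc": -6.0, "mor_cc": -5.0}
        c = selectivity_deltas(pd.DataFrame([shifted_scores_only]))
        assert (c.per_compound["dor_cc_delta"].iloc[0]
                == a.per_compound["dor_cc_delta"].iloc[0] + 1.0)

    def test_missing_score_skipped_with_warning(self):
        t = pd.DataFrame(
            [dict(compound_id="X", original_score=-7.0,
                  dor_cc=-7.0, kor_cc=None, mor_cc=-7.0),
             dict(compound_id="Y", original_score=-8.0,
                  dor_cc=-8.0, kor_cc=-8.0, mor_cc=-8.0)]
        )
        with pytest.warns(UserWarning, match="missing score"):
            sel = selectivity_deltas(t)
        assert sel.per_compound["compound_id"].tolist() == ["Y"]

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(7.75) == 7.8
        assert round_half_away(-7.75) == -7.8
        assert round_half_away(1.275) == 1.3
        assert round_half_away(-9.55) == -9.6


class TestScaffolds:
    SMILES = ["CCO", "CCCO", "CCCCO", "c1ccccc1", "c1ccccc1C", "C1CC1N"]

    def test_identical_structures_cluster_together(self):
        labels = scaffold_clusters(["CCO", "CCO", "CCO"])
        assert len(set(labels)) == 1

    def test_dissimilar_structures_split(self):
        labels = scaffold_clusters(["CCCCCCCC", "c1ccc2ccccc2c1"], similarity_cutoff=0.5)
        assert labels[0] != labels[1]

    def test_unparseable_structure_flagged(self):
        with pytest.warns(UserWarning, match="unparseable"):
            labels = scaffold_clusters(["CCO", "not_a_smiles", "CCO"])
        assert labels[1] == -1 and labels[0] == labels[2]

    def test_matches_similarity_matrix_linkage_oracle(self):
        import scipy.cluster.hierarchy as sch
        from rdkit import Chem, DataStructs
        from scipy.spatial.distance import squareform

        cutoff = 0.5
        labels = scaffold_clusters(self.SMILES, similarity_cutoff=cutoff)
        mols = [Chem.MolFromSmiles(s) for s in self.SMILES]
        fps = [Chem.RDKFingerprint(m, fpSize=2048) for m in mols]
        n = len(fps)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = 1 - DataStructs.TanimotoSimilarity(
                    fps[i], fps[j])
        raw = sch.fcluster(
            sch.linkage(squareform(dist), method="average"),
            t=1 - cutoff, criterion="distance",
        )
        # same partition up to label names
        for i in range(n):
            for j in range(n):
                assert (labels[i] == labels[j]) == (raw[i] == raw[j])
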