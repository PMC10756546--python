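"""Grouping, PCA, seasonal ratios, ternary FA compositions and indices."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_annotated
from krillipid.chem_core import HeadGroupClass, SumComposition
from krillipid.composition_stats import (
    compositions_to_matrix,
    derive_grouping,
    fa_saturation_ternary,
    group_matrix,
    pca_scores,
    pufa_indices,
    reference_overlap,
    seasonal_ratios,
)
from krillipid.quantification import SampleComposition, percentage_distribution

H = HeadGroupClass


def comp(sample_id, entries, organ="stomach", month="Jan"):
    return percentage_distribution(entries, sample_id, organ, month)


NINE_PCS = [f"PC({c}:{d})" for c, d in
            [(30, 0), (32, 1), (34, 2), (36, 3), (38, 4), (40, 6),
             (42, 8), (44, 10), (46, 12)]]


class TestGrouping:
    def test_tertiles_give_three_per_mass_bin(self):
        comps = [comp("s1", {name: 1.0 for name in NINE_PCS})]
        scheme = derive_grouping(comps)
        groups = [scheme.group_of(SumComposition.parse(n)) for n in NINE_PCS]
        mw = [g.split("-")[1] for g in groups]
        assert mw.count("LMW") == mw.count("MMW") == mw.count("HMW") == 3

    def test_explicit_breakpoints_override(self):
        comps = [comp("s1", {name: 1.0 for name in NINE_PCS})]
        scheme = derive_grouping(comps, explicit_mw={H.PC: (700.0, 701.0)},
                                 explicit_du={H.PC: (0.5, 1.5)})
        assert scheme.mw_breaks[H.PC] == (700.0, 701.0)
        # every species above 701 Da -> HMW
        assert all(scheme.group_of(SumComposition.parse(n)).split("-")[1]
                   == "HMW" for n in NINE_PCS[1:])

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        comps = [comp(f"s{i}", {n: float(rng.uniform(0.5, 2))
                                for n in NINE_PCS}) for i in range(6)]
        a = derive_grouping(comps)
        b = derive_grouping(list(reversed(comps)))
        assert a.mw_breaks == b.mw_breaks and a.du_breaks == b.du_breaks

    def test_sparse_class_collapses_to_single_group(self):
        comps = [comp("s1", {"PS(36:2)": 50.0, "PS(38:2)": 50.0})]
        scheme = derive_grouping(comps)
        assert scheme.mw_breaks[H.PS] == ()
        assert scheme.group_of(SumComposition.parse("PS(36:2)")).startswith("PS-")


class TestGroupMatrix:
    def test_one_species_per_group_equals_species_matrix(self):
        entries = {"PC(30:0)": 20.0, "PE(32:1)": 30.0, "PS(36:2)": 50.0}
        comps = [comp("s1", entries)]
        scheme = derive_grouping(comps)
        matrix = group_matrix(comps, scheme)
        assert sorted(matrix.loc["s1"]) == sorted(entries.values())

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(4)
        comps = [comp(f"s{i}", {n: float(rng.uniform(0.1, 3))
                                for n in NINE_PCS}) for i in range(5)]
        matrix = group_matrix(comps, derive_grouping(comps))
        assert np.allclose(matrix.sum(axis=1), 100.0, atol=1e-9)

    def test_grouping_preserves_planted_separation(self):
        """PCA on grouped data separates the same samples as on ungrouped
        data when a strong abundance contrast is planted."""
        rng = np.random.default_rng(8)
        comps = []
        for i in range(12):
            boosted = i < 6  # first half: high-mass PCs enriched
            entries = {}
            for j, name in enumerate(NINE_PCS):
                base = 3.0 if (j >= 6) == boosted else 1.0
                entries[name] = base * float(rng.lognormal(0, 0.1))
            comps.append(comp(f"s{i}", entries))
        ungrouped, _, _ = pca_scores(compositions_to_matrix(comps))
        grouped, _, _ = pca_scores(group_matrix(comps, derive_grouping(comps)))
        a = ungrouped["PC1"].to_numpy()
        b = grouped["PC1"].to_numpy()
        corr = np.corrcoef(a, b)[0, 1]
        assert abs(corr) > 0.9  # sign-aligned up to PCA sign ambiguity


class TestPca:
    def test_two_cluster_separation_on_pc1(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(10):
            center = 10.0 if i < 5 else 30.0
            a = center + rng.normal(0, 0.5)
            rows.append([a, 50 - a, 50.0])
        matrix = pd.DataFrame(rows, index=[f"s{i}" for i in range(10)],
                              columns=["g1", "g2", "g3"])
        scores, _, _ = pca_scores(matrix)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:5].max() < pc1[5:].min()) or (pc1[:5].min() > pc1[5:].max())

    def test_too_few_samples_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]], index=["s1"], columns=["a", "b"])
        with pytest.raises(ValueError):
            pca_scores(matrix)

    def test_constant_matrix_rejected(self):
        matrix = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError, match="constant"):
            pca_scores(matrix)

    def test_score_columns_orthogonal(self):
        rng = np.random.default_rng(6)
        matrix = pd.DataFrame(rng.uniform(0, 1, size=(8, 5)))
        scores, _, _ = pca_scores(matrix, n_components=2)
        dot = float(scores["PC1"] @ scores["PC2"])
        assert abs(dot) < 1e-8


class TestSeasonalRatios:
    def test_identical_groups_give_unit_ratios(self):
        entries = {n: 100.0 / len(NINE_PCS) for n in NINE_PCS}
        comps = [comp("a1", entries, month="May"),
                 comp("b1", entries, month="Jan")]
        ratios = seasonal_ratios(comps, ["May"], ["Jan"], H.PC)
        assert all(r.ratio == pytest.approx(1.0) for r in ratios)

    def test_planted_summer_enrichment(self):
        """A species twice as abundant in summer shows ratio ~0.5 with the
        autumn months as group A."""
        rng = np.random.default_rng(12)
        comps = []
        for i in range(16):
            month = "May" if i < 8 else "Jan"
            boost = 1.0 if month == "May" else 2.0
            entries = {"PC(38:6)": 10.0 * boost * float(rng.lognormal(0, 0.05)),
                       "PC(34:1)": 50.0 * float(rng.lognormal(0, 0.05))}
            comps.append(comp(f"s{i}", entries, month=month))
        ratios = {r.species: r for r in
                  seasonal_ratios(comps, ["May"], ["Jan"], H.PC)}
        assert ratios["PC(38:6)"].ratio == pytest.approx(0.5, rel=0.15)

    def test_one_sided_species_flagged(self):
        comps = [comp("a1", {"PC(34:1)": 100.0}, month="May"),
                 comp("b1", {"PC(34:1)": 50.0, "PC(38:6)": 50.0}, month="Jan")]
        ratios = {r.species: r for r in
                  seasonal_ratios(comps, ["May"], ["Jan"], H.PC)}
        assert ratios["PC(38:6)"].one_sided == "b_only"
        assert np.isnan(ratios["PC(38:6)"].ratio)

    def test_reciprocal_when_groups_swapped(self):
        rng = np.random.default_rng(13)
        comps = []
        for i in range(10):
            month = "May" if i % 2 else "Jan"
            entries = {n: float(rng.uniform(0.5, 3)) for n in NINE_PCS}
            comps.append(comp(f"s{i}", entries, month=month))
        fwd = {r.species: r.ratio for r in
               seasonal_ratios(comps, ["May"], ["Jan"], H.PC)}
        rev = {r.species: r.ratio for r in
               seasonal_ratios(comps, ["Jan"], ["May"], H.PC)}
        for species in fwd:
            assert fwd[species] == pytest.approx(1.0 / rev[species])


class TestTernary:
    def test_single_sfa_pufa_species(self):
        annotations = {"s1": [make_annotated("PC(38:6)",
                                             [("16:0", "22:6", 1e3, 2e3)])]}
        comps = [comp("s1", {"PC(38:6)": 100.0})]
        table, excluded = fa_saturation_ternary(comps, annotations, H.PC)
        assert excluded == 0
        assert table.loc["s1"].to_list() == pytest.approx([50.0, 0.0, 50.0])

    def test_pure_mufa_species(self):
        annotations = {"s1": [make_annotated("PC(36:2)",
                                             [("18:1", "18:1", 1e3, 1e3)])]}
        comps = [comp("s1", {"PC(36:2)": 100.0})]
        table, _ = fa_saturation_ternary(comps, annotations, H.PC)
        assert table.loc["s1"].to_list() == pytest.approx([0.0, 100.0, 0.0])

    def test_multi_pair_intensity_apportionment(self):
        # two pairs with more-abundant-acyl intensities 3e3 and 1e3 split the
        # species 75/25
        ann = make_annotated("PC(38:6)", [("16:0", "22:6", 1e3, 3e3),
                                          ("18:3", "20:3", 1e3, 1e3)])
        comps = [comp("s1", {"PC(38:6)": 100.0})]
        table, _ = fa_saturation_ternary(comps, {"s1": [ann]}, H.PC)
        # pair1 (w=.75): 16:0 SFA + 22:6 PUFA; pair2 (w=.25): both PUFA
        assert table.loc["s1", "SFA"] == pytest.approx(37.5)
        assert table.loc["s1", "PUFA"] == pytest.approx(62.5)

    def test_rows_sum_to_100(self):
        annotations = {"s1": [
            make_annotated("PC(38:6)", [("16:0", "22:6", 1e3, 2e3)]),
            make_annotated("PC(34:1)", [("16:0", "18:1", 2e3, 1e3)])]}
        comps = [comp("s1", {"PC(38:6)": 30.0, "PC(34:1)": 70.0})]
        table, _ = fa_saturation_ternary(comps, annotations, H.PC)
        assert table.sum(axis=1).to_list() == pytest.approx([100.0], abs=1e-9)


class TestPufaIndices:
    def test_single_dha_species(self):
        annotations = {"s1": [make_annotated("PC(38:6)",
                                             [("16:0", "22:6", 1e3, 2e3)])]}
        comps = [comp("s1", {"PC(38:6)": 100.0})]
        table = pufa_indices(comps, annotations, H.PC)
        row = table.loc["s1"]
        assert row["mean_unsaturation"] == pytest.approx(3.0)
        assert row["epa_pct"] == pytest.approx(0.0)
        assert row["dha_pct"] == pytest.approx(100.0)

    def test_dha_free_species_dilutes_dha_share(self):
        annotations = {"s1": [
            make_annotated("PC(38:6)", [("16:0", "22:6", 1e3, 2e3)]),
            make_annotated("PC(36:2)", [("18:1", "18:1", 1e3, 1e3)])]}
        comps = [comp("s1", {"PC(38:6)": 50.0, "PC(36:2)": 50.0})]
        row = pufa_indices(comps, annotations, H.PC).loc["s1"]
        assert row["dha_pct"] == pytest.approx(50.0)
        assert row["mean_unsaturation"] == pytest.approx((3.0 + 1.0) / 2)

    def test_empty_class_rejected(self):
        comps = [comp("s1", {"PC(38:6)": 100.0})]
        with pytest.raises(ValueError):
            pufa_indices(comps, {}, H.PE)


class TestReferenceOverlap:
    def test_identity_reference_full_overlap(self):
        own = pd.DataFrame({"species": ["PC(38:6)", "PE(32:0)"],
                            "pct": [60.0, 40.0]})
        table = reference_overlap(own, own.copy())
        assert (table["n_overlap"] == table["n_own"]).all()
        assert table.loc["PC", "pct_overlap_own"] == pytest.approx(60.0)

    def test_disjoint_reference(self):
        own = pd.DataFrame({"species": ["PC(38:6)"], "pct": [100.0]})
        ref = pd.DataFrame({"species": ["PC(40:6)"], "pct": [100.0]})
        table = reference_overlap(own, ref)
        assert table.loc["PC", "n_overlap"] == 0
        assert table.loc["PC", "pct_overlap_own"] == 0.0

    def test_half_overlap_counts_match_hand_enumeration(self):
        own = pd.DataFrame({
            "species": ["PC(38:6)", "PC(34:1)", "PE(32:0)", "PE(36:2)"],
            "pct": [40.0, 20.0, 30.0, 10.0]})
        ref = pd.DataFrame({
            "species": ["PC(38:6)", "PC(40:8)", "PE(36:2)"],
            "pct": [50.0, 25.0, 25.0]})
        table = reference_overlap(own, ref)
        assert table.loc["PC"].to_dict() == pytest.approx(
            {"n_own": 2, "n_reference": 2, "n_overlap": 1,
             "pct_overlap_own": 40.0, "pct_overlap_reference": 50.0})
        assert table.loc["PE", "n_overlap"] == 1
        assert table.loc["PE", "pct_overlap_own"] == pytest.approx(10.0)

    def test_empty_reference_rejected(self):
        own = pd.DataFrame({"species": ["PC(38:6)"], "pct": [100.0]})
        with pytest.raises(ValueError, match="empty reference"):
            reference_overlap(own, pd.DataFrame(columns=["species", "pct"]))
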