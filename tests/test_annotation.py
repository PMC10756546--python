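"""Identification chain: class rules, sum compositions, acyl pairs,
cross-polarity confirmation and whole-run annotation."""

import itertools

import numpy as np
import pytest

from krillipid.annotation import (
    annotate_run,
    confirm_species,
    enumerate_acyl_pairs,
    identify_class,
    infer_sum_composition,
)
from krillipid.chem_core import (
    FattyAcyl,
    HeadGroupClass,
    SumComposition,
    acyl_anion_mz,
    precursor_mz,
)
from krillipid.config import Config
from krillipid.spectra_model import Feature, Ms2Spectrum, Peak
from krillipid.synthetic_data import NoiseModel, generate_lipidome, render_run

H = HeadGroupClass


def feature(mz, rt=5.0, polarity="positive", area=1e5, peaks=None):
    ms2 = Ms2Spectrum(mz, [Peak(m, i) for m, i in peaks]) if peaks else None
    return Feature("f", polarity, rt, mz, area, ms2)


class TestIdentifyClass:
    def test_pc_from_phosphocholine_fragment(self):
        f = feature(806.5694, peaks=[(184.0733, 1e4)])
        assert identify_class(f) == [H.PC]

    def test_pe_from_head_group_neutral_loss(self):
        mz, _ = precursor_mz(SumComposition(H.PE, 32, 0), "positive")
        f = feature(mz, peaks=[(mz - 141.0191, 1e4)])
        assert identify_class(f) == [H.PE]

    def test_no_diagnostic_signal(self):
        f = feature(806.5694, peaks=[(400.0, 1e4)])
        assert identify_class(f) == []

    def test_no_ms2_unidentifiable(self):
        assert identify_class(feature(806.5694)) == []


class TestInferSumComposition:
    def test_pc_38_6_unique_at_5ppm(self):
        hits = infer_sum_composition(806.5694, H.PC, "positive", 5.0)
        assert [h.name for h in hits] == ["PC(38:6)"]

    def test_matches_bruteforce_grid(self):
        """The vectorised grid scan equals a naive double loop."""
        for mz, cls in [(806.5694, H.PC), (690.5079 + 2 * 1.00728, H.PE),
                        (750.123, H.PG)]:
            naive = set()
            for c in range(20, 71):
                for d in range(0, 17):
                    try:
                        theo, _ = precursor_mz(SumComposition(cls, c, d),
                                               "positive")
                    except ValueError:
                        continue
                    if abs(1e6 * (mz - theo) / theo) <= 5.0:
                        naive.add((c, d))
            hits = infer_sum_composition(mz, cls, "positive", 5.0)
            assert {(h.c_total, h.dbe_total) for h in hits} == naive

    def test_huge_tolerance_yields_many_hits(self):
        hits = infer_sum_composition(806.5694, H.PC, "positive", 5000.0)
        assert len(hits) > 1
        assert hits[0].name == "PC(38:6)"  # sorted by |ppm|

    def test_below_grid_is_empty(self):
        assert infer_sum_composition(184.0733, H.PC, "positive", 5.0) == []


def spectrum_with_anions(precursor, acyls_with_intensity):
    peaks = [Peak(acyl_anion_mz(FattyAcyl.parse(fa)), i)
             for fa, i in acyls_with_intensity]
    return Ms2Spectrum(precursor, peaks)


class TestEnumerateAcylPairs:
    def test_vlcpufa_pair_22_6_and_36_8(self):
        sc = SumComposition(H.PC, 58, 14)
        ms2 = spectrum_with_anions(903.0, [("22:6", 2e4), ("36:8", 1e4)])
        pairs = enumerate_acyl_pairs(sc, ms2)
        assert len(pairs) == 1
        assert {pairs[0].fa_a.name, pairs[0].fa_b.name} == {"22:6", "36:8"}

    def test_sn2_is_more_intense_acyl(self):
        sc = SumComposition(H.PC, 38, 6)
        ms2 = spectrum_with_anions(850.56, [("16:0", 1e4), ("22:6", 3e4)])
        pairs = enumerate_acyl_pairs(sc, ms2)
        assert len(pairs) == 1
        assert pairs[0].sn2_acyl.name == "22:6"
        assert pairs[0].sn1_acyl.name == "16:0"

    def test_multiple_combinations_resolved(self):
        sc = SumComposition(H.PC, 36, 0)
        ms2 = spectrum_with_anions(800.0, [("16:0", 1e4), ("18:0", 2e4),
                                           ("20:0", 5e3)])
        pairs = enumerate_acyl_pairs(sc, ms2)
        names = {frozenset((p.fa_a.name, p.fa_b.name)) for p in pairs}
        assert names == {frozenset({"16:0", "20:0"}), frozenset({"18:0"})}

    def test_swapping_intensities_swaps_sn2_not_pairs(self):
        sc = SumComposition(H.PC, 38, 6)
        fwd = enumerate_acyl_pairs(sc, spectrum_with_anions(
            850.0, [("16:0", 1e4), ("22:6", 3e4)]))
        rev = enumerate_acyl_pairs(sc, spectrum_with_anions(
            850.0, [("16:0", 3e4), ("22:6", 1e4)]))
        assert {(p.fa_a, p.fa_b) for p in fwd} == {(p.fa_a, p.fa_b)
                                                   for p in rev}
        assert fwd[0].sn2_acyl.name == "22:6"
        assert rev[0].sn2_acyl.name == "16:0"

    def test_equals_naive_double_loop(self):
        """Random sum compositions and spectra: the constrained enumeration
        equals brute force over the full acyl-space cross product."""
        rng = np.random.default_rng(7)
        space = [FattyAcyl(c, d) for c in range(12, 41) for d in range(0, 11)
                 if d <= c - 2]
        for _ in range(50):
            cls = list(H)[rng.integers(len(H))]
            observed = [space[i] for i in
                        rng.choice(len(space), size=6, replace=False)]
            ms2 = Ms2Spectrum(900.0, [
                Peak(acyl_anion_mz(fa), float(rng.uniform(1e3, 1e5)))
                for fa in observed])
            a, b = observed[0], observed[1]
            sc = SumComposition(cls, a.n_carbon + b.n_carbon,
                                a.n_dbe + b.n_dbe)
            expected = set()
            for fa_a, fa_b in itertools.product(space, space):
                if (fa_a.n_carbon + fa_b.n_carbon == sc.c_total
                        and fa_a.n_dbe + fa_b.n_dbe == sc.dbe_total
                        and ms2.match(acyl_anion_mz(fa_a), 10.0)
                        and ms2.match(acyl_anion_mz(fa_b), 10.0)):
                    expected.add(frozenset((fa_a, fa_b)))
            got = {frozenset((p.fa_a, p.fa_b))
                   for p in enumerate_acyl_pairs(sc, ms2)}
            assert got == expected


def rendered_pair(sc: SumComposition, fa_sn1: str, fa_sn2: str,
                  rt: float = 5.0):
    """Noiseless synthetic evidence for one species in both polarities."""
    mz_pos, _ = precursor_mz(sc, "positive")
    mz_neg, _ = precursor_mz(sc, "negative")
    if sc.cls is H.PC:
        pos_peaks = [(184.07332, 1e4)]
        neg_extra = [(mz_neg - 60.02113, 5e3)]
    else:
        raise NotImplementedError
    neg_peaks = neg_extra + [
        (acyl_anion_mz(FattyAcyl.parse(fa_sn2)), 2e4),
        (acyl_anion_mz(FattyAcyl.parse(fa_sn1)), 1e4),
    ]
    pos = Feature("pos", "positive", rt, mz_pos, 1e5,
                  Ms2Spectrum(mz_pos, [Peak(m, i) for m, i in pos_peaks]))
    neg = Feature("neg", "negative", rt, mz_neg, 8e4,
                  Ms2Spectrum(mz_neg, [Peak(m, i) for m, i in neg_peaks]))
    return pos, neg


class TestConfirmSpecies:
    def test_full_evidence_confirms(self, config):
        pos, neg = rendered_pair(SumComposition(H.PC, 38, 6), "16:0", "22:6")
        ann, rej = confirm_species(pos, neg, config)
        assert rej is None
        assert ann.species == "PC(38:6)"
        assert len(ann.pairs) == 1
        assert ann.pairs[0].sn2_acyl.name == "22:6"
        assert "PC-" in ann.evidence.matched_rules

    def test_missing_acyl_signals_rejected(self, config):
        pos, neg = rendered_pair(SumComposition(H.PC, 38, 6), "16:0", "22:6")
        neg.ms2.peaks = [p for p in neg.ms2.peaks if p.mz > 700]  # keep NL only
        ann, rej = confirm_species(pos, neg, config)
        assert ann is None
        assert rej.reason == "no matching fatty acid signals"

    def test_wrong_negative_precursor_rejected(self, config):
        pos, neg = rendered_pair(SumComposition(H.PC, 38, 6), "16:0", "22:6")
        neg.mz += 0.5
        ann, rej = confirm_species(pos, neg, config)
        assert ann is None
        assert "both polarities" in rej.reason

    def test_missing_negative_class_rule_rejected(self, config):
        pos, neg = rendered_pair(SumComposition(H.PC, 38, 6), "16:0", "22:6")
        neg.ms2.peaks = [p for p in neg.ms2.peaks if p.mz < 700]  # drop NL
        ann, rej = confirm_species(pos, neg, config)
        assert ann is None
        assert rej.stage == "negative_rule"


class TestAnnotateRun:
    def test_recovers_all_rendered_species(self, config):
        lipidome = generate_lipidome(10, seed=3)
        sample = render_run(lipidome, "Jan", "stomach",
                            NoiseModel.noiseless(), seed=3, sample_id="s")
        annotations, _ = annotate_run(sample, config)
        assert ({a.species for a in annotations}
                == {sp.species for sp in lipidome.species})

    def test_recovered_pairs_and_sn2_match_truth(self, config):
        lipidome = generate_lipidome(10, seed=3)
        sample = render_run(lipidome, "Jan", "stomach",
                            NoiseModel.noiseless(), seed=3, sample_id="s")
        annotations, _ = annotate_run(sample, config)
        truth = {sp.species: sp for sp in lipidome.species}
        for ann in annotations:
            sp = truth[ann.species]
            assert {frozenset((p.fa_a, p.fa_b)) for p in ann.pairs} >= {
                frozenset((sp.fa_sn1, sp.fa_sn2))}
            assert ann.pairs[0].sn2_acyl == sp.fa_sn2

    def test_mass_decoys_rejected_at_default_tolerance(self, config):
        """Precursors displaced by 20 ppm fail the 5 ppm MS1 gate."""
        pos, neg = rendered_pair(SumComposition(H.PC, 38, 6), "16:0", "22:6")
        pos.mz *= 1 + 20e-6
        neg.mz *= 1 + 20e-6
        ann, rej = confirm_species(pos, neg, config)
        assert ann is None

    def test_blank_run_annotates_nothing(self, config):
        lipidome = generate_lipidome(10, seed=3)
        blank = render_run(lipidome, "Jan", "stomach", NoiseModel(),
                           seed=3, sample_id="b", is_blank=True)
        annotations, _ = annotate_run(blank, config)
        assert annotations == []

    def test_shrinking_tolerance_never_adds_annotations(self):
        lipidome = generate_lipidome(25, seed=9)
        sample = render_run(lipidome, "Jan", "stomach", NoiseModel(),
                            seed=9, sample_id="s")
        species_at = {}
        for ms1 in (1.0, 3.0, 5.0):
            cfg = Config(ms1_ppm=ms1, ms2_ppm=2 * ms1)
            annotations, _ = annotate_run(sample, cfg)
            species_at[ms1] = {a.species for a in annotations}
        assert species_at[1.0] <= species_at[3.0] <= species_at[5.0]
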