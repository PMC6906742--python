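"""Peak alignment, intensity filter, isotopologue collapse, temporal
classification, RT correction, and neighborhood annotation."""

import numpy as np
import pandas as pd
import pytest

from ceconet.features import (
    FeatureTable,
    PeakList,
    TemporalClass,
    align_peaks,
    annotate_by_mass_and_neighborhood,
    classify_temporal,
    collapse_isotopologues,
    correct_retention_time,
    filter_intensity,
)
from ceconet.knowledge import load_knowledge_base


def peaklist(sample, rows, mode="positive"):
    return PeakList(
        sample_id=sample,
        mode=mode,
        peaks=pd.DataFrame(rows, columns=["mz", "rt_min", "intensity_cps"]),
    )


def make_ft(features: dict[str, tuple[float, float]], intensities: dict[str, dict]):
    """features: fid -> (mz, rt); intensities: fid -> {sample: value}."""
    feats = pd.DataFrame(
        {
            "mz": {f: v[0] for f, v in features.items()},
            "rt_min": {f: v[1] for f, v in features.items()},
            "mode": "positive",
            "monoisotopic": False,
        }
    )
    samples = sorted({s for d in intensities.values() for s in d})
    intens = pd.DataFrame(np.nan, index=list(features), columns=samples)
    for f, d in intensities.items():
        for s, v in d.items():
            intens.at[f, s] = v
    return FeatureTable(features=feats, intensities=intens)


class TestAlignPeaks:
    def test_peaks_within_tolerance_merge(self):
        # 7.5 ppm and 0.2 min apart -> one feature
        ft = align_peaks(
            [
                peaklist("s1", [(200.0000, 5.0, 500.0)]),
                peaklist("s2", [(200.0015, 5.2, 400.0)]),
            ]
        )
        assert len(ft.feature_ids) == 1
        fid = ft.feature_ids[0]
        assert ft.intensities.at[fid, "s1"] == 500.0
        assert ft.intensities.at[fid, "s2"] == 400.0

    def test_peaks_beyond_ppm_tolerance_stay_separate(self):
        # 15 ppm apart -> two features
        ft = align_peaks(
            [
                peaklist("s1", [(200.0000, 5.0, 500.0)]),
                peaklist("s2", [(200.0030, 5.0, 400.0)]),
            ]
        )
        assert len(ft.feature_ids) == 2

    def test_single_peak_is_its_own_consensus(self):
        ft = align_peaks([peaklist("s1", [(300.5, 2.0, 123.0)])])
        assert len(ft.feature_ids) == 1
        row = ft.features.iloc[0]
        assert row["mz"] == pytest.approx(300.5)
        assert row["rt_min"] == pytest.approx(2.0)

    def test_mixed_modes_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            align_peaks(
                [
                    peaklist("s1", [(200.0, 5.0, 10.0)], mode="positive"),
                    peaklist("s2", [(200.0, 5.0, 10.0)], mode="negative"),
                ]
            )

    def test_most_intense_peak_per_sample_wins(self):
        ft = align_peaks(
            [peaklist("s1", [(200.0000, 5.0, 900.0), (200.0004, 5.01, 100.0)])]
        )
        assert len(ft.feature_ids) == 1
        assert ft.intensities.iloc[0]["s1"] == 900.0

    def test_consensus_is_intensity_weighted_mean(self):
        ft = align_peaks(
            [
                peaklist("s1", [(200.0000, 5.0, 300.0)]),
                peaklist("s2", [(200.0010, 5.2, 100.0)]),
            ]
        )
        assert ft.features.iloc[0]["mz"] == pytest.approx(
            (200.0000 * 300 + 200.0010 * 100) / 400
        )
        assert ft.features.iloc[0]["rt_min"] == pytest.approx((5.0 * 300 + 5.2 * 100) / 400)

    def test_order_independent_and_count_bounded(self):
        rng = np.random.default_rng(3)
        rows = [
            (float(rng.uniform(100, 600)), float(rng.uniform(0, 14)), float(rng.uniform(50, 5000)))
            for _ in range(60)
        ]
        pls = [peaklist("s1", rows[:30]), peaklist("s2", rows[30:])]
        ft_a = align_peaks(pls)
        ft_b = align_peaks(pls[::-1])
        assert len(ft_a.feature_ids) <= 60
        pd.testing.assert_frame_equal(ft_a.features, ft_b.features)


class TestFilterIntensity:
    def test_threshold_boundary(self):
        ft = make_ft(
            {"lo": (200.0, 1.0), "at": (300.0, 2.0)},
            {"lo": {"s1": 99.0}, "at": {"s1": 100.0}},
        )
        out = filter_intensity(ft, 100.0)
        assert out.feature_ids == ["at"]

    def test_all_above_threshold_is_identity(self):
        ft = make_ft(
            {"a": (200.0, 1.0), "b": (300.0, 2.0)},
            {"a": {"s1": 500.0}, "b": {"s1": 800.0}},
        )
        out = filter_intensity(ft, 100.0)
        assert out.feature_ids == ["a", "b"]

    def test_matches_brute_force_max_check(self):
        rng = np.random.default_rng(17)
        feats = {f"f{i}": (100.0 + i, 1.0) for i in range(30)}
        intens = {
            f: {s: float(rng.uniform(0, 300)) for s in ("s1", "s2", "s3")}
            for f in feats
        }
        out = filter_intensity(make_ft(feats, intens), 100.0)
        expected = [f for f in feats if max(intens[f].values()) >= 100.0]
        assert out.feature_ids == expected


class TestCollapseIsotopologues:
    def test_plus_one_rung_collapsed_to_monoisotopic(self):
        # 302.1034 sits 1.2 ppm off the expected 301.1000 + 1.00336 rung
        ft = make_ft(
            {"m0": (301.1000, 6.00), "m1": (302.1034, 6.02)},
            {"m0": {"s1": 1000.0}, "m1": {"s1": 300.0}},
        )
        out = collapse_isotopologues(ft)
        assert out.feature_ids == ["m0"]
        assert bool(out.features.at["m0", "monoisotopic"])
        # summed group intensity recorded, survivor's own intensity untouched
        assert out.group_intensities.at["m0", "s1"] == pytest.approx(1300.0)
        assert out.intensities.at["m0", "s1"] == pytest.approx(1000.0)

    def test_isolated_feature_unchanged_but_flagged(self):
        ft = make_ft({"a": (250.0, 3.0)}, {"a": {"s1": 400.0}})
        out = collapse_isotopologues(ft)
        assert out.feature_ids == ["a"]
        assert bool(out.features.at["a", "monoisotopic"])

    def test_far_rt_not_collapsed(self):
        ft = make_ft(
            {"m0": (301.1000, 6.00), "other": (302.10336, 8.00)},
            {"m0": {"s1": 1000.0}, "other": {"s1": 300.0}},
        )
        out = collapse_isotopologues(ft, rt_tol_min=0.1)
        assert set(out.feature_ids) == {"m0", "other"}

    def test_planted_ladders_leave_one_survivor_each(self):
        from ceconet.features import ISOTOPE_SPACING

        rng = np.random.default_rng(5)
        feats, intens = {}, {}
        expected_survivors = []
        for lad in range(10):
            m0 = float(rng.uniform(150, 500))
            rt = float(rng.uniform(1, 13))
            expected_survivors.append(f"lad{lad}_0")
            for k in range(3):
                fid = f"lad{lad}_{k}"
                feats[fid] = (m0 + k * ISOTOPE_SPACING, rt + float(rng.normal(0, 0.01)))
                intens[fid] = {"s1": 1000.0 * 0.4**k}
        out = collapse_isotopologues(make_ft(feats, intens))
        assert sorted(out.feature_ids) == sorted(expected_survivors)


class TestClassifyTemporal:
    GROUPS = {
        1: (["i1a", "i1b", "i1c"], ["b1a", "b1b", "b1c"]),
        7: (["i7a", "i7b", "i7c"], ["b7a", "b7b", "b7c"]),
    }

    @classmethod
    def feature_with(cls, day1_inoc, day7_inoc, blank=1000.0):
        """Intensities with tiny within-group jitter so variance is nonzero."""
        vals = {}
        for i, s in enumerate(["i1a", "i1b", "i1c"]):
            vals[s] = day1_inoc + i * 0.1
        for i, s in enumerate(["i7a", "i7b", "i7c"]):
            vals[s] = day7_inoc + i * 0.1
        for i, s in enumerate(["b1a", "b1b", "b1c", "b7a", "b7b", "b7c"]):
            vals[s] = blank + i * 0.1
        return vals

    def test_depleted_both_days_is_fast_substrate(self):
        ft = make_ft({"f": (200.0, 1.0)}, {"f": self.feature_with(100.0, 100.0)})
        cls, _ = classify_temporal(ft, self.GROUPS)
        assert cls["f"] == TemporalClass.FAST_SUBSTRATE.value

    def test_elevated_day1_back_to_blank_day7_is_intermediate(self):
        ft = make_ft({"f": (200.0, 1.0)}, {"f": self.feature_with(5000.0, 1000.15)})
        cls, _ = classify_temporal(ft, self.GROUPS)
        assert cls["f"] == TemporalClass.INTERMEDIATE.value

    def test_elevated_only_day7_is_slow_product(self):
        ft = make_ft({"f": (200.0, 1.0)}, {"f": self.feature_with(1000.15, 5000.0)})
        cls, _ = classify_temporal(ft, self.GROUPS)
        assert cls["f"] == TemporalClass.SLOW_PRODUCT.value

    def test_zero_variance_everywhere_is_unclassified_with_diagnostic(self):
        vals = {s: 500.0 for g in self.GROUPS.values() for part in g for s in part}
        ft = make_ft({"f": (200.0, 1.0)}, {"f": vals})
        cls, summary = classify_temporal(ft, self.GROUPS)
        assert cls["f"] == TemporalClass.UNCLASSIFIED.value
        assert summary["diagnostics"]

    def test_class_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        feats = {f"f{i}": (100.0 + i, 1.0) for i in range(12)}
        intens = {
            f: {
                s: float(rng.uniform(100, 2000))
                for g in self.GROUPS.values()
                for part in g
                for s in part
            }
            for f in feats
        }
        _, summary = classify_temporal(make_ft(feats, intens), self.GROUPS)
        assert sum(summary["class_percentages"].values()) == pytest.approx(100.0)

    def test_too_few_samples_rejected(self):
        ft = make_ft({"f": (200.0, 1.0)}, {"f": {"i1": 1.0, "b1": 2.0}})
        with pytest.raises(ValueError, match=">= 2"):
            classify_temporal(ft, {1: (["i1"], ["b1"]), 7: (["i1"], ["b1"])})


class TestCorrectRetentionTime:
    def test_exact_linear_anchors_give_zero_residuals(self):
        rt_std = np.linspace(1, 10, 8)
        rt_obs = 1.05 * rt_std + 0.1
        anchors = list(zip(rt_obs, rt_std))
        corrected = correct_retention_time(anchors, rt_obs)
        np.testing.assert_allclose(corrected, rt_std, atol=1e-9)

    def test_two_segments_each_use_their_own_fit(self):
        # segment A: std = obs - 0.5 (obs < 6); segment B: std = 0.8*obs (obs > 8)
        obs_a = np.array([1.0, 2.0, 3.0, 4.0])
        obs_b = np.array([8.0, 9.0, 10.0, 11.0])
        anchors = [(o, o - 0.5) for o in obs_a] + [(o, 0.8 * o) for o in obs_b]
        got = correct_retention_time(anchors, [2.5, 9.5], k=3)
        assert got[0] == pytest.approx(2.0, abs=1e-9)
        assert got[1] == pytest.approx(0.8 * 9.5, abs=1e-9)

    def test_query_at_anchor_recovers_anchor_standard_rt(self):
        anchors = [(1.0, 0.9), (2.0, 1.9), (3.0, 2.9)]
        got = correct_retention_time(anchors, [2.0])
        assert got[0] == pytest.approx(1.9, abs=1e-9)

    def test_fewer_than_two_anchors_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            correct_retention_time([(1.0, 1.0)], [1.5])

    def test_extrapolates_from_nearest_window(self):
        rt_std = np.array([2.0, 4.0, 6.0])
        anchors = [(s + 0.3, s) for s in rt_std]
        got = correct_retention_time(anchors, [10.0])
        assert got[0] == pytest.approx(9.7, abs=1e-9)


class TestAnnotation:
    def test_candidate_with_detected_neighbors_outranks_zero_neighbor_decoy(
        self, tiny_kb_dir
    ):
        kb = load_knowledge_base(tiny_kb_dir)
        # feature at putrescine's [M+H]+; its pair partner N-acetylputrescine is
        # also detected.  Pyruvate (88.01604) is near-isobaric with putrescine
        # (88.10005) only at huge tolerance; use a wide ppm to force the tie.
        putrescine_mz = 88.10005 + 1.007276
        partner_mz = 130.11061 + 1.007276
        ft = make_ft(
            {"f1": (putrescine_mz, 5.0), "f2": (partner_mz, 6.0)},
            {"f1": {"s1": 500.0}, "f2": {"s1": 700.0}},
        )
        cands = annotate_by_mass_and_neighborhood(ft, kb, ppm_tol=10.0)
        assert cands["f1"][0].compound_id == "C00134"
        assert cands["f1"][0].score >= 1

    def test_feature_matching_nothing_gets_empty_list(self, tiny_kb_dir):
        kb = load_knowledge_base(tiny_kb_dir)
        ft = make_ft({"f1": (999.999, 5.0)}, {"f1": {"s1": 100.0}})
        cands = annotate_by_mass_and_neighborhood(ft, kb)
        assert cands["f1"] == []

    def test_no_compound_masses_rejected(self, tiny_kb_dir):
        kb = load_knowledge_base(tiny_kb_dir)
        kb.compounds = kb.compounds.assign(monoisotopic_mass=np.nan)
        ft = make_ft({"f1": (100.0, 5.0)}, {"f1": {"s1": 100.0}})
        with pytest.raises(ValueError, match="mass"):
            annotate_by_mass_and_neighborhood(ft, kb)

    def test_score_monotone_in_detected_neighbors(self, tiny_kb_dir):
        kb = load_knowledge_base(tiny_kb_dir)
        putrescine_mz = 88.10005 + 1.007276
        partner_mz = 130.11061 + 1.007276
        without = make_ft(
            {"f1": (putrescine_mz, 5.0)}, {"f1": {"s1": 500.0}}
        )
        with_nb = make_ft(
            {"f1": (putrescine_mz, 5.0), "f2": (partner_mz, 6.0)},
            {"f1": {"s1": 500.0}, "f2": {"s1": 700.0}},
        )
        score_without = annotate_by_mass_and_neighborhood(without, kb)["f1"][0].score
        score_with = annotate_by_mass_and_neighborhood(with_nb, kb)["f1"][0].score
        assert score_with >= score_without
        assert score_with >= 1
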