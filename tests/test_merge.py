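import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from breathflow import merge as mg
from breathflow.cliques import CliqueCompound
from breathflow.deconv import AlignedCompound
from breathflow.peakpick import Feature, FeatureGroup, FeatureMatrix


def group(gid, mz, rt, maxo_by_sample):
    members = {
        s: Feature(f"{s}_{gid}", s, mz, rt, rt - 0.05, rt + 0.05, v)
        for s, v in maxo_by_sample.items()
    }
    return FeatureGroup(gid, mz, rt, members)


def matrix_for(groups, samples):
    values = pd.DataFrame(
        {
            s: [g.members[s].maxo if s in g.members else 0.0 for g in groups]
            for s in samples
        },
        index=[g.group_feature_id for g in groups],
    )
    return FeatureMatrix(groups, list(samples), values)


class TestMatchFeaturesToIons:
    def test_same_mz_within_tolerance_matches(self):
        g = group("f91", 91, 10.02, {"a": 10.0})
        pairs = mg.match_features_to_ions([g], 10.00, {91: 1000.0})
        assert pairs == [("f91", 91)]

    def test_boundary_rt_exactly_005_matches(self):
        g = group("f91", 91, 10.05, {"a": 10.0})
        assert mg.match_features_to_ions([g], 10.00, {91: 1000.0}) == [("f91", 91)]

    def test_rt_006_does_not_match(self):
        g = group("f91", 91, 10.06, {"a": 10.0})
        assert mg.match_features_to_ions([g], 10.00, {91: 1000.0}) == []

    def test_mz_absent_from_spectrum_does_not_match(self):
        g = group("f92", 92, 10.00, {"a": 10.0})
        assert mg.match_features_to_ions([g], 10.00, {91: 1000.0}) == []

    def test_nearest_rt_wins_within_compound(self):
        g1 = group("near", 91, 10.01, {"a": 10.0})
        g2 = group("far", 91, 10.04, {"a": 10.0})
        pairs = mg.match_features_to_ions([g2, g1], 10.00, {91: 1000.0})
        assert pairs == [("near", 91)]


class TestRelativeIntensities:
    def test_three_step_protocol(self):
        gs = [
            group("A", 91, 1.0, {"s1": 300.0, "s2": 100.0}),  # avg 200
            group("B", 92, 1.0, {"s1": 100.0, "s2": 100.0}),  # avg 100
            group("C", 65, 1.0, {"s1": 60.0, "s2": 40.0}),  # avg 50
        ]
        cc = CliqueCompound("c1", 1.0, gs, 1.0)
        rel = mg.relative_intensities(cc, matrix_for(gs, ["s1", "s2"]))
        assert rel == {"A": 1000.0, "B": 500.0, "C": 250.0}

    def test_single_member_gets_1000(self):
        gs = [group("X", 91, 1.0, {"s1": 7.0})]
        cc = CliqueCompound("c1", 1.0, gs, 1.0)
        rel = mg.relative_intensities(cc, matrix_for(gs, ["s1"]))
        assert rel == {"X": 1000.0}

    def test_tied_averages_both_base_peak(self):
        gs = [
            group("A", 91, 1.0, {"s1": 7.0}),
            group("B", 92, 1.0, {"s1": 7.0}),
        ]
        cc = CliqueCompound("c1", 1.0, gs, 1.0)
        rel = mg.relative_intensities(cc, matrix_for(gs, ["s1"]))
        assert rel == {"A": 1000.0, "B": 1000.0}


class TestVectorize:
    def test_default_range_has_412_positions(self):
        assert len(mg.vectorize({91: 1000.0})) == 412

    def test_empty_spectrum_flagged(self):
        v = mg.vectorize({})
        assert v.empty and np.linalg.norm(v.values) == 0.0

    def test_single_ion_lands_at_offset_position(self):
        v = mg.vectorize({91: 1000.0})
        assert v.values[91 - 38] == pytest.approx(1.0)
        assert np.count_nonzero(v.values) == 1

    def test_out_of_range_keys_dropped(self):
        v = mg.vectorize({91: 1000.0, 500: 300.0, 20: 100.0})
        assert np.count_nonzero(v.values) == 1

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            mg.vectorize({91: 1.0}, mz_lo=100, mz_hi=100)


class TestSpectralDot:
    def test_self_dot_is_one(self):
        v = mg.vectorize({91: 1000.0, 92: 500.0})
        assert mg.spectral_dot(v, v) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports_dot_zero(self):
        a = mg.vectorize({91: 1000.0})
        b = mg.vectorize({105: 1000.0})
        assert mg.spectral_dot(a, b) == 0.0

    def test_hand_computed_value(self):
        a = mg.vectorize({91: 1000.0})
        b = mg.vectorize({91: 1000.0, 92: 500.0})
        assert mg.spectral_dot(a, b) == pytest.approx(2 / np.sqrt(5), abs=1e-12)

    def test_mismatched_bounds_rejected(self):
        a = mg.vectorize({91: 1000.0})
        b = mg.vectorize({91: 1000.0}, mz_lo=35, mz_hi=460)
        with pytest.raises(ValueError):
            mg.spectral_dot(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.integers(38, 449),
            st.floats(1.0, 1000.0, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        st.dictionaries(
            st.integers(38, 449),
            st.floats(1.0, 1000.0, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        st.floats(0.1, 50.0, allow_nan=False),
    )
    def test_symmetric_scale_invariant_and_identity(self, s1, s2, scale):
        v1, v2 = mg.vectorize(s1), mg.vectorize(s2)
        d12, d21 = mg.spectral_dot(v1, v2), mg.spectral_dot(v2, v1)
        assert d12 == pytest.approx(d21, abs=1e-12)
        scaled = mg.vectorize({mz: v * scale for mz, v in s1.items()})
        assert mg.spectral_dot(scaled, v2) == pytest.approx(d12, abs=1e-9)
        assert mg.spectral_dot(v1, scaled) == pytest.approx(1.0, abs=1e-9)


def aligned(aid, rt, spectrum, areas=None):
    return AlignedCompound(aid, rt, dict(spectrum), dict(areas or {}))


class TestMatchCompounds:
    def test_identical_compound_is_filtered_in(self):
        spec = {91: 1000.0, 92: 500.0}
        fset, results = mg.match_compounds(
            {"c1": spec},
            {"c1": 10.0},
            [aligned("d1", 10.0, spec), aligned("d2", 10.0, {105: 1000.0})],
        )
        assert fset.filtered_compounds == ["d1"]
        best = [r for r in results if r.is_best_for_clique]
        assert len(best) == 1 and best[0].aligned_id == "d1"

    def test_dot_below_and_at_threshold_rejected(self):
        # 0.7 exactly must NOT pass the strictly-greater filter
        spec_c = {91: 1000.0}
        v = mg.vectorize(spec_c)
        # construct a deconv spectrum with dot exactly 0.7 against spec_c
        x = 1000.0 * np.sqrt(1 - 0.7**2) / 0.7
        spec_d = {91: 1000.0, 105: x}
        d = mg.spectral_dot(v, mg.vectorize(spec_d))
        assert d == pytest.approx(0.7, abs=1e-12)
        fset, _ = mg.match_compounds(
            {"c1": spec_c}, {"c1": 10.0}, [aligned("d1", 10.0, spec_d)]
        )
        assert fset.filtered_compounds == []

    def test_second_best_excluded_even_above_threshold(self):
        spec = {91: 1000.0, 92: 500.0}
        near = {91: 1000.0, 92: 400.0}  # dot > 0.7 but never the best
        fset, _ = mg.match_compounds(
            {"c1": spec},
            {"c1": 10.0},
            [aligned("d1", 10.0, spec), aligned("d2", 10.0, near)],
        )
        assert fset.filtered_compounds == ["d1"]

    def test_filtered_features_follow_filtered_compounds(self):
        spec = {91: 1000.0, 92: 500.0}
        groups = [
            group("f91", 91, 10.0, {"a": 200.0}),
            group("f92", 92, 10.0, {"a": 100.0}),
            group("f105", 105, 10.0, {"a": 50.0}),
        ]
        fset, _ = mg.match_compounds(
            {"c1": spec}, {"c1": 10.0}, [aligned("d1", 10.0, spec)], groups
        )
        assert fset.filtered_features == ["f91", "f92"]
        assert fset.feature_to_compound == {"f91": ["d1"], "f92": ["d1"]}

    def test_empty_sides_give_empty_filtered_set(self):
        fset, results = mg.match_compounds({}, {}, [])
        assert fset.filtered_compounds == [] and results == []


class TestDetectDuplicates:
    SPEC = {91: 1000.0, 92: 500.0, 65: 200.0}
    AREAS_A = {"s1": 10.0, "s2": 20.0, "s3": 30.0}
    AREAS_B = {"s1": 9.0, "s2": 19.0, "s3": 28.0}  # Pearson ~ 0.99, smaller total

    def rec(self, rid, rt, areas=None, spec=None):
        return mg.DupRecord(rid, rt, spec or self.SPEC, areas)

    def test_planted_split_is_flagged_and_deduplicated(self):
        a = self.rec("a", 10.00, self.AREAS_A)
        b = self.rec("b", 10.03, self.AREAS_B)
        pairs, dedup = mg.detect_duplicates([a, b])
        assert len(pairs) == 1 and pairs[0].dot > 0.99
        assert [r.id for r in dedup] == ["a"]  # larger total area kept

    def test_distant_rt_not_flagged(self):
        a = self.rec("a", 10.0, self.AREAS_A)
        b = self.rec("b", 10.2, self.AREAS_B)
        assert mg.detect_duplicates([a, b])[0] == []

    def test_rt_boundary_005_is_flagged(self):
        a = self.rec("a", 10.00, self.AREAS_A)
        b = self.rec("b", 10.05, self.AREAS_B)
        assert len(mg.detect_duplicates([a, b])[0]) == 1

    def test_uncorrelated_areas_not_flagged(self):
        a = self.rec("a", 10.00, {"s1": 10.0, "s2": 20.0, "s3": 30.0})
        b = self.rec("b", 10.02, {"s1": 30.0, "s2": 10.0, "s3": 20.0})
        assert mg.detect_duplicates([a, b])[0] == []

    def test_pearson_boundary_is_strict(self):
        a = self.rec("a", 10.00, {"s1": 1.0, "s2": 2.0, "s3": 3.0})
        b = self.rec("b", 10.02, {"s1": 1.0, "s2": 3.0, "s3": 2.0})
        # Pearson here is exactly 0.5: not above 0.75 -> not flagged
        assert mg.detect_duplicates([a, b])[0] == []

    def test_dot_boundary_08_is_strict(self):
        x = 1000.0 * np.sqrt(1 - 0.8**2) / 0.8
        a = self.rec("a", 10.00, None, {91: 1000.0})
        b = self.rec("b", 10.02, None, {91: 1000.0, 105: x})
        assert mg.detect_duplicates([a, b])[0] == []

    def test_clique_side_needs_no_area_correlation(self):
        a = self.rec("a", 10.00)  # no areas: feature-route compound
        b = self.rec("b", 10.03)
        pairs, _ = mg.detect_duplicates([a, b])
        assert len(pairs) == 1 and pairs[0].area_pearson is None

    def test_single_compound_no_report(self):
        assert mg.detect_duplicates([self.rec("a", 10.0)]) == ([], [self.rec("a", 10.0)])


class TestNormalizeMatrix:
    def test_printed_formula_example(self):
        # one feature: 100 in one sample, sum across samples 10000
        values = pd.DataFrame({"s1": [100.0], "s2": [9900.0]}, index=["f"])
        out = mg.normalize_matrix(values)
        assert out.at["f", "s1"] == pytest.approx(2 / 4 * 1000)

    def test_single_sample_subset_is_1000(self):
        values = pd.DataFrame({"s1": [123.0]}, index=["f"])
        out = mg.normalize_matrix(values)
        assert out.at["f", "s1"] == pytest.approx(1000.0)

    def test_value_one_maps_to_zero(self):
        values = pd.DataFrame({"s1": [1.0], "s2": [999.0]}, index=["f"])
        out = mg.normalize_matrix(values)
        assert out.at["f", "s1"] == 0.0

    def test_zeros_floored_before_log(self):
        values = pd.DataFrame({"s1": [0.0], "s2": [1000.0]}, index=["f"])
        out = mg.normalize_matrix(values)
        assert out.at["f", "s1"] == 0.0
        assert np.isfinite(out.to_numpy()).all()

    def test_per_subset_denominators(self):
        values = pd.DataFrame(
            {"m1": [100.0], "m2": [100.0], "r1": [10.0], "r2": [10.0]}, index=["f"]
        )
        subsets = {"m1": "mother", "m2": "mother", "r1": "room", "r2": "room"}
        out = mg.normalize_matrix(values, subsets=subsets)
        assert out.at["f", "m1"] == pytest.approx(np.log10(100) / np.log10(200) * 1000)
        assert out.at["f", "r1"] == pytest.approx(np.log10(10) / np.log10(20) * 1000)

    def test_alternative_denominator_modes(self):
        values = pd.DataFrame({"s1": [100.0], "s2": [100.0]}, index=["f"])
        out_sum = mg.normalize_matrix(values, mode="sum")
        out_mean = mg.normalize_matrix(values, mode="mean")
        out_sumlog = mg.normalize_matrix(values, mode="sumlog")
        assert out_sum.at["f", "s1"] == pytest.approx(2 / np.log10(200) * 1000)
        assert out_mean.at["f", "s1"] == pytest.approx(1000.0)
        assert out_sumlog.at["f", "s1"] == pytest.approx(500.0)
        with pytest.raises(ValueError):
            mg.normalize_matrix(values, mode="median")
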