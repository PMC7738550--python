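import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from breathflow import peakpick as pp
from breathflow import synth
from breathflow.eic import bin_run
from conftest import clean_design, gaussian_compound


class TestSmoothAndBaseline:
    def test_identity_configuration(self, single_peak_run):
        run, _ = single_peak_run
        out = pp.smooth_and_baseline(run, window=1, baseline_quantile=0.0)
        np.testing.assert_allclose(bin_run(out).matrix, bin_run(run).matrix)
        np.testing.assert_allclose(out.rts, run.rts)

    def test_constant_signal_zeroed_by_median_baseline(self):
        run = synth.simulate_run(
            [], clean_design(baseline_level=7.0), "s1", "group1", "mother"
        )
        out = pp.smooth_and_baseline(run, window=1, baseline_quantile=0.5)
        np.testing.assert_allclose(bin_run(out).matrix, 0.0)

    def test_constant_offset_removed_from_apex(self):
        comp = gaussian_compound("x", {91: 1000.0}, 1.5)
        comp.abundance_by_sample["s1"] = 1e4
        run = synth.simulate_run(
            [comp], clean_design(baseline_level=500.0), "s1", "group1", "mother",
            jitter_sd=0,
        )
        out = pp.smooth_and_baseline(run, window=1, baseline_quantile=0.25)
        apex = bin_run(out).eic(91).max()
        assert apex == pytest.approx(1e4, rel=0.01)  # reduced by about b

    def test_even_window_rejected(self, single_peak_run):
        run, _ = single_peak_run
        with pytest.raises(ValueError):
            pp.smooth_and_baseline(run, window=2)


class TestDetectPeaks:
    def test_single_noiseless_peak_matches_brute_force_oracle(self, single_peak_run):
        run, comp = single_peak_run
        feats = pp.detect_peaks(run, fwhm=0.047, snr_threshold=5)
        assert len(feats) == 1
        (f,) = feats
        br = bin_run(run)
        oracle_rt = br.rts[int(np.argmax(br.eic(91)))]  # brute-force apex
        assert f.mz == 91
        assert abs(f.rt - oracle_rt) <= br.scan_interval
        assert abs(f.rt - 1.5) <= br.scan_interval
        assert f.maxo == pytest.approx(1e5, rel=0.01)
        assert f.rt_lo <= f.rt <= f.rt_hi

    def test_two_peaks_six_sigma_apart_resolved(self):
        c1 = gaussian_compound("a", {91: 1000.0}, 1.5, sigma=0.02)
        c2 = gaussian_compound("b", {91: 1000.0}, 1.5 + 6 * 0.02, sigma=0.02)
        run = synth.simulate_run(
            [c1, c2], clean_design(), "s1", "group1", "mother", jitter_sd=0
        )
        feats = pp.detect_peaks(run, fwhm=0.047, snr_threshold=5)
        assert len(feats) == 2
        rts = sorted(f.rt for f in feats)
        assert rts[0] == pytest.approx(1.5, abs=0.01)
        assert rts[1] == pytest.approx(1.62, abs=0.01)

    def test_pure_noise_rarely_detected(self):
        hits = 0
        for seed in range(20):
            run = synth.simulate_run(
                [],
                clean_design(noise_sd=30.0, mz_range=(38, 60), seed=seed),
                f"n{seed}",
                "group1",
                "room_air",
            )
            hits += len(pp.detect_peaks(run, fwhm=0.047, snr_threshold=10))
        assert hits == 0  # 0 features in >= 99% of seeded replicates

    def test_noiseless_recall_at_correct_mz_and_rt(self):
        _, comps = synth.make_library(
            3, seed=5, mz_range=(38, 150), program=clean_design().program
        )
        for c, rt in zip(comps, (0.5, 1.5, 2.5)):  # chromatographically resolved
            c.rt_mean = rt
            c.abundance_by_sample["s1"] = 1e5
        run = synth.simulate_run(
            comps, clean_design(), "s1", "group1", "mother", jitter_sd=0
        )
        feats = pp.detect_peaks(run, fwhm=0.047, snr_threshold=5)
        br = bin_run(run)
        found = {(f.mz, round(f.rt, 2)) for f in feats}
        for c in comps:
            for mz in c.spectrum:  # all ions >= 20x the (zero) noise floor
                assert any(
                    fmz == mz and abs(frt - c.rt_mean) <= 2 * br.scan_interval
                    for fmz, frt in ((m, r) for m, r in found)
                ), (c.name, mz)


def synthetic_features(sample_id, shift=0.0, n=12, seed=0):
    """A ladder of single-ion features shared by all samples."""
    rng = np.random.default_rng(seed)
    rts = np.linspace(0.3, 2.7, n)
    return [
        pp.Feature(
            f"{sample_id}_F{i}",
            sample_id,
            91 + i,
            rt + shift,
            rt + shift - 0.05,
            rt + shift + 0.05,
            float(rng.uniform(1e3, 1e5)),
        )
        for i, rt in enumerate(rts)
    ]


class TestAlignment:
    def test_already_aligned_is_identity(self):
        fs = {s: synthetic_features(s) for s in ("a", "b", "c")}
        corrected, warps = pp.align_retention_times(fs)
        for s in fs:
            for f0, f1 in zip(fs[s], corrected[s]):
                assert abs(f1.rt - f0.rt) < 1e-6

    def test_injected_shift_removed(self):
        fs = {s: synthetic_features(s) for s in ("a", "b", "c")}
        fs["d"] = synthetic_features("d", shift=0.30)
        corrected, warps = pp.align_retention_times(fs)
        residuals = [
            abs(fd.rt - fa.rt) for fd, fa in zip(corrected["d"], corrected["a"])
        ]
        assert max(residuals) < 0.01

    def test_anchor_variance_non_increasing(self):
        fs = {s: synthetic_features(s) for s in ("a", "b", "c")}
        fs["d"] = synthetic_features("d", shift=0.30)
        corrected, _ = pp.align_retention_times(fs)
        for i in range(12):
            before = np.var([fs[s][i].rt for s in fs])
            after = np.var([corrected[s][i].rt for s in fs])
            assert after <= before + 1e-12

    def test_single_sample_identity_warp(self):
        fs = {"only": synthetic_features("only")}
        corrected, warps = pp.align_retention_times(fs)
        assert warps["only"].deviation(1.0) == 0.0
        assert [f.rt for f in corrected["only"]] == [f.rt for f in fs["only"]]


def oracle_clusters(rts, bw):
    """Independent exhaustive clustering: single linkage cut at bw."""
    if len(rts) == 1:
        return 1
    Z = linkage(np.asarray(rts, dtype=float).reshape(-1, 1), method="single")
    return len(set(fcluster(Z, t=bw, criterion="distance")))


class TestGrouping:
    def test_identical_peak_in_three_samples(self):
        fs = {
            s: [pp.Feature(f"{s}_F0", s, 91, 1.0, 0.95, 1.05, 100.0)]
            for s in ("a", "b", "c")
        }
        groups = pp.group_features(fs, rt_bw=0.033)
        assert len(groups) == 1
        assert set(groups[0].members) == {"a", "b", "c"}

    def test_two_distant_clusters_split(self):
        bw = 0.033
        fs = {
            s: [
                pp.Feature(f"{s}_F0", s, 91, 1.0, 0.95, 1.05, 10.0),
                pp.Feature(f"{s}_F1", s, 91, 1.0 + 10 * bw, 1.28, 1.38, 10.0),
            ]
            for s in ("a", "b")
        }
        groups = pp.group_features(fs, rt_bw=bw)
        assert len(groups) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        rts = np.sort(rng.uniform(0, 1, n))
        bw = float(rng.uniform(0.02, 0.2))
        # all features same m/z, one synthetic sample each -> minfrac off
        fs = {
            f"s{i}": [pp.Feature(f"s{i}_F", f"s{i}", 91, rt, rt - 0.01, rt + 0.01, 1.0)]
            for i, rt in enumerate(rts)
        }
        groups = pp.group_features(fs, rt_bw=bw, minfrac=0.0)
        assert len(groups) == oracle_clusters(rts, bw)

    def test_singleton_below_minfrac_dropped(self):
        fs = {
            "a": [pp.Feature("a_F0", "a", 91, 1.0, 0.95, 1.05, 10.0)],
            "b": [],
            "c": [],
        }
        assert pp.group_features(fs, rt_bw=0.033, minfrac=0.5) == []


class TestFillMissing:
    def make_scene(self, drop_sample=None, height=5e4):
        comp = gaussian_compound("x", {91: 1000.0}, 1.5)
        runs, fs = {}, {}
        for s in ("a", "b", "c"):
            comp.abundance_by_sample[s] = height
            present = s != drop_sample
            runs[s] = synth.simulate_run(
                [comp] if present else [],
                clean_design(),
                s,
                "group1",
                "mother",
                jitter_sd=0,
            )
            fs[s] = pp.detect_peaks(runs[s], fwhm=0.047, snr_threshold=5)
        groups = pp.group_features(fs, rt_bw=0.033, minfrac=0.5)
        return runs, fs, groups

    def test_no_gaps_keeps_member_values(self):
        runs, fs, groups = self.make_scene()
        matrix = pp.fill_missing(groups, runs)
        assert matrix.filled == set()
        for g in groups:
            for s, f in g.members.items():
                assert matrix.values.at[g.group_feature_id, s] == f.maxo

    def test_gap_over_flat_signal_fills_zero(self):
        runs, fs, groups = self.make_scene(drop_sample="c")
        matrix = pp.fill_missing(groups, runs)
        gid = groups[0].group_feature_id
        assert (gid, "c") in matrix.filled
        assert matrix.values.at[gid, "c"] == 0.0

    def test_gap_over_subthreshold_peak_recovers_height(self):
        # the peak exists in c but is too weak for the detector
        comp = gaussian_compound("x", {91: 1000.0}, 1.5)
        runs, fs = {}, {}
        for s, height in (("a", 5e4), ("b", 5e4), ("c", 400.0)):
            comp.abundance_by_sample[s] = height
            runs[s] = synth.simulate_run(
                [comp], clean_design(), s, "group1", "mother", jitter_sd=0
            )
            fs[s] = pp.detect_peaks(runs[s], fwhm=0.047, snr_threshold=5)
            if s == "c":
                fs[s] = [f for f in fs[s] if f.maxo > 1e3]  # below detection
        groups = pp.group_features(fs, rt_bw=0.033, minfrac=0.5)
        matrix = pp.fill_missing(groups, runs)
        gid = groups[0].group_feature_id
        assert (gid, "c") in matrix.filled
        assert matrix.values.at[gid, "c"] == pytest.approx(400.0, rel=0.05)
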