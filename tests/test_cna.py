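import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radgen.cna import (CbsConfig, CnaCall, CoreProfile, Segment,
                        build_core_profiles, cbs_segment, compute_log_ratio,
                        filter_significant, identify_index_lesions)
from radgen._cbs_core import max_arc_tstat
from radgen.synthetic import expected_significant_implants

from conftest import make_track


def brute_force_max_split(x: np.ndarray, min_seg: int):
    """Independent exhaustive arc scan using scipy's two-sample t test."""
    best = (-np.inf, None, None)
    n = len(x)
    for i in range(n):
        for j in range(i + min_seg, n + 1):
            if n - (j - i) < min_seg:
                continue
            arc = x[i:j]
            comp = np.r_[x[:i], x[j:]]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = stats.ttest_ind(arc, comp, equal_var=True).statistic
            t = np.inf if np.isnan(t) and not np.isclose(arc.mean(), comp.mean()) \
                else abs(t)
            if t > best[0]:
                best = (t, i, j)
    return best


class TestLogRatio:
    def _table(self, intensity, probe_ids=None):
        n = len(intensity)
        return pd.DataFrame({
            "probe_id": probe_ids or [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": np.arange(n) * 100_000,
            "intensity": intensity,
        })

    def test_tumor_equal_reference_gives_zero_track(self):
        t = self._table(np.full(50, 900.0))
        track = compute_log_ratio(t, [t.copy(), t.copy()])
        assert np.allclose(track.table["log2_ratio"], 0.0)

    def test_doubled_intensity_gives_plus_one(self):
        ref = self._table(np.linspace(500, 1500, 40))
        tum = ref.copy()
        tum["intensity"] *= 2
        track = compute_log_ratio(tum, ref)
        assert np.allclose(track.table["log2_ratio"], 1.0)

    def test_matches_elementwise_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        tum = self._table(rng.uniform(100, 2000, 100))
        refs = [self._table(rng.uniform(100, 2000, 100)) for _ in range(3)]
        track = compute_log_ratio(tum, refs)
        expected = np.log2(
            tum["intensity"].to_numpy()
            / np.median(np.stack([r["intensity"] for r in refs]), axis=0))
        assert np.allclose(track.table["log2_ratio"], expected, atol=1e-12)

    def test_empty_intersection_rejected(self):
        a = self._table(np.full(10, 1.0), [f"a{i}" for i in range(10)])
        b = self._table(np.full(10, 1.0), [f"b{i}" for i in range(10)])
        with pytest.raises(ValueError, match="no probes"):
            compute_log_ratio(a, b)

    def test_nonpositive_intensity_dropped_with_warning(self):
        tum = self._table(np.full(20, 1000.0))
        tum.loc[5, "intensity"] = -1.0
        ref = self._table(np.full(20, 1000.0))
        with pytest.warns(UserWarning, match="dropped"):
            track = compute_log_ratio(tum, ref)
        assert len(track.table) == 19


class TestCbs:
    def test_flat_track_one_segment_per_chromosome(self):
        track = make_track(np.zeros(60))
        segs = cbs_segment(track, CbsConfig(seed=0))
        assert len(segs) == 1
        assert segs[0].n_probes == 60

    def test_noise_free_step_found_exactly(self):
        track = make_track(np.r_[np.zeros(50), np.full(50, 0.5)])
        segs = cbs_segment(track, CbsConfig(seed=0))
        assert [s.n_probes for s in segs] == [50, 50]
        assert np.isclose(segs[0].mean_log2r, 0.0)
        assert np.isclose(segs[1].mean_log2r, 0.5)

    def test_split_location_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            x = rng.normal(0, 0.1, 14)
            x[5:10] += 0.8
            stat, i, j = max_arc_tstat(x, 3)
            bstat, bi, bj = brute_force_max_split(x, 3)
            assert (i, j) == (bi, bj)
            assert np.isclose(stat, bstat, rtol=1e-10)

    def test_permutation_pvalue_within_mc_tolerance_of_oracle(self):
        # clear change point: p should be small under both implementations
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 0.1, 8), rng.normal(1.0, 0.1, 8)]
        obs, _, _ = max_arc_tstat(x, 3)
        from radgen.cna import _permutation_pvalue
        cfg = CbsConfig(seed=5, n_permutations=500)
        p_impl = _permutation_pvalue(x, obs, 3, cfg, np.random.default_rng(5))
        oracle_rng = np.random.default_rng(99)
        count = sum(
            brute_force_max_split(oracle_rng.permutation(x), 3)[0] >= obs
            for _ in range(500))
        p_oracle = (1 + count) / 501
        assert abs(p_impl - p_oracle) < 0.05
        # null data: both decide "no split" at alpha
        xn = rng.normal(0, 0.1, 14)
        obs_n, _, _ = max_arc_tstat(xn, 3)
        p_null = _permutation_pvalue(xn, obs_n, 3, cfg, np.random.default_rng(6))
        assert p_null >= cfg.alpha

    def test_partition_property_weighted_mean(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 0.15, 120)
        vals[40:80] -= 0.4
        track = make_track(vals)
        segs = cbs_segment(track, CbsConfig(seed=1))
        assert sum(s.n_probes for s in segs) == 120
        weighted = sum(s.mean_log2r * s.n_probes for s in segs) / 120
        assert np.isclose(weighted, vals.mean(), atol=1e-10)

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 0.2, 150)
        vals[30:90] += 0.35
        track = make_track(vals)
        a = cbs_segment(track, CbsConfig(seed=4))
        b = cbs_segment(track, CbsConfig(seed=4))
        assert a == b

    def test_short_chromosome_returned_whole(self):
        track = make_track([0.1, 0.2, 0.9, 1.0])
        segs = cbs_segment(track, CbsConfig(min_probes_per_segment=3, seed=0))
        assert len(segs) == 1 and segs[0].n_probes == 4


def seg(mean, length_bp, chrom="chr1", start=0, n_probes=20):
    return Segment(chrom, start, start + length_bp + 1, n_probes, mean)


class TestFilter:
    def test_boundary_mean_exactly_threshold_excluded(self):
        assert filter_significant([seg(0.2, 20_000_000)]) == []
        assert filter_significant([seg(-0.2, 20_000_000)]) == []
        assert len(filter_significant([seg(0.2000001, 20_000_000)])) == 1

    def test_length_boundary_inclusive_at_10_mbp(self):
        assert filter_significant([seg(0.5, 9_999_999)]) == []
        calls = filter_significant([seg(0.5, 10_000_000)])
        assert len(calls) == 1 and calls[0].length_bp == 10_000_000

    def test_toy_set_matches_hand_enumeration(self):
        segments = [
            seg(0.5, 20_000_000),    # kept, gain
            seg(-0.3, 15_000_000),   # kept, loss
            seg(0.15, 50_000_000),   # mean too small
            seg(0.9, 5_000_000),     # too short
            seg(-0.21, 9_999_999),   # too short by 1 bp
        ]
        calls = filter_significant(segments)
        assert [(c.direction, c.length_bp) for c in calls] == [
            ("gain", 20_000_000), ("loss", 15_000_000)]

    @pytest.mark.parametrize("threshold,min_len", [
        (0.2, 10_000_000), (0.3, 10_000_000), (0.2, 20_000_000),
        (0.4, 30_000_000)])
    def test_monotonicity_in_threshold_and_length(self, threshold, min_len):
        rng = np.random.default_rng(5)
        segments = [seg(rng.uniform(-0.8, 0.8), int(rng.uniform(1e6, 6e7)))
                    for _ in range(40)]
        base = len(filter_significant(segments, CbsConfig()))
        stricter = len(filter_significant(
            segments, CbsConfig(threshold=threshold, min_length_bp=min_len)))
        assert stricter <= base


class TestProfilesAndIndexLesions:
    def _profiles(self, counts: dict[str, int], patient="P1"):
        out = []
        for cid, k in counts.items():
            calls = [CnaCall(seg(0.5, 20_000_000), "gain")] * k
            out.append(CoreProfile(cid, patient, list(calls)))
        return out

    def test_zero_calls_means_no_tumor_signature(self):
        p = CoreProfile("c", "P1", [])
        assert not p.mol_tu and p.hs_mut == 0

    def test_tie_rule_flags_all_maximal_cores(self):
        profiles = self._profiles({"A": 7, "B": 7, "C": 3})
        lesions = identify_index_lesions(profiles)
        assert lesions["P1"] == {"A", "B"}
        assert all(p.hi_les == (p.core_id in {"A", "B"}) for p in profiles)

    def test_all_zero_patient_gets_no_index_lesion(self):
        profiles = self._profiles({"A": 0, "B": 0})
        with pytest.warns(UserWarning, match="no index lesion"):
            lesions = identify_index_lesions(profiles)
        assert lesions["P1"] == set()

    def test_index_lesion_implies_tumor_signature(self):
        profiles = self._profiles({"A": 2, "B": 1})
        identify_index_lesions(profiles)
        assert all(p.mol_tu for p in profiles if p.hi_les)


class TestNoiseFreeRecovery:
    def test_calls_equal_implants_surviving_filter(self, mini_cohort):
        cohort, implants = mini_cohort
        cfg = CbsConfig(seed=2)
        for pid in cohort.patients:
            refs = [cohort.intensities[r] for r in cohort.reference_cores(pid)]
            for cid in cohort.tumor_cores(pid):
                track = compute_log_ratio(cohort.intensities[cid], refs, core_id=cid)
                calls = filter_significant(cbs_segment(track, cfg), cfg)
                expected = expected_significant_implants(
                    implants[cid], cohort.template)
                assert len(calls) == len(expected), cid
                for call, im in zip(
                        sorted(calls, key=lambda c: (c.segment.chrom, c.segment.start)),
                        sorted(expected, key=lambda i: (i.chrom, i.start))):
                    # boundaries at the first/last probe inside the implant
                    pos = cohort.template.probe_positions(im.chrom)
                    inside = pos[(pos >= im.start) & (pos < im.end)]
                    assert call.segment.chrom == im.chrom
                    assert call.segment.start == inside[0]
                    assert call.segment.end == inside[-1] + 1
                    assert np.isclose(call.segment.mean_log2r, im.log2_shift)

    def test_ledger_oracle_for_core_profiles(self, mini_cohort):
        cohort, implants = mini_cohort
        cfg = CbsConfig(seed=2)
        calls_by_core = {}
        for pid in cohort.patients:
            refs = [cohort.intensities[r] for r in cohort.reference_cores(pid)]
            for cid in cohort.tumor_cores(pid):
                track = compute_log_ratio(cohort.intensities[cid], refs, core_id=cid)
                calls_by_core[cid] = filter_significant(cbs_segment(track, cfg), cfg)
        profiles = build_core_profiles(calls_by_core, cohort.manifest)
        by_id = {p.core_id: p for p in profiles}
        for cid, ims in implants.items():
            expected = len(expected_significant_implants(ims, cohort.template))
            assert by_id[cid].hs_mut == expected
        # index cores = ledger argmax per patient
        for pid in cohort.patients:
            counts = {cid: len(expected_significant_implants(implants[cid],
                                                             cohort.template))
                      for cid in cohort.tumor_cores(pid)}
            mx = max(counts.values())
            winners = {c for c, k in counts.items() if k == mx and mx > 0}
            assert {p.core_id for p in profiles
                    if p.patient_id == pid and p.hi_les} == winners
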