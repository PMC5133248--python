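"""Profile normalization, peak calling, shifts, LOD and clade summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagsip import io as gio
from tagsip import shifts as sh


def _run(n, gradient_id="g1", top=1.74, width=0.002):
    fracs = [gio.FractionRecord(gradient_id, i + 1, top - i * width, 1.0, True) for i in range(n)]
    return gio.GradientRun(gradient_id, fracs)


def _profile(ratios_or_reads, top=1.74, width=0.002):
    reads = np.asarray(ratios_or_reads, dtype=float)
    return sh.build_profile(reads, _run(len(reads), top=top, width=width), "OTU1")


class TestBuildProfile:
    def test_ratios_are_reads_over_max(self):
        prof = _profile([10, 50, 25])
        assert prof.ratios.tolist() == [0.2, 1.0, 0.5]

    def test_uniform_reads_give_all_ones(self):
        assert _profile([7, 7, 7, 7]).ratios.tolist() == [1.0] * 4

    def test_depth_scale_invariance(self):
        a = _profile([3, 9, 6, 1])
        b = _profile([6, 18, 12, 2])
        assert np.allclose(a.ratios, b.ratios)

    def test_all_zero_reads_flags_no_signal(self):
        prof = _profile([0, 0, 0])
        assert prof.no_signal and prof.ratios.tolist() == [0.0, 0.0, 0.0]

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="sequenced fractions"):
            sh.build_profile(np.array([1.0, 2.0]), _run(3), "OTU1")


class TestDetectPeaks:
    def test_supported_peak_at_global_maximum(self):
        call = sh.detect_peaks(_profile([1, 6, 10, 7, 2]))
        assert call.valid and call.method == "peak"
        assert call.support_size == 3  # the 0.6, 1.0, 0.7 fractions
        assert call.mode_density == pytest.approx(1.74 - 2 * 0.002)

    def test_single_point_spike_rejected_with_centroid_fallback(self):
        call = sh.detect_peaks(_profile([0, 0, 10, 0, 0]))
        assert not call.valid
        assert call.method == "centroid"
        assert "single-point-peak" in call.flags
        assert call.mode_density == pytest.approx(1.74 - 2 * 0.002)  # all reads in one fraction

    def test_bimodal_profile_reports_supported_secondary_peak(self):
        call = sh.detect_peaks(_profile([50, 100, 60, 10, 40, 80, 50]))
        assert call.valid and call.support_size == 3
        assert len(call.secondary_peaks) == 1
        density, support = call.secondary_peaks[0]
        assert support == 3
        assert density == pytest.approx(1.74 - 5 * 0.002)

    def test_no_signal_profile_flagged(self):
        call = sh.detect_peaks(_profile([0, 0, 0]))
        assert call.method == "none" and sh.NO_SIGNAL in call.flags

    def test_reversing_fraction_order_leaves_peak_density_unchanged(self):
        reads = [5, 60, 100, 70, 20, 10]
        fwd = sh.detect_peaks(_profile(reads))
        rev_profile = _profile(reads)
        rev = sh.detect_peaks(
            sh.OtuDensityProfile(
                otu_id="OTU1",
                gradient_id="g1",
                densities=rev_profile.densities[::-1].copy(),
                reads=rev_profile.reads[::-1].copy(),
                ratios=rev_profile.ratios[::-1].copy(),
            )
        )
        assert fwd.mode_density == pytest.approx(rev.mode_density)
        assert fwd.support_size == rev.support_size


class TestComputeShift:
    def _peak(self, density, valid=True, centroid=None):
        return sh.PeakCall(
            mode_density=density,
            support_size=3 if valid else 1,
            secondary_peaks=[],
            valid=valid,
            method="peak" if valid else "centroid",
            centroid_density=centroid if centroid is not None else density,
        )

    def test_simple_difference(self):
        delta, method = sh.compute_shift(self._peak(1.7000), self._peak(1.7040))
        assert delta == pytest.approx(0.0040) and method == "peak"

    def test_identical_profiles_give_zero(self):
        prof = _profile([5, 20, 50, 30, 10])
        call = sh.detect_peaks(prof)
        delta, _ = sh.compute_shift(call, sh.detect_peaks(prof))
        assert delta == 0.0

    def test_negative_shift_preserved(self):
        delta, _ = sh.compute_shift(self._peak(1.7040), self._peak(1.7000))
        assert delta == pytest.approx(-0.0040)

    def test_mixed_methods_compared_centroid_vs_centroid(self):
        valid = self._peak(1.7040, centroid=1.7035)
        invalid = self._peak(1.7000, valid=False, centroid=1.7000)
        delta, method = sh.compute_shift(invalid, valid)
        assert method == "centroid"
        assert delta == pytest.approx(1.7035 - 1.7000)

    def test_no_signal_side_yields_undefined_shift(self):
        nosig = sh.detect_peaks(_profile([0, 0, 0]))
        delta, method = sh.compute_shift(nosig, self._peak(1.71))
        assert delta is None and method == "none"

    def test_shift_invariant_to_per_gradient_depth_scaling(self):
        control_reads = [5, 30, 80, 60, 15]
        labeled_reads = [2, 10, 50, 90, 40]
        base = sh.compute_shift(
            sh.detect_peaks(_profile(control_reads)), sh.detect_peaks(_profile(labeled_reads))
        )
        scaled = sh.compute_shift(
            sh.detect_peaks(_profile([7 * r for r in control_reads])),
            sh.detect_peaks(_profile([3 * r for r in labeled_reads])),
        )
        assert base == scaled


class TestLodCalibration:
    def test_cutoff_is_factor_times_largest_shift(self):
        lod = sh.calibrate_lod([0.0, 0.001, 0.002] * 4)
        assert lod.cutoff == pytest.approx(0.003)

    def test_summary_stats(self):
        lod = sh.calibrate_lod([0.0, 0.001, 0.002] * 4)
        assert lod.mean == pytest.approx(0.001)
        assert lod.n == 12
        assert lod.max_abs == pytest.approx(0.002)

    def test_sd_uses_n_minus_one(self):
        vals = [0.0, 0.001, 0.002, 0.001] * 3
        lod = sh.calibrate_lod(vals)
        assert lod.sd == pytest.approx(np.std(vals, ddof=1))

    def test_sd_distance_from_study_like_null(self):
        # 100 shifts with mean exactly 0.0004, sd ~0.0007, max 0.002:
        # the 0.003 cutoff sits ~3.7 sd above the mean
        null = [0.002] * 5 + [0.0015] * 20 + [0.0] * 75
        lod = sh.calibrate_lod(null)
        assert lod.cutoff == pytest.approx(0.003)
        assert lod.mean == pytest.approx(0.0004)
        assert lod.sd == pytest.approx(0.0007, abs=5e-6)
        assert round(lod.sd_distance, 1) == 3.7

    def test_degenerate_null_is_error(self):
        with pytest.raises(sh.DegenerateNullError, match="manually"):
            sh.calibrate_lod([0.0] * 20)

    def test_small_null_set_warns_and_flags(self):
        with pytest.warns(UserWarning, match="small-n"):
            lod = sh.calibrate_lod([0.001, 0.002, 0.0])
        assert lod.small_n

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(factor=st.floats(min_value=0.5, max_value=5.0), seed=st.integers(0, 20))
    def test_cutoff_linear_in_factor(self, factor, seed):
        shifts = np.random.default_rng(seed).normal(0, 0.001, size=30).tolist()
        a = sh.calibrate_lod(shifts, factor=factor)
        b = sh.calibrate_lod(shifts, factor=2 * factor)
        assert b.cutoff == pytest.approx(2 * a.cutoff)

    def test_report_contains_histogram_and_stats(self):
        lod = sh.calibrate_lod([0.0, 0.001, 0.002] * 5)
        text = lod.report()
        assert "cutoff" in text and "histogram" in text and "0.0030" in text


class TestEnrichmentCalls:
    @pytest.fixture()
    def lod(self):
        return sh.calibrate_lod([0.0, 0.001, 0.002] * 4)  # cutoff 0.003

    def test_boundary_is_inclusive(self, lod):
        assert sh.call_enrichment(0.003, lod)

    def test_below_cutoff_not_enriched(self, lod):
        assert not sh.call_enrichment(0.002, lod)

    def test_negative_shift_not_enriched(self, lod):
        assert not sh.call_enrichment(-0.004, lod)


class TestCladeSummaries:
    def _result(self, otu, enriched):
        peak = sh.PeakCall(1.71, 3, [], True, "peak", 1.71)
        return sh.ShiftResult(otu, "T", 0.004 if enriched else 0.0, peak, peak, "peak", enriched)

    def test_percentages(self):
        tax = gio.TaxonomyMap(
            {f"OTU{i}": ("B", "p", "c", "o", "X" if i < 10 else "Y", "g") for i in range(14)}
        )
        results = [self._result(f"OTU{i}", i != 0 and i < 10) for i in range(14)]
        summaries = {s.clade: s for s in sh.summarize_clades(results, tax, "family")}
        assert summaries["X"].n_otus == 10 and summaries["X"].n_enriched == 9
        assert summaries["X"].percent_enriched == pytest.approx(90.0)
        assert summaries["Y"].percent_enriched == 0.0
        assert summaries["(all)"].n_otus == 14

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(5)
        clades = ["SAR11", "Flavobacteriaceae", "Roseobacter", "MG-II", "SAR86"]
        assign = {f"OTU{i:02d}": clades[rng.integers(len(clades))] for i in range(30)}
        enriched = {o: bool(rng.integers(2)) for o in assign}
        tax = gio.TaxonomyMap({o: ("B", "p", "c", "o", c, "g") for o, c in assign.items()})
        results = [self._result(o, enriched[o]) for o in assign]
        got = {s.clade: (s.n_otus, s.n_enriched) for s in sh.summarize_clades(results, tax, "family")}
        for clade in clades:
            members = [o for o, c in assign.items() if c == clade]
            assert got[clade] == (len(members), sum(enriched[o] for o in members))

    def test_unknown_otus_grouped_unclassified(self):
        tax = gio.TaxonomyMap({})
        summaries = sh.summarize_clades([self._result("OTUx", True)], tax, "family")
        assert summaries[0].clade == "unclassified"
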