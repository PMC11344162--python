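"""Boundary extraction, window metrics, and the rank-sum/FDR/Cliff's-delta layer."""

import numpy as np
import pytest

from tadbound import (
    GenomicInterval,
    PeakRecord,
    SignalTrack,
    TadMap,
    boundary_metrics,
    cliffs_delta,
    compare_groups,
    effect_label,
    extract_boundaries,
    random_boundaries,
)
from tadbound.boundaries import BoundaryRecord, _window
from tests.conftest import make_transcript


def ctcf_peak(start, end, signal=1.0):
    return PeakRecord(GenomicInterval("chr1", start, end), 10.0, 1e-4, signal)


class TestExtractBoundaries:
    def test_shared_coordinate_deduplicated(self):
        tm = TadMap(
            [GenomicInterval("chr1", 500_000, 1_000_000),
             GenomicInterval("chr1", 1_000_000, 1_500_000)],
            {"chr1": 3_000_000},
        )
        recs = extract_boundaries(tm, [], set())
        assert [r.position for r in recs] == [500_000, 1_000_000, 1_500_000]

    def test_dev_tss_in_first_decile_labels_start_boundary(self):
        tm = TadMap([GenomicInterval("chr1", 500_000, 1_500_000)], {"chr1": 3_000_000})
        ts = [make_transcript("dev", 520_000)]
        recs = {r.position: r for r in extract_boundaries(tm, ts, {"dev"})}
        assert recs[500_000].class_label == "developmental"
        assert recs[1_500_000].class_label == "other"

    def test_no_dev_genes_all_other(self, small_bundle):
        recs = extract_boundaries(small_bundle.tad_map, small_bundle.transcripts, set())
        assert all(r.class_label == "other" for r in recs)

    def test_either_side_qualifies_shared_boundary(self):
        tm = TadMap(
            [GenomicInterval("chr1", 500_000, 1_500_000),
             GenomicInterval("chr1", 1_500_000, 2_500_000)],
            {"chr1": 3_000_000},
        )
        # dev gene in the last decile of the first TAD only
        ts = [make_transcript("dev", 1_450_000)]
        recs = {r.position: r for r in extract_boundaries(tm, ts, {"dev"})}
        assert recs[1_500_000].class_label == "developmental"
        strict = {
            r.position: r for r in extract_boundaries(tm, ts, {"dev"}, strict=True)
        }
        assert strict[1_500_000].class_label == "other"

    def test_window_is_100kb(self):
        tm = TadMap([GenomicInterval("chr1", 500_000, 1_500_000)], {"chr1": 3_000_000})
        recs = extract_boundaries(tm, [], set())
        assert all(r.window.width == 100_000 for r in recs)


class TestRandomBoundaries:
    def test_exact_count(self):
        recs = random_boundaries({"chr1": 10_000_000}, n=5000, seed=1)
        assert len(recs) == 5000

    def test_deterministic_under_seed(self):
        a = random_boundaries({"chr1": 10_000_000, "chr2": 5_000_000}, n=100, seed=7)
        b = random_boundaries({"chr1": 10_000_000, "chr2": 5_000_000}, n=100, seed=7)
        assert [(r.chrom, r.position) for r in a] == [(r.chrom, r.position) for r in b]

    def test_margin_respected(self):
        genome = {"chr1": 1_000_000}
        recs = random_boundaries(genome, n=500, seed=3)
        assert all(50_000 <= r.position <= 950_000 for r in recs)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            random_boundaries({"tiny": 90_000}, n=10, seed=0)

    def test_class_label_random(self):
        recs = random_boundaries({"chr1": 10_000_000}, n=10, seed=0)
        assert all(r.class_label == "random" for r in recs)


class TestBoundaryMetrics:
    def _record(self, pos=1_000_000):
        return BoundaryRecord(
            chrom="chr1", position=pos, window=_window("chr1", pos, None), class_label="other"
        )

    def _tracks(self):
        insul = SignalTrack([(GenomicInterval("chr1", 980_000, 1_020_000), -0.7)])
        strength = SignalTrack([(GenomicInterval("chr1", 995_000, 1_005_000), 0.5)])
        return insul, strength

    def test_count_and_aggregate(self):
        rec = self._record()
        insul, strength = self._tracks()
        peaks = [ctcf_peak(990_000, 991_000, 5.0), ctcf_peak(990_500, 991_500, 7.0)]
        boundary_metrics([rec], peaks, insul, strength)
        assert rec.n_ctcf_peaks == 2
        assert rec.ctcf_aggregate_signal == 12.0
        assert rec.insulation_min == -0.7
        assert rec.strength_max == 0.5

    def test_peak_outside_window_ignored(self):
        rec = self._record()
        insul, strength = self._tracks()
        boundary_metrics([rec], [ctcf_peak(2_000_000, 2_001_000)], insul, strength)
        assert rec.n_ctcf_peaks == 0 and rec.ctcf_aggregate_signal == 0.0

    def test_strength_floor_applied_only_when_flagged(self):
        insul = SignalTrack([(GenomicInterval("chr1", 980_000, 1_020_000), -0.7)])
        weak = SignalTrack([(GenomicInterval("chr1", 995_000, 1_005_000), 0.15)])
        rec = self._record()
        boundary_metrics([rec], [], insul, weak, apply_floor=True)
        assert rec.strength_max == 0.0
        rec2 = self._record()
        boundary_metrics([rec2], [], insul, weak, apply_floor=False)
        assert rec2.strength_max == 0.15

    def test_missing_track_error_names_track(self):
        rec = self._record()
        with pytest.raises(ValueError, match="insulation"):
            boundary_metrics([rec], [], None, SignalTrack())
        with pytest.raises(ValueError, match="strength"):
            boundary_metrics([rec], [], SignalTrack(), None)

    def test_locality_outside_window(self):
        """Perturbing data outside the window never changes the record."""
        insul, strength = self._tracks()
        peaks = [ctcf_peak(990_000, 991_000, 5.0)]
        rec_a = self._record()
        boundary_metrics([rec_a], peaks, insul, strength)
        far_peaks = peaks + [ctcf_peak(5_000_000, 5_001_000, 99.0)]
        far_insul = SignalTrack(
            list(insul.segments())
            + [(GenomicInterval("chr1", 6_000_000, 6_100_000), -5.0)]
        )
        rec_b = self._record()
        boundary_metrics([rec_b], far_peaks, far_insul, strength)
        assert (rec_a.n_ctcf_peaks, rec_a.ctcf_aggregate_signal) == (
            rec_b.n_ctcf_peaks,
            rec_b.ctcf_aggregate_signal,
        )
        assert rec_a.insulation_min == rec_b.insulation_min


class TestCliffsDelta:
    def test_identical_groups_zero(self):
        x = [1.0, 2.0, 3.0]
        assert cliffs_delta(x, x) == 0.0
        assert effect_label(0.0) == "negligible"

    def test_fully_separated_is_one(self):
        assert cliffs_delta([10, 11, 12], [1, 2, 3]) == 1.0
        assert effect_label(1.0) == "large"

    def test_sign_convention(self):
        assert cliffs_delta([1, 2, 3], [10, 11, 12]) == -1.0

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(300):
            x = rng.normal(size=rng.integers(2, 50))
            y = rng.normal(size=rng.integers(2, 50))
            brute = np.mean(np.sign(x[:, None] - y[None, :]))
            assert cliffs_delta(x, y) == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize(
        "d,label",
        [(0.1, "negligible"), (0.2, "small"), (0.4, "medium"), (0.6, "large"),
         (-0.5, "large"), (0.147, "small"), (0.474, "large")],
    )
    def test_effect_labels(self, d, label):
        assert effect_label(d) == label


class TestCompareGroups:
    def test_identical_constant_groups(self):
        comps = compare_groups({"m": {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}})
        assert comps[0].p_value == 1.0
        assert comps[0].cliffs_delta == 0.0
        assert comps[0].effect_label == "negligible"

    def test_q_at_least_p(self, rng):
        data = {
            f"m{i}": {g: rng.normal(size=20) for g in ("a", "b", "c")} for i in range(3)
        }
        comps = compare_groups(data)
        assert all(c.q_value >= c.p_value - 1e-12 for c in comps)

    def test_detects_designed_count_shift(self, rng):
        """Power check: 3 extra peaks per developmental boundary at n=200."""
        hits = 0
        for trial in range(20):
            r = np.random.default_rng(trial)
            dev = r.poisson(5, 200) + 3
            other = r.poisson(5, 200)
            comps = compare_groups({"n_ctcf_peaks": {"dev": dev, "other": other}})
            hits += comps[0].q_value <= 0.05
        assert hits >= 18

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"m": {"a": [1.0], "b": [1.0, 2.0]}})
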