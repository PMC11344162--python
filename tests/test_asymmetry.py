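"""Inner/outer window construction, delta statistics, and motif orientation."""

import numpy as np
import pytest

from tadbound import (
    GenomicInterval,
    PeakRecord,
    asymmetry_windows,
    compare_delta_distributions,
    delta_ctcf,
    orientation_contingency,
    peak_orientation,
)
from tadbound.asymmetry import OrientationRecord


def peak_at(mid, signal=1.0, motif=None, motif_q=None, chrom="chr1", half=200):
    return PeakRecord(
        GenomicInterval(chrom, mid - half, mid + half), 10.0, 1e-4, signal, motif, motif_q
    )


class TestAsymmetryWindows:
    def test_left_boundary_side_and_clipping(self):
        tad = GenomicInterval("chr1", 0, 200_000)
        win = asymmetry_windows(5_000, tad, chrom_length=1_000_000)
        assert win.nearest_side == "start"
        assert win.outer == GenomicInterval("chr1", 0, 5_000)  # clipped at chrom start
        assert win.inner == GenomicInterval("chr1", 5_000, 105_000)

    def test_right_boundary_side(self):
        tad = GenomicInterval("chr1", 0, 160_000)
        win = asymmetry_windows(150_000, tad, chrom_length=1_000_000)
        assert win.nearest_side == "end"
        assert win.outer == GenomicInterval("chr1", 150_000, 250_000)
        assert win.inner == GenomicInterval("chr1", 50_000, 150_000)

    def test_mirrored_locus_swaps_roles(self):
        M = 1_000_000
        tad = GenomicInterval("chr1", 100_000, 300_000)
        tss = 110_000
        win = asymmetry_windows(tss, tad, M)
        tad_m = GenomicInterval("chr1", M - 300_000, M - 100_000)
        win_m = asymmetry_windows(M - 1 - tss, tad_m, M)
        assert win.nearest_side == "start" and win_m.nearest_side == "end"
        assert win.outer.width == win_m.outer.width
        assert win.inner.width == win_m.inner.width

    def test_non_bin1_gene_rejected(self):
        tad = GenomicInterval("chr1", 0, 200_000)
        with pytest.raises(ValueError, match="bin-1"):
            asymmetry_windows(100_000, tad, 1_000_000)


class TestDeltaCtcf:
    def test_counts_by_midpoint(self):
        tad = GenomicInterval("chr1", 0, 1_000_000)
        tss = 20_000  # bin 1, nearest = start, outer = left, inner = right
        peaks = [peak_at(50_000), peak_at(10_000), peak_at(5_000)]
        rec = delta_ctcf("g", tss, tad, peaks, 2_000_000)
        assert (rec.n_inner, rec.n_outer) == (1, 2)
        assert rec.delta_peaks == -1

    def test_signal_sums(self):
        tad = GenomicInterval("chr1", 0, 1_000_000)
        tss = 20_000
        peaks = [peak_at(50_000, 4.0), peak_at(60_000, 6.0), peak_at(10_000, 3.0)]
        rec = delta_ctcf("g", tss, tad, peaks, 2_000_000)
        assert rec.signal_inner == 10.0 and rec.signal_outer == 3.0
        assert rec.delta_signal == 7.0

    def test_midpoint_on_tss_counts_inner(self):
        # inner window lies left of the TSS here (gene near the TAD end)
        tad = GenomicInterval("chr1", 0, 1_000_000)
        tss = 980_000
        rec = delta_ctcf("g", tss, tad, [peak_at(tss)], 2_000_000)
        assert (rec.n_inner, rec.n_outer) == (1, 0)

    def test_reflection_about_tss_flips_delta_exactly(self, rng):
        """Reflecting the peak set about the TSS swaps the half-window contents.

        The inner and outer windows are the two 100 kb half-windows around
        the TSS, so the reflection m -> 2*TSS - m maps one onto the other
        and delta_peaks / delta_signal flip sign exactly.
        """
        M = 2_000_000
        for _ in range(200):
            start = int(rng.integers(100_000, 500_000))
            L = int(rng.integers(300_000, 900_000))
            tad = GenomicInterval("chr1", start, start + L)
            off = int(rng.integers(1000, max(1001, L // 10)))
            tss = start + off if rng.random() < 0.5 else start + L - 1 - off
            mids = tss + rng.integers(-98_000, 98_000, size=rng.integers(1, 8))
            # exclude the TSS base itself: its inner-window tie-break is a
            # deliberate convention outside the reflection symmetry
            mids = [int(m) for m in mids if 500 < m < M - 500 and m != tss]
            if not mids:
                continue
            peaks = [peak_at(m, signal=float(i + 1)) for i, m in enumerate(mids)]
            rec = delta_ctcf("g", tss, tad, peaks, M)
            peaks_r = [
                peak_at(2 * tss - m, signal=float(i + 1)) for i, m in enumerate(mids)
            ]
            rec_r = delta_ctcf("g", tss, tad, peaks_r, M)
            assert rec_r.delta_peaks == -rec.delta_peaks
            assert rec_r.delta_signal == pytest.approx(-rec.delta_signal)

    def test_full_locus_mirror_preserves_delta(self):
        """Mirroring TAD, gene and peaks together keeps delta unchanged:
        the boundary-skew of the configuration is a reflection invariant."""
        M = 2_000_000
        tad = GenomicInterval("chr1", 200_000, 800_000)
        tss = 230_000
        mids = [250_000, 260_000, 210_000]
        rec = delta_ctcf("g", tss, tad, [peak_at(m) for m in mids], M)
        tad_m = GenomicInterval("chr1", M - 800_000, M - 200_000)
        rec_m = delta_ctcf(
            "g", M - 1 - tss, tad_m, [peak_at(M - m) for m in mids], M
        )
        assert rec_m.delta_peaks == rec.delta_peaks

    def test_matches_brute_force_oracle(self, rng):
        M = 2_000_000
        for _ in range(1000):
            start = int(rng.integers(0, 500_000))
            L = int(rng.integers(150_000, 800_000))
            tad = GenomicInterval("chr1", start, start + L)
            off = int(rng.integers(0, max(1, L // 10)))
            tss = start + off if rng.random() < 0.5 else start + L - 1 - off
            mids = [
                int(m)
                for m in tss + rng.integers(-120_000, 120_000, size=rng.integers(0, 10))
                if 500 < m < M - 500
            ]
            peaks = [peak_at(m, signal=float(i + 1)) for i, m in enumerate(mids)]
            rec = delta_ctcf("g", tss, tad, peaks, M)
            # brute force: classify each midpoint against the half-windows
            f = (tss - start) / L
            if f < 0.5:
                inner_lo, inner_hi = tss, min(M, tss + 100_000)
                outer_lo, outer_hi = max(0, tss - 100_000), tss
            else:
                inner_lo, inner_hi = max(0, tss - 100_000), tss
                outer_lo, outer_hi = tss, min(M, tss + 100_000)
            n_in = n_out = 0
            s_in = s_out = 0.0
            for i, m in enumerate(mids):
                if m == tss:
                    n_in += 1
                    s_in += i + 1
                elif inner_lo <= m < inner_hi:
                    n_in += 1
                    s_in += i + 1
                elif outer_lo <= m < outer_hi:
                    n_out += 1
                    s_out += i + 1
            assert (rec.n_inner, rec.n_outer) == (n_in, n_out)
            assert (rec.signal_inner, rec.signal_outer) == (s_in, s_out)


class TestPeakOrientation:
    def test_plus_motif_left_of_center_is_inward(self):
        rec = peak_orientation(peak_at(10_000, motif="+", motif_q=0.01), 100_000)
        assert rec.orientation == +1

    def test_plus_motif_right_of_center_is_outward(self):
        rec = peak_orientation(peak_at(190_000, motif="+", motif_q=0.01), 100_000)
        assert rec.orientation == -1

    def test_minus_motif_mirrors(self):
        assert peak_orientation(peak_at(10_000, motif="-", motif_q=0.01), 100_000).orientation == -1
        assert peak_orientation(peak_at(190_000, motif="-", motif_q=0.01), 100_000).orientation == +1

    def test_lowest_q_motif_wins(self):
        rec = peak_orientation(
            peak_at(10_000), 100_000, candidate_motifs=[("-", 0.01), ("+", 0.2)]
        )
        assert rec.orientation == -1  # '-' left of center -> outward

    def test_no_motif_is_none(self):
        assert peak_orientation(peak_at(10_000), 100_000).orientation is None

    def test_midpoint_at_center_flagged(self):
        rec = peak_orientation(peak_at(100_000, motif="+", motif_q=0.01), 100_000)
        assert rec.orientation is None and rec.flagged

    def test_counts_partition_window(self, rng):
        """#inward + #outward + #none equals the number of peaks."""
        center = 500_000
        n = 200
        records = []
        for i in range(n):
            has_motif = rng.random() < 0.8
            rec = peak_orientation(
                peak_at(
                    int(rng.integers(1000, 999_000)),
                    motif="+" if has_motif and rng.random() < 0.5 else ("-" if has_motif else None),
                    motif_q=0.01 if has_motif else None,
                ),
                center,
            )
            records.append(rec)
        n_in = sum(r.orientation == 1 for r in records)
        n_out = sum(r.orientation == -1 for r in records)
        n_none = sum(r.orientation is None for r in records)
        assert n_in + n_out + n_none == n


class TestOrientationContingency:
    def test_identical_fractions_zero_v(self):
        records = (
            [OrientationRecord("inner", +1)] * 30
            + [OrientationRecord("inner", -1)] * 20
            + [OrientationRecord("outer", +1)] * 60
            + [OrientationRecord("outer", -1)] * 40
        )
        _, p, v = orientation_contingency(records)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association_v_one(self):
        records = [OrientationRecord("inner", +1)] * 50 + [
            OrientationRecord("outer", -1)
        ] * 50
        _, _, v = orientation_contingency(records)
        assert v == pytest.approx(1.0)

    def test_closed_form_chi2_and_v(self):
        table = np.array([[60, 40], [45, 55]])
        records = (
            [OrientationRecord("inner", +1)] * 60
            + [OrientationRecord("inner", -1)] * 40
            + [OrientationRecord("outer", +1)] * 45
            + [OrientationRecord("outer", -1)] * 55
        )
        # direct Pearson formula
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - exp) ** 2 / exp).sum()
        got_table, p, v = orientation_contingency(records)
        assert np.array_equal(got_table, table)
        assert v == pytest.approx(np.sqrt(chi2 / n))

    def test_zero_margin_rejected(self):
        records = [OrientationRecord("inner", +1)] * 10 + [
            OrientationRecord("outer", +1)
        ] * 10
        with pytest.raises(ValueError, match="zero margin"):
            orientation_contingency(records)


class TestCompareDeltaDistributions:
    def test_single_category_no_tests(self):
        res = compare_delta_distributions({"developmental": [-1, -2, 0, 1]})
        assert res.comparisons == []
        assert res.negative_fraction["developmental"] == 0.5
        assert res.cdfs["developmental"].size == 4

    def test_negative_fraction_definition(self):
        res = compare_delta_distributions({"a": [-3, -1, 0, 0, 2], "b": [1, 2, 3]})
        assert res.negative_fraction["a"] == pytest.approx(0.4)
        assert res.negative_fraction["b"] == 0.0
        assert len(res.comparisons) == 1
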