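"""TAD density tertiles, Fisher enrichment, and the intra-TAD decile binning."""

import numpy as np
import pytest
from scipy import stats

from tadbound import (
    GeneCategorySet,
    GenomicInterval,
    TadMap,
    assign_bins,
    bin1_boundary_distance,
    bin_distribution,
    density_tertiles,
    gene_level_assignments,
    ld_enrichment,
    tad_density,
)
from tadbound.geometry import TadDensityRecord, _bin_of
from tests.conftest import make_transcript


class TestTadDensity:
    def test_density_is_count_over_length(self, simple_tad_map):
        ts = [make_transcript(f"g{i}", 10_000 + i * 15_000) for i in range(5)]
        recs = tad_density(simple_tad_map, ts)
        assert recs[0].n_tss == 5
        assert recs[0].density == pytest.approx(5e-5)

    def test_tss_at_tad_end_counts_toward_next(self, simple_tad_map):
        recs = tad_density(simple_tad_map, [make_transcript("g", 100_000)])
        assert recs[0].n_tss == 0 and recs[1].n_tss == 1

    def test_empty_tad_zero_density(self, simple_tad_map):
        recs = tad_density(simple_tad_map, [])
        assert all(r.density == 0 for r in recs)


def density_records(densities):
    return [
        TadDensityRecord(GenomicInterval("chr1", i * 1000, (i + 1) * 1000), 0, d)
        for i, d in enumerate(densities)
    ]


class TestDensityTertiles:
    def test_even_split_lowest_is_ld(self):
        recs = density_tertiles(density_records([9, 1, 5, 8, 2, 6, 7, 3, 4]))
        by_density = sorted(recs, key=lambda r: r.density)
        assert [r.tertile for r in by_density] == ["LD"] * 3 + ["MD"] * 3 + ["HD"] * 3

    def test_remainder_goes_to_lower_tertiles_first(self):
        recs = density_tertiles(density_records(range(10)))
        counts = {t: sum(r.tertile == t for r in recs) for t in ("LD", "MD", "HD")}
        assert counts == {"LD": 4, "MD": 3, "HD": 3}

    def test_ties_broken_by_genomic_order(self):
        recs = density_tertiles(density_records([1.0] * 6))
        assert [r.tertile for r in recs] == ["LD", "LD", "MD", "MD", "HD", "HD"]

    def test_too_few_tads_rejected(self):
        with pytest.raises(ValueError):
            density_tertiles(density_records([1, 2]))


class TestLdEnrichment:
    def _setup(self, n_ld_cat, n_ld_other, n_rest_cat, n_rest_other):
        """Two TADs: a designated low-density one and a gene-rich one."""
        genome = {"chr1": 10_000_000}
        tm = TadMap(
            [GenomicInterval("chr1", 0, 2_000_000), GenomicInterval("chr1", 2_000_000, 4_000_000),
             GenomicInterval("chr1", 4_000_000, 6_000_000)],
            genome,
        )
        ts, cat = [], set()
        k = 0
        counters = {0: 0, 2_000_000: 0, 4_000_000: 0}
        rest = [2_000_000, 4_000_000]

        def add(in_cat, tad_start):
            nonlocal k
            gid = f"g{k}"
            ts.append(
                make_transcript(gid, tad_start + 600_000 + counters[tad_start] * 1200)
            )
            counters[tad_start] += 1
            if in_cat:
                cat.add(gid)
            k += 1

        for _ in range(n_ld_cat):
            add(True, 0)
        for _ in range(n_ld_other):
            add(False, 0)
        # split the remaining genes over the two gene-rich TADs so the first
        # TAD is the unique low-density tertile member holding genes
        for j in range(n_rest_cat):
            add(True, rest[j % 2])
        for j in range(n_rest_other):
            add(False, rest[j % 2])
        return tm, ts, cat

    def test_closed_form_odds_ratio(self):
        tm, ts, cat = self._setup(30, 100, 70, 800)
        recs = density_tertiles(tad_density(tm, ts))
        res = ld_enrichment(cat, recs, ts, tm)
        assert res.odds_ratio == pytest.approx((30 * 800) / (70 * 100), rel=1e-12)
        expected_p = stats.fisher_exact([[30, 70], [100, 800]], alternative="greater")[1]
        assert res.p_value == pytest.approx(expected_p)

    def test_proportional_distribution_is_null(self):
        tm, ts, cat = self._setup(10, 100, 40, 400)
        recs = density_tertiles(tad_density(tm, ts))
        res = ld_enrichment(cat, recs, ts, tm)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.5

    def test_empty_category_rejected(self, simple_tad_map):
        recs = density_tertiles(tad_density(simple_tad_map, []))
        with pytest.raises(ValueError):
            ld_enrichment(set(), recs, [], simple_tad_map)


def brute_force_bin(pos, start, end):
    """Oracle: explicit decile intervals paired by distance from the boundary.

    Valid for TAD lengths divisible by ten, where the decile edges are
    integers and the pairing (outermost pair = bin 1, central pair = bin 5)
    is unambiguous.
    """
    L = end - start
    assert L % 10 == 0
    edges = [start + k * (L // 10) for k in range(11)]
    decile = next(k for k in range(10) if edges[k] <= pos < edges[k + 1])
    b = min(decile, 9 - decile) + 1
    return b, min(pos - start, end - 1 - pos)


class TestAssignBins:
    @pytest.mark.parametrize(
        "tss,expected_bin,expected_dist",
        [
            (5_000, 1, 5_000),  # first decile
            (50_000, 5, 49_999),  # exact center capped at bin 5
            (99_999, 1, 0),  # mirror of position 0
            (0, 1, 0),  # TAD start belongs to the TAD
            (10_000, 2, 10_000),  # second decile
            (49_999, 5, 49_999),
        ],
    )
    def test_examples_in_single_tad(self, tss, expected_bin, expected_dist):
        tm = TadMap([GenomicInterval("chr1", 0, 100_000)], {"chr1": 1_000_000})
        asn = assign_bins(tm, [make_transcript("g", tss)])[0]
        assert (asn.bin, asn.distance_to_boundary) == (expected_bin, expected_dist)

    def test_intertad_tss_is_bin_zero(self, simple_tad_map):
        asn = assign_bins(simple_tad_map, [make_transcript("g", 450_000)])[0]
        assert asn.bin == 0 and asn.tad_index is None and asn.distance_to_boundary is None

    def test_mirror_invariance(self, rng):
        length = 1_000_000
        tm = TadMap([GenomicInterval("chr1", 100_000, 900_000)], {"chr1": length})
        for _ in range(200):
            pos = int(rng.integers(100_000, 900_000))
            mirrored = length - 1 - pos
            b1 = assign_bins(tm, [make_transcript("g", pos)])[0]
            tm2 = TadMap([GenomicInterval("chr1", 100_000, 900_000)], {"chr1": length})
            b2 = assign_bins(tm2, [make_transcript("g", mirrored)])[0]
            assert b1.bin == b2.bin
            assert b1.distance_to_boundary == b2.distance_to_boundary

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            start = int(rng.integers(0, 1_000))
            L = 10 * int(rng.integers(10, 5_000))
            tm = TadMap([GenomicInterval("chr1", start, start + L)], {"chr1": 100_000})
            pos = int(rng.integers(start, start + L))
            asn = assign_bins(tm, [make_transcript("g", pos, length=50)])[0]
            b, d = brute_force_bin(pos, start, start + L)
            assert (asn.bin, asn.distance_to_boundary) == (b, d)


class TestBinDistribution:
    def test_all_in_bin1(self):
        tm = TadMap([GenomicInterval("chr1", 0, 100_000)], {"chr1": 1_000_000})
        ts = [make_transcript(f"g{i}", 1000 + i * 100, length=50) for i in range(10)]
        cats = GeneCategorySet(all_genes={t.gene_id for t in ts})
        asn = assign_bins(tm, ts)
        dist = bin_distribution(asn, cats)
        assert list(dist.loc["all"]) == [0, 100, 0, 0, 0, 0]

    def test_rows_sum_to_100(self, small_bundle):
        b = small_bundle
        dist = bin_distribution(assign_bins(b.tad_map, b.transcripts), b.categories)
        assert np.allclose(dist.sum(axis=1), 100.0)

    def test_uniform_placement_near_20_percent_per_bin(self, rng):
        tm = TadMap([GenomicInterval("chr1", 0, 1_000_000)], {"chr1": 2_000_000})
        ts = [
            make_transcript(f"g{i}", int(rng.integers(0, 1_000_000)), length=50)
            for i in range(5000)
        ]
        cats = GeneCategorySet(all_genes={t.gene_id for t in ts})
        dist = bin_distribution(assign_bins(tm, ts), cats)
        assert dist.loc["all", 0] == 0.0
        for b in range(1, 6):
            assert dist.loc["all", b] == pytest.approx(20.0, abs=2.5)

    def test_empty_category_rejected(self, simple_tad_map):
        cats = GeneCategorySet(developmental={"nope"}, all_genes={"nope"})
        with pytest.raises(ValueError):
            bin_distribution([], cats)


class TestBin1BoundaryDistance:
    def test_distances_returned_for_bin1_only(self):
        tm = TadMap([GenomicInterval("chr1", 0, 100_000)], {"chr1": 1_000_000})
        ts = [make_transcript("near", 1, length=50), make_transcript("far", 50_000, length=50)]
        cats = GeneCategorySet(all_genes={"near", "far"})
        d = bin1_boundary_distance(assign_bins(tm, ts), cats)
        assert list(d["all"]) == [1]

    def test_last_base_distance_zero(self):
        tm = TadMap([GenomicInterval("chr1", 0, 100_000)], {"chr1": 1_000_000})
        d = bin1_boundary_distance(
            assign_bins(tm, [make_transcript("g", 99_999, length=50)]),
            GeneCategorySet(all_genes={"g"}),
        )
        assert list(d["all"]) == [0]

    def test_category_without_bin1_genes_is_empty_not_error(self):
        tm = TadMap([GenomicInterval("chr1", 0, 100_000)], {"chr1": 1_000_000})
        cats = GeneCategorySet(developmental={"mid"}, all_genes={"mid"})
        d = bin1_boundary_distance(
            assign_bins(tm, [make_transcript("mid", 50_000, length=50)]), cats
        )
        assert d["developmental"].size == 0


class TestGeneLevelAssignments:
    def test_representative_is_nearest_boundary_transcript(self):
        tm = TadMap([GenomicInterval("chr1", 0, 100_000)], {"chr1": 1_000_000})
        from tadbound import TranscriptRecord

        t1 = TranscriptRecord("g", "g.far", GenomicInterval("chr1", 40_000, 50_000), "+")
        t2 = TranscriptRecord("g", "g.near", GenomicInterval("chr1", 3_000, 9_000), "+")
        rep = gene_level_assignments(assign_bins(tm, [t1, t2]))
        assert rep["g"].transcript_id == "g.near"
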