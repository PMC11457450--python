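"""Window pooling/merging, hexamer search, density mode, rank-bin distances."""

import numpy as np
import pytest

import apakit
from apakit.clip import (
    FlankingDistances,
    density_mode,
    extract_context,
    find_flanking_pas,
    pooled_signed_distances,
)
from apakit.io_formats import BedRecord, GenomicInterval
from apakit.synthetic import PAS_HEXAMERS, reverse_complement


def _window(contig, start, end, counts, strand="+", name="w"):
    return BedRecord(GenomicInterval(contig, start, end, strand), name=name,
                     score=float(sum(counts)), extra=tuple(float(c) for c in counts))


class TestPoolAndFilter:
    def test_threshold(self):
        wins = [
            _window("c", 0, 50, [10, 10, 10, 10], name="low"),     # pooled 40: dropped
            _window("c", 100, 150, [20, 20, 20, 20], name="high"), # pooled 80: kept
        ]
        sites = apakit.pool_and_filter_windows(wins, min_reads=50)
        assert [s.gene for s in sites] == ["high"]

    def test_overlapping_windows_merge_to_union(self):
        wins = [
            _window("c", 100, 150, [30, 30, 0, 0]),
            _window("c", 149, 200, [30, 30, 0, 0]),
        ]
        (site,) = apakit.pool_and_filter_windows(wins, min_reads=50)
        assert (site.interval.start, site.interval.end) == (100, 200)
        assert site.center == (100 + 200 - 1) // 2

    def test_different_strands_not_merged(self):
        wins = [
            _window("c", 100, 150, [60, 0, 0, 0], strand="+"),
            _window("c", 120, 180, [60, 0, 0, 0], strand="-"),
        ]
        assert len(apakit.pool_and_filter_windows(wins)) == 2

    def test_ragged_replicates_rejected(self):
        wins = [_window("c", 0, 50, [60, 0, 0, 0]), _window("c", 100, 150, [60, 0])]
        with pytest.raises(ValueError, match="ragged"):
            apakit.pool_and_filter_windows(wins)

    def test_pool_then_filter_equals_filter_on_pooled_column(self):
        rng = np.random.default_rng(0)
        wins = [
            _window("c", 1000 * i, 1000 * i + 51, rng.poisson(15, size=4), name=f"w{i}")
            for i in range(100)
        ]
        sites = apakit.pool_and_filter_windows(wins, min_reads=50)
        expected = [w.name for w in wins if sum(w.extra) >= 50]
        assert [s.gene for s in sites] == expected


class TestFindFlankingPas:
    def test_downstream_only(self):
        ctx = "T" * 500 + "C" + "T" * 61 + "AATAAA" + "T" * 433
        res = find_flanking_pas(ctx, center_index=500)
        assert res == FlankingDistances(upstream=None, downstream=62, truncated=False)

    def test_both_directions(self):
        ctx = "G" * 1001
        ctx = ctx[: 500 - 30] + "ATTAAA" + ctx[500 - 24: 600] + "AATAAA" + ctx[606:]
        res = find_flanking_pas(ctx, center_index=500)
        assert (res.upstream, res.downstream) == (-30, +100)

    def test_truncated_context_flagged(self):
        ctx = "G" * 50 + "AATAAA" + "G" * 50
        res = find_flanking_pas(ctx, center_index=40)
        assert res.truncated and res.downstream == 10

    def test_matches_brute_force_enumeration(self):
        """Nearest up/downstream hexamer agrees with a full scan, 1000 contexts."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(30, 300))
            ctx = "".join(rng.choice(list("ACGT"), size=n, p=[0.4, 0.1, 0.1, 0.4]))
            center = int(rng.integers(0, n))
            res = find_flanking_pas(ctx, center_index=center, max_distance=100)
            offsets = [
                i - center
                for i in range(n - 5)
                if ctx[i:i + 6] in PAS_HEXAMERS
            ]
            ups = [o for o in offsets if -100 <= o < 0]
            downs = [o for o in offsets if 0 <= o <= 100]
            assert res.upstream == (max(ups) if ups else None)
            assert res.downstream == (min(downs) if downs else None)

    def test_strand_symmetry_via_extract_context(self):
        """A minus-strand site over the reverse-complemented genome gives the
        same transcript-orientation distances as its plus-strand twin."""
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=1200))
        center = 600
        ctx_plus, idx_plus = extract_context(seq, center, "+", radius=400)
        res_plus = find_flanking_pas(ctx_plus, idx_plus, max_distance=400)
        rc = reverse_complement(seq)
        center_rc = len(seq) - 1 - center
        ctx_minus, idx_minus = extract_context(rc, center_rc, "-", radius=400)
        res_minus = find_flanking_pas(ctx_minus, idx_minus, max_distance=400)
        assert (res_plus.upstream, res_plus.downstream) == (res_minus.upstream, res_minus.downstream)


class TestDensityMode:
    def test_degenerate_point_mass(self):
        prof = density_mode([62.0] * 25)
        assert prof.mode == 62.0

    def test_symmetric_tie_broken_to_smaller_offset(self):
        prof = density_mode([-50.0] * 100 + [50.0] * 100)
        assert prof.mode == -50.0

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            density_mode([1.0] * 19)

    def test_recovers_planted_normal_mode(self):
        rng = np.random.default_rng(3)
        d = rng.normal(62, 10, size=500)
        prof = density_mode(d)
        assert abs(prof.mode - 62) <= 5

    def test_mode_within_5bp_over_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            prof = density_mode(rng.normal(62, 10, size=500))
            if abs(prof.mode - 62) <= 5:
                hits += 1
        assert hits >= 19


class TestBinnedDistances:
    def test_arithmetic_example(self):
        sites = [apakit.BindingSite(GenomicInterval("c", 89, 92, "+"), gene="g")]
        assert sites[0].center == 90
        pas = [
            apakit.PolyASiteRecord(GenomicInterval("c", 100, 106, "+"), "g", "proximal"),
            apakit.PolyASiteRecord(GenomicInterval("c", 200, 206, "+"), "g", "intermediate"),
            apakit.PolyASiteRecord(GenomicInterval("c", 300, 306, "+"), "g", "distal"),
        ]
        res = apakit.distances_to_binned_sites(sites, pas)
        assert res.distances["proximal"].tolist() == [10]
        assert res.distances["intermediate"].tolist() == [110]
        assert res.distances["distal"].tolist() == [210]

    def test_minus_strand_proximal_is_highest_coordinate(self):
        recs = [
            BedRecord(GenomicInterval("c", 100, 106, "-"), name="g", score=0),
            BedRecord(GenomicInterval("c", 300, 306, "-"), name="g", score=0),
        ]
        binned, n_excl = apakit.assign_rank_bins(recs)
        by_start = {r.interval.start: r.rank_bin for r in binned}
        assert by_start[300] == "proximal" and by_start[100] == "distal"
        assert n_excl == 0

    def test_single_site_genes_excluded(self):
        recs = [BedRecord(GenomicInterval("c", 10, 16, "+"), name="lonely", score=0)]
        binned, n_excl = apakit.assign_rank_bins(recs)
        assert binned == [] and n_excl == 1

    def test_planted_upstream_binding_orders_bins(self):
        """Binding planted near proximal sites: median distance grows with rank."""
        rng = np.random.default_rng(4)
        sites, pas = [], []
        for i in range(200):
            g = f"g{i}"
            positions = sorted(rng.choice(np.arange(200, 3000, 40), size=3, replace=False))
            for p, b in zip(positions, ("proximal", "intermediate", "distal")):
                pas.append(apakit.PolyASiteRecord(GenomicInterval("c", p, p + 6, "+"), g, b))
            c = positions[0] - 40
            sites.append(apakit.BindingSite(GenomicInterval("c", c - 25, c + 26, "+"), gene=g))
        res = apakit.distances_to_binned_sites(sites, pas)
        assert res.medians["proximal"] < res.medians["intermediate"] < res.medians["distal"]
        assert res.pairwise_p.loc["proximal", "distal"] < 0.01

    def test_no_gene_overlap_rejected(self):
        sites = [apakit.BindingSite(GenomicInterval("c", 0, 10, "+"), gene="a")]
        pas = [apakit.PolyASiteRecord(GenomicInterval("c", 50, 56, "+"), "b", "proximal")]
        with pytest.raises(ValueError, match="no binding site"):
            apakit.distances_to_binned_sites(sites, pas)


def test_pooled_signed_distances_nearest_only():
    import pandas as pd

    table = pd.DataFrame(
        {"upstream": [-30, None], "downstream": [100, 62],
         "gene": ["a", "b"], "contig": ["a", "b"], "center": [0, 0],
         "strand": ["+", "+"], "truncated": [False, False]}
    )
    both = pooled_signed_distances(table)
    assert sorted(both.tolist()) == [-30.0, 62.0, 100.0]
    nearest = pooled_signed_distances(table, nearest_only=True)
    assert sorted(nearest.tolist()) == [-30.0, 62.0]
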