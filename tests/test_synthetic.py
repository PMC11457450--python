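"""Generators: determinism, truth-consistency, and planted structure."""

import numpy as np
import pandas as pd
import pytest

import apakit
from apakit.motifs import scan_sequence
from apakit.synthetic import PAS_HEXAMERS, _scrub_hexamers, reverse_complement


class TestDeterminism:
    def test_cohort_identical_across_runs(self):
        cfg = apakit.CohortSimConfig(n_samples=30, n_genes=50, seed=5)
        e1, u1, t1 = apakit.simulate_cohort(cfg)
        e2, u2, t2 = apakit.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(e1.data, e2.data)
        pd.testing.assert_frame_equal(u1.data, u2.data)
        assert t1.regulators == t2.regulators

    def test_clip_identical_across_runs(self):
        a = apakit.simulate_clip_dataset(n_sites=10, seed=9)
        b = apakit.simulate_clip_dataset(n_sites=10, seed=9)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_sequences_identical_across_runs(self):
        genes = [f"g{i}" for i in range(20)]
        s1, _ = apakit.simulate_utr_sequences(genes, genes[:5], seed=3)
        s2, _ = apakit.simulate_utr_sequences(genes, genes[:5], seed=3)
        assert s1 == s2


class TestCohort:
    def test_truth_consistent_with_outputs(self):
        cfg = apakit.CohortSimConfig(n_samples=30, n_genes=100, seed=1)
        expr, utr, truth = apakit.simulate_cohort(cfg)
        apakit.validate_truth(truth, matrices=[expr, utr])
        assert set(truth.regulators) <= set(expr.genes)
        assert sorted(truth.regulators.values()).count(1) == cfg.n_regulators_pos

    def test_expression_is_positive_tpm(self):
        cfg = apakit.CohortSimConfig(n_samples=20, n_genes=50, seed=2)
        expr, _, _ = apakit.simulate_cohort(cfg)
        assert (expr.data.to_numpy() > 0).all()

    def test_decoupled_null_correlations(self):
        cfg = apakit.CohortSimConfig(n_samples=150, n_genes=300, decoupled=True, seed=3)
        expr, utr, truth = apakit.simulate_cohort(cfg)
        res = apakit.screen_cohort(expr, apakit.median_utr(utr)).records.set_index("gene")
        assert res.loc[list(truth.regulators), "r"].abs().max() < 0.3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            apakit.CohortSimConfig(n_samples=0)
        with pytest.raises(ValueError):
            apakit.CohortSimConfig(noise_sd_utr=0.0)


class TestMutationCohort:
    def test_lof_samples_carry_qualifying_records(self):
        utr, maf, truth = apakit.simulate_mutation_cohort(
            n_samples=40, lof_fraction=0.4, target_genes=["T1", "T2"], seed=4
        )
        by_sample = {}
        for r in maf:
            by_sample.setdefault(r.sample_barcode, []).append(r.variant_classification)
        for s in truth.lof_samples:
            assert any(c in apakit.LOF_CLASSES for c in by_sample[s])
        for s, classes in by_sample.items():
            if s not in truth.lof_samples:
                assert set(classes) == {"Missense_Mutation"}

    def test_missense_only_sample_is_control(self):
        utr, maf, truth = apakit.simulate_mutation_cohort(
            n_samples=60, lof_fraction=0.3, target_genes=["T1"], seed=5
        )
        groups = apakit.stratify_by_mutation(maf, roster=utr.samples)
        assert set(groups.samples("condition")) == set(truth.lof_samples)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="target_genes"):
            apakit.simulate_mutation_cohort(target_genes=[])

    def test_null_delta_yields_no_bh_significance(self):
        utr, maf, truth = apakit.simulate_mutation_cohort(
            n_samples=100, lof_fraction=0.5, target_genes=["T1"], delta=0.0,
            n_genes=400, seed=6,
        )
        groups = apakit.stratify_by_mutation(maf, roster=utr.samples)
        out = apakit.test_differential_apa(utr, groups)
        raw_pos = (out["p"] < 0.05).mean()
        assert raw_pos == pytest.approx(0.05, abs=0.03)
        assert (out["class"] != "unchanged").sum() <= 2


class TestUtrSequences:
    def test_bearing_genes_have_a_hit_at_recorded_position(self):
        genes = [f"g{i}" for i in range(30)]
        seqs, truth = apakit.simulate_utr_sequences(genes, genes[:10], seed=7)
        for g in truth.motif_genes:
            (pos, word) = truth.motif_plants[g][0]
            assert seqs[g][pos:pos + len(word)] == word

    def test_gc_zero_background_is_at_only(self):
        genes = ["a", "b"]
        seqs, truth = apakit.simulate_utr_sequences(genes, [], gc=0.0, length=300, seed=8)
        assert set("".join(seqs.values())) <= set("AT")

    def test_background_presence_matches_monte_carlo(self):
        """Non-bearing presence fraction matches an independent Monte-Carlo
        estimate of the background hit probability at this length/GC."""
        genes = [f"g{i}" for i in range(1500)]
        seqs, _ = apakit.simulate_utr_sequences(genes, [], length=300, gc=0.5, seed=9)
        frac = np.mean([
            any(scan_sequence(s, m) for m in apakit.TOP_ENRICHED_MOTIFS)
            for s in seqs.values()
        ])
        # independent oracle: fresh uniform sequences scanned by brute force
        rng = np.random.default_rng(10)
        hits = 0
        reps = 1500
        for _ in range(reps):
            s = "".join(rng.choice(list("ACGT"), size=300))
            if any(scan_sequence(s, m) for m in apakit.TOP_ENRICHED_MOTIFS):
                hits += 1
        mc = hits / reps
        se = np.sqrt(mc * (1 - mc) / reps) + np.sqrt(frac * (1 - frac) / len(genes))
        assert frac == pytest.approx(mc, abs=4 * se)


class TestRegionCounts:
    def test_f_one_red_near_zero(self):
        f = pd.DataFrame(np.ones((500, 1)), index=[f"g{i}" for i in range(500)], columns=["s"])
        counts, _ = apakit.simulate_region_counts(f, depth=200, seed=11)
        red = apakit.quantify_cohort(counts).data["s"]
        assert abs(red.mean()) < 0.1

    def test_fourfold_fraction_shifts_red_by_two(self):
        idx = [f"g{i}" for i in range(1000)]
        f1 = pd.DataFrame(np.ones((1000, 1)), index=idx, columns=["s"])
        f4 = pd.DataFrame(np.full((1000, 1), 4.0), index=idx, columns=["s"])
        c1, _ = apakit.simulate_region_counts(f1, depth=200, seed=12)
        c4, _ = apakit.simulate_region_counts(f4, depth=200, seed=13)
        r1 = apakit.quantify_cohort(c1).data["s"].mean()
        r4 = apakit.quantify_cohort(c4).data["s"].mean()
        assert r4 - r1 == pytest.approx(2.0, abs=0.1)


class TestClipDataset:
    def test_zero_jitter_distances_exact(self):
        windows, seqs, pas, truth = apakit.simulate_clip_dataset(
            n_sites=40, d_true=62, jitter_sd=0.0, n_noise_windows=0, seed=14
        )
        sites = apakit.pool_and_filter_windows(windows)
        table = apakit.flanking_distances_for_sites(sites, seqs)
        assert (table["downstream"] == 62).all()

    def test_strand_symmetry_of_signed_distances(self):
        windows, seqs, pas, truth = apakit.simulate_clip_dataset(
            n_sites=60, d_true=62, jitter_sd=0.0, n_noise_windows=0, seed=15
        )
        sites = apakit.pool_and_filter_windows(windows)
        table = apakit.flanking_distances_for_sites(sites, seqs)
        strands = table.set_index("gene")["strand"]
        minus = table[table["strand"] == "-"]
        plus = table[table["strand"] == "+"]
        assert len(minus) and len(plus)
        assert (minus["downstream"] == 62).all() and (plus["downstream"] == 62).all()

    def test_planted_hexamers_are_only_canonical_instances(self):
        windows, seqs, pas, truth = apakit.simulate_clip_dataset(n_sites=20, seed=16)
        for gene, positions in truth.pas_positions.items():
            seq_t = seqs[gene] if truth.gene_strand[gene] == "+" else reverse_complement(seqs[gene])
            found = sorted(
                i for hx in PAS_HEXAMERS
                for i in range(len(seq_t) - 5)
                if seq_t[i:i + 6] == hx
            )
            assert found == sorted(positions)

    def test_scrub_preserves_kept_positions(self):
        rng = np.random.default_rng(17)
        seq = "AAAATTAAAGG" + "AATAAA" + "CCCC"
        out = _scrub_hexamers(seq, rng, keep={11})
        assert out[11:17] == "AATAAA"
        for hx in PAS_HEXAMERS:
            assert out.find(hx) in (-1, 11)
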