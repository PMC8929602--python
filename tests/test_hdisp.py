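import math

import numpy as np
import pytest

from plastovar.hdisp import (DispersionRanking, dispersion_scores,
                             majority_consensus, map_kmers_to_reference,
                             merge_hits, annotate_regions,
                             progressive_selection, rank_features_by_variability,
                             select_high_dispersion, call_hdisp_regions)
from plastovar.kmer import FrequencyMatrix, count_kmers
from plastovar.records import Feature, PlastomeRecord, revcomp
from plastovar.simulate import SimulationConfig, generate_backbone, simulate_population


def freq_from(counts, kmers=None):
    counts = np.asarray(counts)
    n_samples, n_kmers = counts.shape
    if kmers is None:
        kmers = [f"{'A' * 3}"[:0] + format(i, "03d").replace("0", "A")
                 .replace("1", "C").replace("2", "G").replace("3", "T")
                 for i in range(n_kmers)]
    return FrequencyMatrix(samples=[f"s{i}" for i in range(n_samples)],
                           kmers=list(kmers), counts=counts)


class TestDispersionScores:
    def test_constant_counts_zero_sd(self):
        f = freq_from([[3], [3], [3], [3]], kmers=["AAA"])
        r = dispersion_scores(f)
        assert r.sd[0] == 0.0

    def test_two_two_zero_zero(self):
        f = freq_from([[2], [2], [0], [0]], kmers=["AAA"])
        r = dispersion_scores(f)
        assert r.sd[0] == pytest.approx(math.sqrt(4 / 3), abs=1e-12)
        assert r.sd[0] == pytest.approx(1.1547, abs=1e-4)

    def test_singleton_in_one_of_two(self):
        f = freq_from([[1], [0]], kmers=["AAA"])
        r = dispersion_scores(f)
        assert r.sd[0] == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_single_sample_rejected(self):
        f = freq_from([[1, 2]], kmers=["AAA", "AAC"])
        with pytest.raises(ValueError):
            dispersion_scores(f)

    def test_matches_bruteforce_oracle(self):
        """sd column-by-column equals the independent n-1 formula to 1e-12
        on random matrices up to 20 samples x 1000 k-mers."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, m = int(rng.integers(2, 21)), int(rng.integers(10, 1001))
            counts = rng.integers(0, 5, size=(n, m))
            kmers = [f"k{j:04d}" for j in range(m)]
            f = FrequencyMatrix(samples=[f"s{i}" for i in range(n)],
                                kmers=kmers, counts=counts)
            r = dispersion_scores(f)
            sd_by_kmer = dict(zip(r.kmers, r.sd))
            for j in range(m):
                col = counts[:, j].astype(float)
                mean = col.sum() / n
                oracle = math.sqrt(((col - mean) ** 2).sum() / (n - 1))
                assert abs(sd_by_kmer[kmers[j]] - oracle) < 1e-12

    def test_sorted_descending_ties_lexicographic(self):
        f = freq_from([[1, 0, 3], [0, 1, 0]], kmers=["TTT", "AAA", "CCC"])
        r = dispersion_scores(f)
        assert list(r.sd) == sorted(r.sd, reverse=True)
        # TTT and AAA tie at sd sqrt(0.5): AAA first
        assert r.kmers.index("AAA") < r.kmers.index("TTT")


class TestSelection:
    def _ranking(self):
        f = freq_from([[5, 1, 0, 2], [0, 1, 0, 0]],
                      kmers=["AAA", "AAC", "AAG", "AAT"])
        return dispersion_scores(f)

    def test_top_n_zero_empty(self):
        assert select_high_dispersion(self._ranking(), "top_n:0") == []

    def test_min_sd_zero_strict(self):
        out = select_high_dispersion(self._ranking(), "min_sd:0")
        r = self._ranking()
        assert out == [km for km, s in zip(r.kmers, r.sd) if s > 0]

    def test_top_n_three_sort_oracle(self):
        r = self._ranking()
        out = select_high_dispersion(r, "top_n:3")
        expected = [km for _s, km in
                    sorted(zip(-r.sd, r.kmers))[:3]]
        assert out == expected

    def test_progressive_nested(self):
        subsets = progressive_selection(self._ranking(), min_n=1)
        for big, small in zip(subsets, subsets[1:]):
            assert set(small) <= set(big)

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            select_high_dispersion(self._ranking(), "weird:1")


class TestMapping:
    def test_forward_hit(self):
        ref = PlastomeRecord(id="r", sequence="AAAACGTAAAA")
        hits, un = map_kmers_to_reference(["AACGT"], ref)
        assert un == []
        assert [(h.position, h.strand) for h in hits] == [(2, "+")]

    def test_ir_planted_kmer_two_hits_opposite_strands(self):
        cfg = SimulationConfig(seed=2, lsc_len=1000, ir_len=300, ssc_len=200)
        bb, _ = generate_backbone(cfg)
        k = 31
        a0, _a1 = cfg.region_interval("IRa")
        kmer = bb.sequence[a0 + 50 : a0 + 50 + k]
        hits, un = map_kmers_to_reference([kmer], bb)
        assert un == []
        strands = {h.strand for h in hits}
        assert len(hits) == 2 and strands == {"+", "-"}

    def test_absent_kmer_unmapped(self):
        ref = PlastomeRecord(id="r", sequence="AAAAAAAAAA")
        hits, un = map_kmers_to_reference(["CGCGC"], ref)
        assert hits == [] and un == ["CGCGC"]

    def test_wraparound_hit_on_circular(self):
        ref = PlastomeRecord(id="r", sequence="GTAAAAAAAC", circular=True)
        # window spanning the origin: "AC" + "GTA" starts at position 8
        hits, _ = map_kmers_to_reference(["ACGTA"], ref)
        assert any(h.position == 8 for h in hits)


class TestMergeHits:
    def _ref(self, seq="A" * 50 + "CCGT" * 40 + "A" * 50):
        return PlastomeRecord(id="r", sequence=seq)

    def test_single_isolated_hit_region_of_length_k(self):
        ref = PlastomeRecord(id="r", sequence="AAACAAACGTGGTGGAAACAAAC")
        hits, _ = map_kmers_to_reference(["CGTGG"], ref)
        regions = merge_hits(hits[:1], ref, k=5)
        assert len(regions) == 1 and regions[0].length == 5

    def test_consecutive_hits_merge_to_48(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 400))
        ref = PlastomeRecord(id="r", sequence=seq)
        k = 31
        kmers = sorted({seq[i : i + k] for i in range(100, 118)})
        hits, _ = map_kmers_to_reference(kmers, ref)
        hits = [h for h in hits if 100 <= h.position <= 117]
        regions = merge_hits(hits, ref, k=k, max_gap=0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 148)
        assert regions[0].length == 48

    def test_gap_beyond_max_gap_splits(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 300))
        ref = PlastomeRecord(id="r", sequence=seq)
        k = 11
        kmers = [seq[50 : 50 + k], seq[100 : 100 + k]]
        hits, _ = map_kmers_to_reference(sorted(set(kmers)), ref)
        hits = [h for h in hits if h.position in (50, 100)]
        regions = merge_hits(hits, ref, k=k, max_gap=0)
        assert len(regions) == 2

    def test_copy_rescan_self_consistency(self, small_population):
        """Every called region's sequence occurs in the reference at every
        reported copy position."""
        _cfg, records, _t, _b = small_population
        freq = FrequencyMatrix.from_tables(
            [count_kmers(r, 31) for r in records])
        ref = majority_consensus(records)
        regions, _ = call_hdisp_regions(freq, ref, strategy="top_n:100")
        assert regions
        doubled = ref.sequence + ref.sequence
        for r in regions:
            for pos, strand in r.copies:
                probe = r.sequence if strand == "+" else revcomp(r.sequence)
                assert doubled[pos : pos + r.length] == probe

    def test_monotone_coverage_under_nested_top_n(self, small_population):
        """Selecting more k-mers never removes a previously called region."""
        _cfg, records, _t, _b = small_population
        freq = FrequencyMatrix.from_tables([count_kmers(r, 31) for r in records])
        ref = majority_consensus(records)
        prev_cover = None
        for n in (25, 50, 100):
            regions, _ = call_hdisp_regions(freq, ref, strategy=f"top_n:{n}")
            cover = set()
            for r in regions:
                cover.update(range(r.start, r.end))
            if prev_cover is not None:
                assert prev_cover <= cover
            prev_cover = cover


class TestAnnotation:
    feats = [Feature(name="ndhH", intervals=((100, 200),)),
             Feature(name="rps15", intervals=((300, 400),))]

    def _region(self, start, end):
        from plastovar.hdisp import HDispRegion
        return HDispRegion(reference_id="r", start=start, end=end,
                           sequence="A" * (end - start), copies=[(start, "+")])

    def test_inside_feature(self):
        (r,) = annotate_regions([self._region(320, 360)], self.feats)
        assert r.context_label == "rps15"

    def test_between_features_intergenic(self):
        (r,) = annotate_regions([self._region(220, 260)], self.feats)
        assert r.context_label == "ndhH-rps15 intergenic"

    def test_no_annotation(self):
        (r,) = annotate_regions([self._region(10, 50)], [])
        assert r.context_label == "unannotated"

    def test_spanning_boundary_joined(self):
        (r,) = annotate_regions([self._region(180, 220)], self.feats)
        assert "ndhH" in r.context_label


class TestFeatureRanking:
    def _population_with_gene_windows(self, mult2=2.0, seed=0):
        cfg = SimulationConfig(
            seed=seed, n_samples=8, lsc_len=6000, ir_len=1500, ssc_len=800,
            hypervariable_windows=[("LSC", 60, 10.0), ("SSC", 60, mult2)])
        records, truth, _ = simulate_population(cfg)
        (w1, w2) = truth.planted_windows[:2]
        feats = [
            Feature(name="hotgene", intervals=((w1[0] - 20, w1[1] + 20),)),
            Feature(name="warmgene", intervals=((w2[0] - 20, w2[1] + 20),)),
            Feature(name="coldgene", intervals=((200, 400),)),
        ]
        ref = majority_consensus(records)
        ref.features = feats
        freq = FrequencyMatrix.from_tables([count_kmers(r, 31) for r in records])
        ranking = dispersion_scores(freq)
        return ranking, ref

    def test_planted_window_gene_ranks_first(self):
        ranking, ref = self._population_with_gene_windows(mult2=1.0, seed=1)
        rows = rank_features_by_variability(
            ranking, ref, selected=select_high_dispersion(ranking, "top_q:0.01"))
        assert rows and rows[0]["feature"] == "hotgene"

    def test_zero_variability_flat_table(self):
        cfg = SimulationConfig(seed=0, n_samples=4, lsc_len=2000, ir_len=400,
                               ssc_len=300, background_rate=0.0)
        records, _t, _b = simulate_population(cfg)
        freq = FrequencyMatrix.from_tables([count_kmers(r, 31) for r in records])
        ranking = dispersion_scores(freq)
        ref = records[0].copy_with(features=[Feature(name="g", intervals=((10, 500),))])
        rows = rank_features_by_variability(ranking, ref)
        assert all(row["sum_sd"] == 0 for row in rows)

    def test_stronger_window_ranks_above_weaker_majority(self):
        """10x-window host outranks 2x-window host in a majority of seeds."""
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            ranking, ref = self._population_with_gene_windows(mult2=2.0, seed=seed)
            rows = rank_features_by_variability(ranking, ref)
            score = {r["feature"]: r["sum_sd"] for r in rows}
            if score.get("hotgene", 0) > score.get("warmgene", 0):
                wins += 1
        assert wins > n_seeds / 2


class TestConsensus:
    def test_majority_base_wins(self):
        recs = [PlastomeRecord(id=f"s{i}", sequence=s)
                for i, s in enumerate(["ACGT", "ACGT", "AGGT"])]
        cons = majority_consensus(recs)
        assert cons.sequence == "ACGT"

    def test_unequal_lengths_rejected(self):
        recs = [PlastomeRecord(id="a", sequence="ACGT"),
                PlastomeRecord(id="b", sequence="ACGTA")]
        with pytest.raises(ValueError):
            majority_consensus(recs)
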