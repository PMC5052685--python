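"""Site calling: density comparison, replicate overlap, ranking, metagene."""

import numpy as np
import pytest
from scipy import stats

import parclipkit as pk
from parclipkit.models import REGION_3UTR, REGION_CDS
from tests.conftest import call_sites_for_replicate


def _tx(seq, utr5=0, utr3=0, tid="tx1"):
    n = len(seq)
    return pk.TranscriptModel(
        tid, seq, (0, utr5), (utr5, n - utr3), (n - utr3, n), "mRNA"
    )


class TestProfileConversions:
    def test_single_read_tc(self):
        seq = "A" * 12 + "T" + "A" * 47
        tx = _tx(seq)
        read = pk.AlignedRead("tx1", 10, 30, ((12, "T", "C"),))
        prof = pk.profile_conversions([read], tx)
        assert prof.depth[10:30].tolist() == [1] * 20
        assert prof.depth.sum() == 20
        assert prof.tc_events[12] == 1 and prof.tc_events.sum() == 1
        assert prof.other_mismatches.sum() == 0

    def test_non_signature_mismatch(self):
        seq = "A" * 12 + "G" + "A" * 47
        tx = _tx(seq)
        read = pk.AlignedRead("tx1", 10, 30, ((12, "G", "A"),))
        prof = pk.profile_conversions([read], tx)
        assert prof.tc_events.sum() == 0
        assert prof.other_mismatches[12] == 1

    def test_out_of_bounds_read_named(self):
        tx = _tx("ACGT" * 10)
        with pytest.raises(ValueError, match="badread"):
            pk.profile_conversions(
                [pk.AlignedRead("tx1", 30, 50, name="badread")], tx
            )

    def test_matches_brute_force_recount(self, small_cfg, small_dataset):
        transcripts, truth, reads1, _ = small_dataset
        tx = transcripts[0]
        mine = [r for r in reads1 if r.transcript_id == tx.id][:500]
        prof = pk.profile_conversions(mine, tx)
        depth = np.zeros(len(tx), int)
        tc = np.zeros(len(tx), int)
        other = np.zeros(len(tx), int)
        for r in mine:
            for p in range(r.start, r.end):
                depth[p] += 1
            for p, ref, alt in set(r.mismatches):
                if ref == "T" and alt == "C":
                    tc[p] += 1
                else:
                    other[p] += 1
        assert np.array_equal(prof.depth, depth)
        assert np.array_equal(prof.tc_events, tc)
        assert np.array_equal(prof.other_mismatches, other)


class TestBuildClusters:
    def test_overlap_merging(self):
        reads = [
            pk.AlignedRead("tx1", 0, 20),
            pk.AlignedRead("tx1", 15, 35),
            pk.AlignedRead("tx1", 100, 120),
        ]
        two = pk.build_clusters(reads, min_reads=2)
        assert [(c.start, c.end) for c in two] == [(0, 35)]
        one = pk.build_clusters(reads, min_reads=1)
        assert [(c.start, c.end) for c in one] == [(0, 35), (100, 120)]
        assert pk.build_clusters([], min_reads=1) == []

    def test_matches_coverage_oracle(self):
        rng = np.random.default_rng(42)
        reads = [
            pk.AlignedRead("tx1", int(s), int(s) + int(l), name=f"r{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 950, 1000), rng.integers(10, 50, 1000))
            )
        ]
        clusters = pk.build_clusters(reads, min_reads=1)
        # union-find oracle over pairwise >=1 nt overlaps (adjacent half-open
        # reads share no base and must stay in separate clusters)
        parent = list(range(len(reads)))
        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i
        for i, a in enumerate(reads):
            for j in range(i + 1, len(reads)):
                b = reads[j]
                if a.start < b.end and b.start < a.end:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(len(reads)):
            groups.setdefault(find(i), []).append(reads[i])
        oracle = sorted(
            (min(r.start for r in g), max(r.end for r in g), len(g))
            for g in groups.values()
        )
        assert [(c.start, c.end, len(c.reads)) for c in clusters] == oracle


class TestCallBindingSites:
    def test_focal_conversions_give_one_site_containing_peak(self):
        seq = "T" * 100
        tx = _tx(seq)
        reads = [
            pk.AlignedRead("tx1", 0, 100, ((48 + i % 5, "T", "C"),), name=f"r{i}")
            for i in range(20)
        ]
        prof = pk.profile_conversions(reads, tx)
        cluster = pk.build_clusters(reads, 1)[0]
        sites = pk.call_binding_sites(cluster, prof, tx)
        assert len(sites) == 1
        assert sites[0].start <= 50 < sites[0].end

        # independent dense-grid KDE oracle: same definition, explicit sums
        bw = pk.SiteCallingParams().kde_bandwidth
        conv = np.zeros(100)
        nonconv = np.zeros(100)
        for r in reads:
            tcp = set(r.tc_positions)
            for p in tcp:
                conv[p] += 1
            for p in range(r.start, r.end):
                if seq[p] == "T" and p not in tcp:
                    nonconv[p] += 1
        grid = np.arange(100)
        radius = int(4 * bw)  # same truncation as the implementation

        def kde(weights):
            out = np.zeros(100)
            for p, w in enumerate(weights):
                if w == 0:
                    continue
                lo, hi = max(0, p - radius), min(100, p + radius + 1)
                out[lo:hi] += w * np.exp(-0.5 * ((grid[lo:hi] - p) / bw) ** 2)
            return out / out.sum() if out.sum() else out

        excess = kde(conv) > kde(nonconv)
        oracle_run = (int(np.flatnonzero(excess)[0]), int(np.flatnonzero(excess)[-1] + 1))
        assert oracle_run[0] <= 50 < oracle_run[1]
        # the called site is the oracle run padded to min_site_len at most
        assert abs(sites[0].start - oracle_run[0]) <= pk.SiteCallingParams().min_site_len
        assert abs(sites[0].end - oracle_run[1]) <= pk.SiteCallingParams().min_site_len

    def test_zero_conversions_yield_no_sites(self):
        tx = _tx("T" * 60)
        reads = [pk.AlignedRead("tx1", 0, 60, name=f"r{i}") for i in range(10)]
        prof = pk.profile_conversions(reads, tx)
        cluster = pk.build_clusters(reads, 1)[0]
        assert pk.call_binding_sites(cluster, prof, tx) == []

    def test_saturated_conversions_span_cluster(self):
        tx = _tx("T" * 60)
        reads = [
            pk.AlignedRead(
                "tx1", 0, 60, tuple((p, "T", "C") for p in range(60)), name=f"r{i}"
            )
            for i in range(10)
        ]
        prof = pk.profile_conversions(reads, tx)
        cluster = pk.build_clusters(reads, 1)[0]
        sites = pk.call_binding_sites(cluster, prof, tx)
        assert len(sites) == 1
        assert sites[0].end - sites[0].start >= 55  # nearly the whole cluster


class TestAnnotateRegion:
    tx = _tx("A" * 200, utr5=0, utr3=100)  # CDS [0,100), 3UTR [100,200)

    def _site(self, s, e):
        return pk.BindingSite("tx1", s, e, tc_read_count=1, read_depth=1)

    def test_inside_cds(self):
        assert pk.annotate_region(self._site(10, 30), self.tx) == REGION_CDS

    def test_tie_goes_to_cds(self):
        assert pk.annotate_region(self._site(95, 105), self.tx) == REGION_CDS

    def test_majority_wins(self):
        assert pk.annotate_region(self._site(98, 110), self.tx) == REGION_3UTR


class TestIntersectReplicates:
    def _site(self, s, e, tid="tx1"):
        return pk.BindingSite(tid, s, e, tc_read_count=2, read_depth=2)

    def test_overlap_kept_boundary_dropped(self):
        kept = pk.intersect_replicates([self._site(10, 30)], [self._site(25, 40)])
        assert len(kept) == 1 and kept[0].replicates_supporting == {1, 2}
        assert pk.intersect_replicates([self._site(10, 30)], [self._site(30, 40)]) == []

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        def mk(n):
            return [
                self._site(int(s), int(s) + int(l), tid=f"tx{int(t)}")
                for s, l, t in zip(
                    rng.integers(0, 500, n), rng.integers(5, 30, n), rng.integers(0, 5, n)
                )
            ]
        a, b = mk(150), mk(150)
        kept = {(s.transcript_id, s.start, s.end) for s in pk.intersect_replicates(a, b)}
        oracle = {
            (s.transcript_id, s.start, s.end)
            for s in a
            if any(
                s.transcript_id == o.transcript_id and s.start < o.end and o.start < s.end
                for o in b
            )
        }
        assert kept == oracle
        assert (len(kept) == 0) == (len(oracle) == 0)


class TestSummarizeTargets:
    def _setup(self, c1, c2):
        """One transcript with c1/c2 conversion reads in replicates 1/2."""
        site = pk.BindingSite("tx1", 10, 20, tc_read_count=2, read_depth=4,
                              replicates_supporting=frozenset({1, 2}))
        def mk(rep, n):
            return [
                pk.AlignedRead("tx1", 5, 25, ((12, "T", "C"),), replicate=rep, name=f"{rep}-{i}")
                for i in range(n)
            ]
        return {1: mk(1, c1), 2: mk(2, c2)}, [site]

    def test_passes_when_both_reach_four(self):
        reads, sites = self._setup(5, 4)
        (rec,) = pk.summarize_targets(reads, sites)
        assert rec.passes_min4_both and rec.total_tc_reads == 9

    def test_retained_but_flagged_when_one_below(self):
        reads, sites = self._setup(5, 3)
        (rec,) = pk.summarize_targets(reads, sites)
        assert not rec.passes_min4_both and rec.total_tc_reads == 8

    def test_ranking_invariant_to_input_order(self, small_cfg, small_dataset):
        transcripts, truth, reads1, reads2 = small_dataset
        s1 = call_sites_for_replicate(transcripts, reads1)
        s2 = call_sites_for_replicate(transcripts, reads2)
        replicated = pk.intersect_replicates(s1, s2)
        recs = pk.summarize_targets({1: reads1, 2: reads2}, replicated)
        shuffled = pk.summarize_targets(
            {2: list(reversed(reads2)), 1: list(reversed(reads1))}, replicated[::-1]
        )
        assert [(r.transcript_id, r.rank, r.total_tc_reads) for r in recs] == [
            (r.transcript_id, r.rank, r.total_tc_reads) for r in shuffled
        ]
        ranks = [r.rank for r in recs]
        assert ranks == list(range(1, len(recs) + 1))
        totals = [r.total_tc_reads for r in recs]
        assert totals == sorted(totals, reverse=True)


def test_collapse_genes_sums_counts_and_reranks():
    recs = [
        pk.TargetRecord("tx1a", {1: 3, 2: 2}, 5, 1, False),
        pk.TargetRecord("tx1b", {1: 2, 2: 3}, 5, 2, False),
        pk.TargetRecord("tx2", {1: 4, 2: 4}, 8, 3, True),
    ]
    out = pk.collapse_genes(recs, {"tx1a": "g1", "tx1b": "g1", "tx2": "g2"})
    by_id = {r.transcript_id: r for r in out}
    assert by_id["g1"].tc_reads_per_replicate == {1: 5, 2: 5}
    assert by_id["g1"].passes_min4_both and by_id["g1"].rank == 1
    assert by_id["g2"].rank == 2


class TestMetageneProfile:
    def test_single_bin_and_normalization(self):
        tx = _tx("A" * 300, utr5=50, utr3=50, tid="tx1")  # CDS [50,250)
        sites = [
            pk.BindingSite("tx1", 145, 155, tc_read_count=5, read_depth=5, region=REGION_CDS)
        ]
        prof = pk.metagene_profile(sites, [tx], n_bins=10)
        cds = prof.profiles[REGION_CDS]
        assert cds.sum() == pytest.approx(1.0)
        assert cds[5] == 1.0  # midpoint 150 -> fraction 0.5
        assert REGION_3UTR in prof.empty_regions

    def test_uniform_planting_not_rejected(self):
        """Sites planted uniformly in the CDS give a flat positional profile."""
        pvals = []
        for seed in range(7):
            cfg = pk.SimulationConfig(
                seed=seed, n_transcripts=400, fraction_targets=0.5, tandems_per_target=1
            )
            transcripts, truth = pk.generate_transcriptome(cfg)
            sites = [
                pk.BindingSite(tid, s, e, tc_read_count=4, read_depth=4, region=REGION_CDS)
                for tid, ivs in truth.planted_sites.items()
                for s, e in ivs
            ]
            prof = pk.metagene_profile(sites, transcripts, n_bins=10)
            counts = prof.counts[REGION_CDS]
            pvals.append(stats.chisquare(counts).pvalue)
        assert np.median(pvals) > 0.01
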