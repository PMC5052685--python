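"""Crosslink binding-site calling from T-to-C conversion evidence.

The caller follows the conversion-density approach used for PAR-CLIP data:
overlapping reads are grouped into clusters, and within each cluster two
read-weighted Gaussian kernel densities are compared — one over positions
where reads recorded a T-to-C conversion, one over covered reference-T
positions where they did not. Both densities are normalized to unit mass, so
the comparison asks where conversions concentrate *relative to* the
uridines the reads could have converted: a binding site is each maximal run
where the conversion likelihood exceeds the non-conversion likelihood.
Without the normalization a per-read conversion rate below 50% would leave
the raw non-conversion density dominant everywhere and no site could ever be
called, which is not how crosslink evidence behaves.

Downstream: replicate-overlap filtering, region annotation, the >=4
crosslinked-reads-in-both-replicates target filter, total-read ranking and
metagene (positional) profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .models import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGION_NONCODING,
    AlignedRead,
    BindingSite,
    Cluster,
    ConversionProfile,
    TargetRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)


@dataclass
class SiteCallingParams:
    """Tunables of the density-based caller.

    ``kde_bandwidth`` is the Gaussian sigma in nt, evaluated at integer
    positions; ``min_site_len`` pads short density runs symmetrically;
    ``min_conversion_reads`` distinct conversion-carrying reads are required
    per site; clusters need ``min_reads`` members to be considered.
    """

    min_reads: int = 5
    min_conversion_reads: int = 2
    min_site_len: int = 8
    kde_bandwidth: float = 3.0


def profile_conversions(
    reads: list[AlignedRead], transcript: TranscriptModel
) -> ConversionProfile:
    """Accumulate per-position depth, T-to-C events and other mismatches."""
    n = len(transcript)
    depth = np.zeros(n, dtype=np.int64)
    tc = np.zeros(n, dtype=np.int64)
    other = np.zeros(n, dtype=np.int64)
    for read in reads:
        if read.transcript_id != transcript.id or read.start < 0 or read.end > n:
            raise ValueError(
                f"read {read.name or '<unnamed>'} outside transcript {transcript.id} "
                f"bounds [0, {n})"
            )
        depth[read.start : read.end] += 1
        seen_tc = set()
        for pos, ref, alt in read.mismatches:
            if ref == "T" and alt == "C":
                if pos not in seen_tc:  # a read contributes <=1 event per position
                    tc[pos] += 1
                    seen_tc.add(pos)
            else:
                other[pos] += 1
    t_mask = np.frombuffer(transcript.sequence.encode("ascii"), dtype=np.uint8) == ord("T")
    return ConversionProfile(
        transcript_id=transcript.id,
        depth=depth,
        tc_events=tc,
        other_mismatches=other,
        t_mask=t_mask,
    )


def build_clusters(reads: list[AlignedRead], min_reads: int = 1) -> list[Cluster]:
    """Maximal unions of overlapping reads (>=1 nt shared) with >= min_reads members."""
    clusters: list[Cluster] = []
    by_tx: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_tx.setdefault(r.transcript_id, []).append(r)
    for tid in sorted(by_tx):
        current: Cluster | None = None
        for r in sorted(by_tx[tid], key=lambda r: (r.start, r.end, r.name)):
            if current is not None and r.start < current.end:
                current.end = max(current.end, r.end)
                current.reads.append(r)
            else:
                if current is not None and len(current.reads) >= min_reads:
                    clusters.append(current)
                current = Cluster(tid, r.start, r.end, [r])
        if current is not None and len(current.reads) >= min_reads:
            clusters.append(current)
    return clusters


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2].tolist(), idx[1::2].tolist()))


def call_binding_sites(
    cluster: Cluster,
    profile: ConversionProfile,
    transcript: TranscriptModel | None = None,
    params: SiteCallingParams | None = None,
) -> list[BindingSite]:
    """Call sites inside one cluster by normalized conversion-density excess.

    A cluster with zero conversion events yields an empty list. Each
    candidate run is padded symmetrically to ``min_site_len`` (clipped to
    the cluster), overlapping candidates are merged, and a site must retain
    at least ``min_conversion_reads`` distinct conversion-carrying reads.
    """
    params = params or SiteCallingParams()
    if len(cluster.reads) < params.min_reads:
        raise ValueError(
            f"cluster {cluster.transcript_id}:{cluster.start}-{cluster.end} has "
            f"{len(cluster.reads)} reads < min_reads={params.min_reads}"
        )
    cs, ce = cluster.start, cluster.end
    conv = profile.tc_events[cs:ce].astype(float)
    noncv = np.where(
        profile.t_mask[cs:ce], profile.depth[cs:ce] - profile.tc_events[cs:ce], 0
    ).astype(float)
    if conv.sum() == 0:
        return []
    conv_d = gaussian_filter1d(conv, params.kde_bandwidth, mode="constant")
    noncv_d = gaussian_filter1d(noncv, params.kde_bandwidth, mode="constant")
    conv_d /= conv_d.sum()
    if noncv_d.sum() > 0:
        noncv_d /= noncv_d.sum()
    candidates = []
    for s, e in _maximal_runs(conv_d > noncv_d):
        if e - s < params.min_site_len:
            pad = params.min_site_len - (e - s)
            s = max(0, s - pad // 2)
            e = min(ce - cs, s + params.min_site_len)
            s = max(0, e - params.min_site_len)
        candidates.append((s + cs, e + cs))
    merged: list[list[int]] = []
    for s, e in sorted(candidates):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    sites = []
    for s, e in merged:
        tc_reads = sum(
            1 for r in cluster.reads if any(s <= p < e for p in r.tc_positions)
        )
        if tc_reads < params.min_conversion_reads:
            continue
        depth = sum(1 for r in cluster.reads if r.start < e and r.end > s)
        site = BindingSite(
            transcript_id=cluster.transcript_id,
            start=s,
            end=e,
            tc_read_count=tc_reads,
            read_depth=depth,
            replicates_supporting=frozenset(r.replicate for r in cluster.reads),
        )
        if transcript is not None:
            site.region = annotate_region(site, transcript)
        sites.append(site)
    return sites


def annotate_region(site: BindingSite, transcript: TranscriptModel) -> str:
    """Region with maximal overlap; ties go CDS > 3'UTR > 5'UTR."""
    if transcript.biotype != "mRNA":
        return REGION_NONCODING
    overlaps = {}
    for name, (rs, re_) in transcript.regions.items():
        overlaps[name] = max(0, min(site.end, re_) - max(site.start, rs))
    if sum(overlaps.values()) == 0:
        raise ValueError(
            f"site {site.start}-{site.end} does not overlap transcript {transcript.id}"
        )
    priority = {REGION_CDS: 0, REGION_3UTR: 1, REGION_5UTR: 2}
    return max(overlaps, key=lambda k: (overlaps[k], -priority[k]))


def intersect_replicates(
    sites_rep1: list[BindingSite], sites_rep2: list[BindingSite]
) -> list[BindingSite]:
    """Replicate-1 sites sharing >=1 nt with any replicate-2 site on the same transcript."""
    by_tx: dict[str, list[BindingSite]] = {}
    for s in sites_rep2:
        by_tx.setdefault(s.transcript_id, []).append(s)
    kept = []
    for s in sites_rep1:
        if any(
            s.start < o.end and o.start < s.end
            for o in by_tx.get(s.transcript_id, [])
        ):
            kept.append(
                BindingSite(
                    transcript_id=s.transcript_id,
                    start=s.start,
                    end=s.end,
                    tc_read_count=s.tc_read_count,
                    read_depth=s.read_depth,
                    region=s.region,
                    replicates_supporting=frozenset({1, 2}),
                )
            )
    return kept


def summarize_targets(
    reads_by_replicate: dict[int, list[AlignedRead]],
    replicated_sites: list[BindingSite],
    min_reads: int = 4,
    site_restricted: bool = True,
    transcripts: list[TranscriptModel] | None = None,
) -> "list[TargetRecord]":
    """Rank transcripts by the summed conversion-read count over replicates.

    A conversion read is a distinct read carrying >=1 T-to-C that (in the
    default site-restricted mode) overlaps a reproducible binding site of
    its transcript; ``passes_min4_both`` requires every replicate's count to
    reach ``min_reads``. Records are sorted by total descending with
    lexicographic transcript tie-break, and ranks assigned after sorting, so
    ranking is invariant to input order.
    """
    known = {t.id for t in transcripts} if transcripts is not None else None
    sites_by_tx: dict[str, list[tuple[int, int]]] = {}
    for s in replicated_sites:
        sites_by_tx.setdefault(s.transcript_id, []).append(s.interval)

    counts: dict[str, dict[int, int]] = {}
    for rep, reads in reads_by_replicate.items():
        for r in reads:
            if known is not None and r.transcript_id not in known:
                raise KeyError(f"read {r.name} maps to unknown transcript {r.transcript_id}")
            tcp = r.tc_positions
            if not tcp:
                continue
            if site_restricted:
                ivs = sites_by_tx.get(r.transcript_id)
                if not ivs or not any(
                    any(s <= p < e for (s, e) in ivs) for p in tcp
                ):
                    continue
            counts.setdefault(r.transcript_id, {})[rep] = (
                counts.get(r.transcript_id, {}).get(rep, 0) + 1
            )

    universe = set(sites_by_tx) if site_restricted else set(counts)
    replicates = sorted(reads_by_replicate)
    records = []
    for tid in universe:
        per_rep = {rep: counts.get(tid, {}).get(rep, 0) for rep in replicates}
        total = sum(per_rep.values())
        records.append(
            TargetRecord(
                transcript_id=tid,
                tc_reads_per_replicate=per_rep,
                total_tc_reads=total,
                rank=0,
                passes_min4_both=all(c >= min_reads for c in per_rep.values()),
            )
        )
    records.sort(key=lambda r: (-r.total_tc_reads, r.transcript_id))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


def collapse_genes(
    records: list[TargetRecord],
    gene_map: dict[str, str],
    min_reads: int = 4,
) -> list[TargetRecord]:
    """Merge transcript-level records onto genes by summing read counts.

    ``gene_map`` maps transcript id to gene id (identity for unmapped
    transcripts). Pass/fail and ranking are recomputed on the summed
    per-replicate counts.
    """
    merged: dict[str, dict[int, int]] = {}
    for r in records:
        gene = gene_map.get(r.transcript_id, r.transcript_id)
        acc = merged.setdefault(gene, {})
        for rep, c in r.tc_reads_per_replicate.items():
            acc[rep] = acc.get(rep, 0) + c
    out = [
        TargetRecord(
            transcript_id=gene,
            tc_reads_per_replicate=per,
            total_tc_reads=sum(per.values()),
            rank=0,
            passes_min4_both=all(c >= min_reads for c in per.values()),
        )
        for gene, per in merged.items()
    ]
    out.sort(key=lambda r: (-r.total_tc_reads, r.transcript_id))
    for i, rec in enumerate(out, start=1):
        rec.rank = i
    return out


@dataclass
class MetageneProfile:
    """Length-normalized positional density of sites per region."""

    n_bins: int
    counts: dict[str, np.ndarray]
    profiles: dict[str, np.ndarray]
    high_support_profiles: dict[str, np.ndarray]
    empty_regions: set[str]


def metagene_profile(
    replicated_sites: list[BindingSite],
    transcripts: list[TranscriptModel],
    n_bins: int = 20,
    support_tiers: tuple[int, int] = (4, 20),
) -> MetageneProfile:
    """Histogram of site midpoints as fractional positions within their region.

    Each profile is normalized to sum 1; a region with zero sites gets an
    all-zero profile and is flagged. ``support_tiers`` mirrors the low/high
    read-support split (sites with >= the second tier of conversion reads
    are additionally profiled separately).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tx_by_id = {t.id: t for t in transcripts}
    regions = (REGION_5UTR, REGION_CDS, REGION_3UTR, REGION_NONCODING)
    counts = {r: np.zeros(n_bins) for r in regions}
    hi_counts = {r: np.zeros(n_bins) for r in regions}
    _, hi_tier = support_tiers
    for site in replicated_sites:
        tx = tx_by_id[site.transcript_id]
        rs, re_ = tx.regions.get(site.region, (0, len(tx)))
        if re_ <= rs:
            continue
        frac = min(max((site.midpoint - rs) / (re_ - rs), 0.0), 1.0 - 1e-12)
        b = int(frac * n_bins)
        counts[site.region][b] += 1
        if site.tc_read_count >= hi_tier:
            hi_counts[site.region][b] += 1
    profiles, hi_profiles, empty = {}, {}, set()
    for r in regions:
        tot = counts[r].sum()
        if tot == 0:
            empty.add(r)
            logger.warning("metagene_profile: region %s has zero sites", r)
            profiles[r] = np.zeros(n_bins)
        else:
            profiles[r] = counts[r] / tot
        hi_tot = hi_counts[r].sum()
        hi_profiles[r] = hi_counts[r] / hi_tot if hi_tot else np.zeros(n_bins)
    return MetageneProfile(
        n_bins=n_bins,
        counts=counts,
        profiles=profiles,
        high_support_profiles=hi_profiles,
        empty_regions=empty,
    )
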