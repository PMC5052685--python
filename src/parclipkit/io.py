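"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, SAM through pysam (mismatches are recovered
from the MD tag), everything tabular is TSV with an explicit header.
Coordinates in every table are 0-based half-open transcript coordinates.
All writers format floats with a fixed precision so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedRead, BindingSite, TargetRecord, TranscriptModel
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"
COORD_NOTE = "coordinates are 0-based half-open, transcript space"


# ---------------------------------------------------------------------------
# Transcripts


def write_transcripts_fasta(transcripts: list[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"biotype={t.biotype}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_region_table(transcripts: list[TranscriptModel], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": t.id,
            "utr5_len": t.utr5[1] - t.utr5[0],
            "cds_len": t.cds[1] - t.cds[0],
            "utr3_len": t.utr3[1] - t.utr3[0],
            "biotype": t.biotype,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcripts(fasta_path: str | Path, region_path: str | Path) -> list[TranscriptModel]:
    regions = pd.read_csv(region_path, sep="\t").set_index("transcript_id")
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = regions.loc[rec.id]
        u5, cds, u3 = int(row["utr5_len"]), int(row["cds_len"]), int(row["utr3_len"])
        biotype = str(row["biotype"])
        if biotype == "mRNA":
            ivs = ((0, u5), (u5, u5 + cds), (u5 + cds, u5 + cds + u3))
        else:
            ivs = ((0, 0), (0, 0), (0, 0))
        transcripts.append(
            TranscriptModel(rec.id, str(rec.seq), ivs[0], ivs[1], ivs[2], biotype)
        )
    return transcripts


# ---------------------------------------------------------------------------
# Ground truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for gene in sorted(truth.true_mrna_log2fc):
        ivs = truth.planted_sites.get(gene, [])
        rows.append(
            {
                "transcript_id": gene,
                "is_target": int(gene in truth.target_ids),
                "planted_intervals": ";".join(f"{s}-{e}" for s, e in ivs) or ".",
                "true_mrna_log2fc": truth.true_mrna_log2fc[gene],
                "true_secretome_log2fc": truth.true_secretome_log2fc.get(gene, np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    truth = GroundTruth()
    for _, row in df.iterrows():
        tid = str(row["transcript_id"])
        truth.true_mrna_log2fc[tid] = float(row["true_mrna_log2fc"])
        if not pd.isna(row["true_secretome_log2fc"]):
            truth.true_secretome_log2fc[tid] = float(row["true_secretome_log2fc"])
        if int(row["is_target"]):
            truth.target_ids.add(tid)
            ivs = []
            if str(row["planted_intervals"]) != ".":
                for tok in str(row["planted_intervals"]).split(";"):
                    s, e = tok.split("-")
                    ivs.append((int(s), int(e)))
            truth.planted_sites[tid] = ivs
    return truth


# ---------------------------------------------------------------------------
# Reads: TSV dialect and SAM


def _format_mismatches(read: AlignedRead) -> str:
    if not read.mismatches:
        return "."
    return ";".join(f"{p}:{r}>{a}" for p, r, a in read.mismatches)


def write_reads_tsv(reads: list[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {COORD_NOTE}; mismatches as pos:ref>alt;...\n")
        fh.write("transcript_id\tstart\tend\treplicate\tname\tmismatches\n")
        for r in reads:
            fh.write(
                f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.replicate}\t{r.name}\t"
                f"{_format_mismatches(r)}\n"
            )


def _parse_mismatch_field(field: str, lineno: int) -> tuple:
    if field == ".":
        return ()
    out = []
    for tok in field.split(";"):
        try:
            pos, sub = tok.split(":")
            ref, alt = sub.split(">")
            out.append((int(pos), ref, alt))
        except ValueError as exc:
            raise ValueError(f"malformed mismatch field {tok!r} on line {lineno}") from exc
    return tuple(out)


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("transcript_id"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"malformed TSV read line {lineno}: expected 6 fields")
            tid, start, end, rep, name, mm = parts
            try:
                reads.append(
                    AlignedRead(
                        transcript_id=tid,
                        start=int(start),
                        end=int(end),
                        mismatches=_parse_mismatch_field(mm, lineno),
                        replicate=int(rep),
                        name=name,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed TSV read line {lineno}: {exc}") from exc
    if not reads:
        logger.warning("read_reads_tsv: no reads parsed from %s", path)
    return reads


def _md_tag(ref_slice: str, mismatches: dict[int, str]) -> str:
    """MD tag for an all-match CIGAR with substitutions at given offsets."""
    md = []
    run = 0
    for i, base in enumerate(ref_slice):
        if i in mismatches:
            md.append(str(run))
            md.append(base)
            run = 0
        else:
            run += 1
    md.append(str(run))
    return "".join(md)


def write_reads_sam(
    reads: list[AlignedRead], transcripts: list[TranscriptModel], path: str | Path
) -> None:
    """Write reads as SAM against the transcript reference, MD/NM tags set.

    The read sequence is reconstructed from the reference with the recorded
    substitutions applied; the replicate index is stored in the ``XR`` tag.
    """
    tx_by_id = {t.id: t for t in transcripts}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.id, "LN": len(t)} for t in transcripts],
    }
    ref_index = {t.id: i for i, t in enumerate(transcripts)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            tx = tx_by_id[r.transcript_id]
            ref_slice = tx.sequence[r.start : r.end]
            offsets = {p - r.start: a for p, _, a in r.mismatches}
            seq = "".join(
                offsets.get(i, b) for i, b in enumerate(ref_slice)
            )
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.name or f"read_{r.transcript_id}_{r.start}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = ref_index[r.transcript_id]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{len(seq)}M"
            a.set_tag("MD", _md_tag(ref_slice, {p - r.start: ref for p, ref, _ in r.mismatches}))
            a.set_tag("NM", len(r.mismatches))
            a.set_tag("XR", int(r.replicate))
            fh.write(a)


def load_alignments(
    path: str | Path,
    dialect: str = "tsv",
    transcripts: list[TranscriptModel] | None = None,
) -> list[AlignedRead]:
    """Load aligned reads from SAM (MD-tag mismatch recovery) or the TSV dialect.

    With ``transcripts`` given, every read is validated against the
    reference: bounds inside the transcript and mismatch reference bases
    agreeing with the sequence.
    """
    if dialect == "tsv":
        reads = read_reads_tsv(path)
    elif dialect == "sam":
        reads = _read_sam(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if transcripts is not None:
        _validate_reads(reads, transcripts)
    logger.info("loaded %d reads from %s", len(reads), path)
    return reads


def _read_sam(path: str | Path) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("MD"):
                raise ValueError(
                    f"SAM record {rec.query_name!r} lacks the MD tag needed to "
                    "recover mismatches"
                )
            mismatches = []
            qseq = rec.query_sequence or ""
            for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None or ref_base is None:
                    continue
                if ref_base.islower():
                    mismatches.append((rpos, ref_base.upper(), qseq[qpos].upper()))
            replicate = int(rec.get_tag("XR")) if rec.has_tag("XR") else 1
            reads.append(
                AlignedRead(
                    transcript_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    mismatches=tuple(mismatches),
                    replicate=replicate,
                    name=rec.query_name,
                )
            )
    if not reads:
        logger.warning("load_alignments: no reads parsed from %s", path)
    return reads


def _validate_reads(reads: list[AlignedRead], transcripts: list[TranscriptModel]) -> None:
    tx_by_id = {t.id: t for t in transcripts}
    for r in reads:
        tx = tx_by_id.get(r.transcript_id)
        if tx is None:
            raise ValueError(f"read {r.name!r} maps to unknown transcript {r.transcript_id}")
        if r.start < 0 or r.end > len(tx):
            raise ValueError(f"read {r.name!r} outside transcript {tx.id} bounds")
        for p, ref, _ in r.mismatches:
            if tx.sequence[p] != ref:
                raise ValueError(
                    f"read {r.name!r}: mismatch reference base {ref} at {p} "
                    f"disagrees with transcript ({tx.sequence[p]})"
                )


# ---------------------------------------------------------------------------
# Sites, targets, enrichments, integration tables


def write_sites_tsv(sites: list[BindingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {COORD_NOTE}\n")
        fh.write(
            "transcript_id\tstart\tend\tregion\ttc_read_count\tread_depth\treplicates\n"
        )
        for s in sites:
            reps = ",".join(str(r) for r in sorted(s.replicates_supporting)) or "."
            fh.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.region}\t"
                f"{s.tc_read_count}\t{s.read_depth}\t{reps}\n"
            )


def write_sites_bed(sites: list[BindingSite], path: str | Path) -> None:
    """BED6 in transcript coordinates: name=region, score=tc_read_count."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.region}\t"
                f"{s.tc_read_count}\t+\n"
            )


def write_targets_tsv(records: list[TargetRecord], path: str | Path) -> None:
    replicates = sorted({rep for r in records for rep in r.tc_reads_per_replicate})
    with open(path, "w") as fh:
        cols = "\t".join(f"tc_reads_rep{rep}" for rep in replicates)
        fh.write(f"transcript_id\t{cols}\ttotal_tc_reads\trank\tpasses_min_filter\n")
        for r in sorted(records, key=lambda r: r.rank):
            per = "\t".join(str(r.tc_reads_per_replicate.get(rep, 0)) for rep in replicates)
            fh.write(
                f"{r.transcript_id}\t{per}\t{r.total_tc_reads}\t{r.rank}\t"
                f"{int(r.passes_min4_both)}\n"
            )


def read_targets_tsv(path: str | Path) -> list[TargetRecord]:
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("tc_reads_rep")]
    records = []
    for _, row in df.iterrows():
        per = {int(c.removeprefix("tc_reads_rep")): int(row[c]) for c in rep_cols}
        records.append(
            TargetRecord(
                transcript_id=str(row["transcript_id"]),
                tc_reads_per_replicate=per,
                total_tc_reads=int(row["total_tc_reads"]),
                rank=int(row["rank"]),
                passes_min4_both=bool(row["passes_min_filter"]),
            )
        )
    return records


def write_kmer_tsv(enrichments, path: str | Path) -> None:
    rows = [
        {
            "kmer": e.kmer,
            "observed_freq": e.observed_freq,
            "background_mean": e.background_mean,
            "background_sd": e.background_sd,
            "z_score": e.z_score,
            "ratio": e.ratio,
            "flagged": int(e.flagged),
        }
        for e in enrichments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_spacer_tsv(enrichments, path: str | Path) -> None:
    rows = [
        {
            "spacer_nt": e.spacer,
            "observed_count": e.observed_count,
            "background_mean": e.background_mean,
            "background_sd": e.background_sd,
            "enrichment": e.enrichment,
            "z_score": e.z_score,
        }
        for e in enrichments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_motif_file(motif, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{motif.pattern}\n")


def write_motif_meme(kmers: list[str], path: str | Path, name: str = "RRE") -> None:
    """Position-frequency matrix of the top k-mers in MEME minimal text format."""
    k = len(kmers[0])
    counts = np.zeros((k, 4))
    order = "ACGT"
    for km in kmers:
        for i, b in enumerate(km.upper().replace("U", "T")):
            counts[i, order.index(b)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {k} nsites= {len(kmers)}\n")
        for row in freqs:
            fh.write(" ".join(FLOAT_FMT % v for v in row) + "\n")


def write_intensity_tsv(matrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# groups: " + ",".join(f"{c}={g}" for c, g in matrix.groups.items()) + "\n")
    matrix.data.to_csv(path, sep="\t", mode="a", float_format=FLOAT_FMT)


def read_intensity_tsv(path: str | Path):
    from .integrate import IntensityMatrix

    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# groups:"):
        raise ValueError(f"{path}: missing '# groups:' header line")
    groups = dict(tok.split("=") for tok in first.split(":", 1)[1].strip().split(","))
    data = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
    return IntensityMatrix(data=data, groups=groups)


def write_foldchange_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_foldchange_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sam_results_tsv(results, path: str | Path) -> None:
    rows = [
        {
            "protein": r.protein,
            "d_statistic": r.d_statistic,
            "log2fc": r.log2fc,
            "significant": int(r.significant),
            "threshold_delta": r.threshold_delta,
            "fdr_target": r.fdr_target,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_ecdf_points_tsv(comparison, path: str | Path) -> None:
    """Step-function support points of each stratum's ECDF, for plotting."""
    rows = []
    for stratum, ecdf in sorted(comparison.ecdfs.items()):
        for x, y in zip(ecdf.x[1:], ecdf.y[1:]):  # drop the -inf anchor
            rows.append({"stratum": stratum, "log2fc": x, "ecdf": y})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
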