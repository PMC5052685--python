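"""Stage orchestration: simulate -> sites -> motif -> integrate.

Each stage reads its inputs from the run directory, writes its outputs
there, and appends record counts to a manifest. Identical config + seed
yields byte-identical TSV outputs; no stage consumes wall-clock time or
environment entropy.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import dump_config
from .integrate import (
    IntensityMatrix,
    correlate_regulation,
    ecdf_compare,
    log2_intensities,
    median_normalize,
    sam_permutation_test,
    stratify_by_crosslink,
)
from .motifs import (
    collapse_kmers_to_iupac,
    kmer_enrichment,
    shuffle_sequences,
    tandem_spacer_enrichment,
)
from .simulate import (
    SimulationConfig,
    generate_transcriptome,
    simulate_expression,
    simulate_parclip_replicate,
    simulate_secretome,
)
from .sites import (
    SiteCallingParams,
    build_clusters,
    call_binding_sites,
    intersect_replicates,
    metagene_profile,
    profile_conversions,
    summarize_targets,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sim_config(cfg: dict) -> SimulationConfig:
    s = cfg["simulate"]
    return SimulationConfig(
        seed=cfg["seed"],
        n_transcripts=s["n_transcripts"],
        fraction_targets=s["fraction_targets"],
        region_lengths=tuple(s["region_lengths"]),
        base_composition=tuple(s["base_composition"]),
        motif_first=s["motif_first"],
        motif_second=s["motif_second"],
        spacer_nt=s["spacer_nt"],
        tandems_per_target=s["tandems_per_target"],
        reads_per_site=s["reads_per_site"],
        background_read_rate=s["background_read_rate"],
        conversion_prob=s["conversion_prob"],
        background_conversion_prob=s["background_conversion_prob"],
        read_length_mean=s["read_length_mean"],
        read_length_sd=s["read_length_sd"],
        n_replicates=s["n_replicates"],
        secretome_slope=s["secretome_slope"],
        secretome_noise_sd=s["secretome_noise_sd"],
        lfq_samples_per_group=s["lfq_samples_per_group"],
        counts_dispersion=s["counts_dispersion"],
        nontarget_shift_fraction=s["nontarget_shift_fraction"],
    )


def _manifest_update(outdir: Path, stage: str, counts: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.setdefault("stages", {})[stage] = counts
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def stage_simulate(cfg: dict, outdir: Path) -> None:
    sim = _sim_config(cfg)
    transcripts, truth = generate_transcriptome(sim)
    io.write_transcripts_fasta(transcripts, outdir / "transcripts.fasta")
    io.write_region_table(transcripts, outdir / "regions.tsv")
    n_reads = {}
    for rep in range(1, sim.n_replicates + 1):
        reads = simulate_parclip_replicate(transcripts, truth, sim, rep)
        io.write_reads_tsv(reads, outdir / f"reads_rep{rep}.tsv")
        io.write_reads_sam(reads, transcripts, outdir / f"reads_rep{rep}.sam")
        n_reads[f"reads_rep{rep}"] = len(reads)
    expression = simulate_expression(truth, sim)
    io.write_foldchange_tsv(expression, outdir / "expression.tsv")
    io.write_ground_truth(truth, outdir / "ground_truth.tsv")
    _manifest_update(
        outdir,
        "simulate",
        {
            "transcripts": len(transcripts),
            "targets": len(truth.target_ids),
            "planted_sites": sum(len(v) for v in truth.planted_sites.values()),
            **n_reads,
        },
    )


def stage_sites(cfg: dict, outdir: Path) -> None:
    transcripts = io.read_transcripts(outdir / "transcripts.fasta", outdir / "regions.tsv")
    tx_by_id = {t.id: t for t in transcripts}
    p = cfg["sites"]
    params = SiteCallingParams(
        min_reads=p["min_cluster_reads"],
        min_conversion_reads=p["min_conversion_reads"],
        min_site_len=p["min_site_len"],
        kde_bandwidth=p["kde_bandwidth"],
    )
    dialect = cfg["dialect"]
    n_reps = cfg["simulate"]["n_replicates"]
    reads_by_rep: dict[int, list] = {}
    sites_by_rep: dict[int, list] = {}
    for rep in range(1, n_reps + 1):
        path = outdir / f"reads_rep{rep}.{'sam' if dialect == 'sam' else 'tsv'}"
        reads = io.load_alignments(path, dialect=dialect, transcripts=transcripts)
        reads_by_rep[rep] = reads
        sites = []
        by_tx: dict[str, list] = {}
        for r in reads:
            by_tx.setdefault(r.transcript_id, []).append(r)
        for tid, tx_reads in sorted(by_tx.items()):
            profile = profile_conversions(tx_reads, tx_by_id[tid])
            for cluster in build_clusters(tx_reads, min_reads=params.min_reads):
                sites.extend(
                    call_binding_sites(cluster, profile, tx_by_id[tid], params)
                )
        sites_by_rep[rep] = sites
        io.write_sites_tsv(sites, outdir / f"sites_rep{rep}.tsv")
    if n_reps >= 2:
        replicated = intersect_replicates(sites_by_rep[1], sites_by_rep[2])
    else:
        replicated = sites_by_rep[1]
    io.write_sites_tsv(replicated, outdir / "sites_replicated.tsv")
    io.write_sites_bed(replicated, outdir / "sites_replicated.bed")
    records = summarize_targets(
        reads_by_rep, replicated, min_reads=p["min_target_reads"], transcripts=transcripts
    )
    io.write_targets_tsv(records, outdir / "targets.tsv")
    prof = metagene_profile(replicated, transcripts, n_bins=p["metagene_bins"])
    rows = []
    for region, arr in sorted(prof.profiles.items()):
        for b, v in enumerate(arr):
            rows.append({"region": region, "bin": b, "density": v})
    pd.DataFrame(rows).to_csv(
        outdir / "metagene.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT
    )
    _manifest_update(
        outdir,
        "sites",
        {
            **{f"sites_rep{r}": len(s) for r, s in sites_by_rep.items()},
            "sites_replicated": len(replicated),
            "targets_passing": sum(1 for r in records if r.passes_min4_both),
            "targets_total": len(records),
        },
    )


def stage_motif(cfg: dict, outdir: Path) -> None:
    transcripts = io.read_transcripts(outdir / "transcripts.fasta", outdir / "regions.tsv")
    tx_by_id = {t.id: t for t in transcripts}
    m = cfg["motif"]
    sites_df = pd.read_csv(outdir / "sites_replicated.tsv", sep="\t", comment="#")
    flank = m["site_flank"]
    cluster_seqs = []
    site_transcripts = set()
    for _, row in sites_df.iterrows():
        tx = tx_by_id[row["transcript_id"]]
        s = max(0, int(row["start"]) - flank)
        e = min(len(tx), int(row["end"]) + flank)
        cluster_seqs.append(tx.sequence[s:e])
        site_transcripts.add(tx.id)
    if not cluster_seqs:
        logger.warning("motif stage: no replicated sites; writing empty outputs")
        for name in ("kmer_enrichment.tsv", "spacer_enrichment.tsv"):
            (outdir / name).write_text("")
        (outdir / "motif.txt").write_text("")
        _manifest_update(outdir, "motif", {"cluster_seqs": 0})
        return
    rng = np.random.default_rng([cfg["seed"], 5])
    orf_pool = sorted(tid for tid in tx_by_id if tid not in site_transcripts) or sorted(tx_by_id)
    chosen = rng.choice(len(orf_pool), size=min(m["background_orfs"], len(orf_pool)), replace=False)
    orfs = [
        tx_by_id[orf_pool[i]].sequence[slice(*tx_by_id[orf_pool[i]].cds)]
        for i in sorted(chosen.tolist())
    ]
    background = shuffle_sequences(
        orfs, n_shuffles=m["n_shuffles"], mode=m["shuffle_mode"], seed=int(cfg["seed"]) + 51
    )
    enr = kmer_enrichment(cluster_seqs, background, k=m["k"], window=m["window"])
    io.write_kmer_tsv(enr, outdir / "kmer_enrichment.tsv")
    top = [e.kmer for e in enr[: m["top_kmers"]]]
    motif = collapse_kmers_to_iupac(top)
    io.write_motif_file(motif, outdir / "motif.txt")
    io.write_motif_meme(top, outdir / "motif_pfm.meme")
    spacers = tandem_spacer_enrichment(
        cluster_seqs, motif, max_spacer=m["max_spacer"], background=background
    )
    io.write_spacer_tsv(spacers, outdir / "spacer_enrichment.tsv")
    _manifest_update(
        outdir,
        "motif",
        {
            "cluster_seqs": len(cluster_seqs),
            "motif": motif.pattern,
            "best_spacer": int(max(spacers, key=lambda s: s.z_score).spacer),
        },
    )


def stage_integrate(cfg: dict, outdir: Path) -> None:
    sim = _sim_config(cfg)
    q = cfg["integrate"]
    truth = io.read_ground_truth(outdir / "ground_truth.tsv")
    records = io.read_targets_tsv(outdir / "targets.tsv")
    expression = io.read_foldchange_tsv(outdir / "expression.tsv")
    crosslink_reads = {g: 0 for g in truth.true_mrna_log2fc}
    for r in records:
        crosslink_reads[r.transcript_id] = r.total_tc_reads
    matrix = simulate_secretome(truth, crosslink_reads, sim)
    io.write_intensity_tsv(matrix, outdir / "secretome_intensities.tsv")
    logm = log2_intensities(median_normalize(matrix))
    results = sam_permutation_test(
        logm,
        s0=q["s0"],
        n_perm=q["n_perm"],
        fdr=q["fdr"],
        contrast=("knockdown", "control"),
        seed=int(cfg["seed"]) + 73,
    )
    io.write_sam_results_tsv(results, outdir / "sam_results.tsv")
    counts: dict = {"sam_significant": sum(r.significant for r in results)}

    strata = stratify_by_crosslink(
        records, expression, top_n=q["top_n"], expression_floor=q["expression_floor"]
    )
    io.write_foldchange_tsv(strata, outdir / "strata_mrna.tsv")
    passing = [r for r in records if r.passes_min4_both]
    if passing and set(strata["stratum"]) >= {"top", "non"}:
        comp = ecdf_compare(strata)
        io.write_ecdf_points_tsv(comp, outdir / "ecdf_mrna.tsv")
        counts["mrna_median_shift_top"] = comp.medians.get("top")

        secr_lfc = {r.protein: r.log2fc for r in results}
        target_lfc = {
            r.transcript_id: secr_lfc[r.transcript_id]
            for r in passing
            if r.transcript_id in secr_lfc
        }
        target_reads = {r.transcript_id: r.total_tc_reads for r in passing}
        try:
            pearson_r, pearson_p = correlate_regulation(target_lfc, target_reads)
            pd.DataFrame(
                [{"pearson_r": pearson_r, "p_value": pearson_p, "n": len(target_lfc)}]
            ).to_csv(outdir / "correlation.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
            counts["pearson_r"] = round(pearson_r, 6)
        except ValueError as exc:
            logger.warning("correlation skipped: %s", exc)
    else:
        logger.warning(
            "integrate stage: no passing targets; ECDF and correlation skipped"
        )
        (outdir / "ecdf_mrna.tsv").write_text("")
        (outdir / "correlation.tsv").write_text("")
    _manifest_update(outdir, "integrate", counts)


_STAGES = {
    "simulate": stage_simulate,
    "sites": stage_sites,
    "motif": stage_motif,
    "integrate": stage_integrate,
}


def run_pipeline(cfg: dict, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all, in order) into cfg['outdir']."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest.update({"seed": cfg["seed"], "parclipkit_version": __version__})
    manifest.setdefault("stages", {})
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    dump_config(cfg, outdir / "config_resolved.yaml")
    for name in stages or list(_STAGES):
        logger.info("running stage %s", name)
        try:
            _STAGES[name](cfg, outdir)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return outdir
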