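"""Synthetic data with the statistical structure of a PAR-CLIP study.

Generates, under one seed, every input the downstream stages consume:

* a transcriptome in which a configurable fraction of transcripts ("targets")
  carry tandem occurrences of a degenerate recognition element planted in
  their coding sequence;
* two-replicate crosslinking reads whose T-to-C conversions concentrate at
  the planted intervals over a uniform low-conversion background;
* an mRNA fold-change table in which targets are, by construction, unchanged
  between conditions;
* a secretome LFQ intensity matrix in which targets are down-regulated in
  the knockdown group proportionally to their crosslink-read counts;

together with a :class:`GroundTruth` record so that every downstream stage
has a parameter-recovery test.

All generators are pure functions of ``(config, seed, replicate)``: the same
seed yields bit-identical outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import AlignedRead, TranscriptModel
from .motifs import DegenerateMotif

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Fixed per-purpose stream offsets so the transcriptome, each read replicate,
# the expression table and the secretome draw from independent substreams of
# the one configured seed.
_STREAM_TRANSCRIPTOME = 1
_STREAM_READS = 2
_STREAM_EXPRESSION = 3
_STREAM_SECRETOME = 4


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-condition defaults.

    Region lengths are nucleotides (5'UTR, CDS, 3'UTR); ``base_composition``
    is (A, C, G, T) and must sum to 1; ``reads_per_site`` is the Poisson
    mean of crosslinked reads per planted site; ``background_read_rate`` is
    reads per kb of transcript; ``conversion_prob`` is the per-read,
    per-uridine probability of recording a T-to-C at a planted position
    (background reads convert at ``background_conversion_prob``, default
    ``conversion_prob / 20``); ``secretome_slope`` is the knockdown log2
    shift per log10 crosslink read.
    """

    seed: int = 0
    n_transcripts: int = 1000
    fraction_targets: float = 0.3
    region_lengths: tuple[int, int, int] = (120, 900, 240)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_first: str = "CUUC"
    motif_second: str = "CACC"
    spacer_nt: int = 5
    tandems_per_target: int = 2
    reads_per_site: float = 30.0
    background_read_rate: float = 1.0
    conversion_prob: float = 0.2
    background_conversion_prob: float | None = None
    read_length_mean: float = 32.0
    read_length_sd: float = 6.0
    read_length_bounds: tuple[int, int] = (20, 50)
    n_replicates: int = 2
    secretome_slope: float = 0.5
    secretome_noise_sd: float = 0.2
    lfq_samples_per_group: int = 4
    lfq_replicate_sd: float = 0.2
    lfq_base_log2_mean: float = 25.0
    lfq_base_log2_sd: float = 2.0
    counts_dispersion: float = 0.05
    expression_depth: float = 50.0
    abundance_log_mean: float = math.log(8.0)
    abundance_log_sd: float = 1.2
    nontarget_shift_fraction: float = 0.0
    nontarget_shift_sd: float = 1.0
    max_spacer: int = 8

    def validate(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1 within 1e-9")
        for p in (
            self.fraction_targets,
            self.conversion_prob,
            self.nontarget_shift_fraction,
            *self.base_composition,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.background_conversion_prob is not None and not (
            0.0 <= self.background_conversion_prob <= 1.0
        ):
            raise ValueError("background_conversion_prob outside [0, 1]")
        if any(n <= 0 for n in self.region_lengths):
            raise ValueError("region lengths must be positive")
        if self.spacer_nt < 0 or self.spacer_nt > self.max_spacer:
            raise ValueError(f"spacer_nt must be in [0, {self.max_spacer}]")
        if self.tandems_per_target < 1:
            raise ValueError("tandems_per_target must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.reads_per_site <= 0:
            raise ValueError("reads_per_site must be positive")
        if self.secretome_slope < 0:
            raise ValueError("secretome_slope must be nonnegative (sign is applied internally)")

    @property
    def bg_conversion_prob(self) -> float:
        if self.background_conversion_prob is not None:
            return self.background_conversion_prob
        return self.conversion_prob / 20.0

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted: target identity, site intervals, true effects.

    ``planted_sites`` intervals are 0-based half-open transcript coordinates
    inside the CDS; ``true_mrna_log2fc`` is exactly 0 for every target;
    ``true_secretome_log2fc`` is filled by :func:`simulate_secretome` with
    the deterministic part of the knockdown shift.
    """

    target_ids: set[str] = field(default_factory=set)
    planted_sites: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_secretome_log2fc: dict[str, float] = field(default_factory=dict)
    true_mrna_log2fc: dict[str, float] = field(default_factory=dict)


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), *stream])


def _sample_concrete(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    """One concrete instance of a degenerate motif, uniform over expansions."""
    choices = sorted(motif.expand())
    return choices[rng.integers(len(choices))]


def generate_transcriptome(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Simulate transcripts and plant tandem motifs into target CDS regions.

    ``round(fraction_targets * n_transcripts)`` transcripts are designated
    targets; each receives ``tandems_per_target`` non-overlapping
    ``motif_first + spacer + motif_second`` windows written at random CDS
    positions. Non-target CDS windows that match the planted tandem by
    chance are rejection-resampled, so non-targets carry no exact tandem at
    the planted spacing.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_TRANSCRIPTOME)
    u5, cds, u3 = cfg.region_lengths
    total_len = u5 + cds + u3
    m1 = DegenerateMotif(cfg.motif_first)
    m2 = DegenerateMotif(cfg.motif_second)
    window_len = len(m1) + cfg.spacer_nt + len(m2)
    n_targets = round(cfg.fraction_targets * cfg.n_transcripts)

    target_idx = set(
        rng.choice(cfg.n_transcripts, size=n_targets, replace=False).tolist()
    )
    comp = np.asarray(cfg.base_composition)
    tandem_rx = re.compile(
        m1.to_regex().pattern + "." * cfg.spacer_nt + m2.to_regex().pattern
    )

    transcripts: list[TranscriptModel] = []
    truth = GroundTruth()
    for i in range(cfg.n_transcripts):
        tid = f"TX{i:05d}"
        seq = bytearray(rng.choice(_BASES, size=total_len, p=comp).tobytes())
        if i in target_idx:
            if cfg.tandems_per_target * window_len > cds:
                raise ValueError(
                    f"{tid}: CDS of {cds} nt cannot host {cfg.tandems_per_target} "
                    f"tandem windows of {window_len} nt"
                )
            starts = _place_windows(rng, u5, u5 + cds, window_len, cfg.tandems_per_target)
            intervals = []
            for s in starts:
                inst = (
                    _sample_concrete(m1, rng)
                    + "".join(
                        chr(b) for b in rng.choice(_BASES, size=cfg.spacer_nt, p=comp)
                    )
                    + _sample_concrete(m2, rng)
                )
                seq[s : s + window_len] = inst.encode("ascii")
                intervals.append((s, s + window_len))
            intervals.sort()
            truth.target_ids.add(tid)
            truth.planted_sites[tid] = intervals
            truth.true_mrna_log2fc[tid] = 0.0
        else:
            _scrub_chance_tandems(seq, u5, u5 + cds, tandem_rx, window_len, rng, comp)
            if cfg.nontarget_shift_fraction > 0 and rng.random() < cfg.nontarget_shift_fraction:
                truth.true_mrna_log2fc[tid] = float(
                    rng.normal(0.0, cfg.nontarget_shift_sd)
                )
            else:
                truth.true_mrna_log2fc[tid] = 0.0
        transcripts.append(
            TranscriptModel(
                id=tid,
                sequence=seq.decode("ascii"),
                utr5=(0, u5),
                cds=(u5, u5 + cds),
                utr3=(u5 + cds, total_len),
                biotype="mRNA",
            )
        )
    return transcripts, truth


def _place_windows(
    rng: np.random.Generator, lo: int, hi: int, wlen: int, count: int
) -> list[int]:
    """Non-overlapping window starts in [lo, hi - wlen]; rejection with fallback."""
    for _ in range(1000):
        starts = sorted(rng.integers(lo, hi - wlen + 1, size=count).tolist())
        if all(b - a >= wlen for a, b in zip(starts, starts[1:])):
            return starts
    # Dense case: place evenly, jitter-free (deterministic).
    stride = (hi - lo) // count
    return [lo + j * stride for j in range(count)]


def _scrub_chance_tandems(seq, lo, hi, tandem_rx, window_len, rng, comp, max_iter=100):
    """Resample CDS windows of a non-target that match the planted tandem."""
    region = seq[lo:hi].decode("ascii")
    for _ in range(max_iter):
        m = tandem_rx.search(region)
        if m is None:
            break
        s = m.start()
        repl = rng.choice(_BASES, size=window_len, p=comp).tobytes().decode("ascii")
        region = region[:s] + repl + region[s + window_len :]
    seq[lo:hi] = region.encode("ascii")


# ---------------------------------------------------------------------------
# PAR-CLIP reads


def _truncated_normal_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.read_length_bounds
    while True:
        L = int(round(rng.normal(cfg.read_length_mean, cfg.read_length_sd)))
        if lo <= L <= hi:
            return L


def simulate_parclip_replicate(
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
    replicate: int,
) -> list[AlignedRead]:
    """Simulate one crosslinking replicate: site reads plus background.

    Site reads: per planted interval, Poisson(``reads_per_site``) reads whose
    spans cover the interval midpoint, every covered T inside the interval
    converting T->C independently with ``conversion_prob``. Background
    reads: Poisson(``background_read_rate`` x length/1kb) per transcript,
    uniform start, covered Ts converting at the reduced background rate.
    """
    if not transcripts:
        raise ValueError("transcript list is empty")
    if not 1 <= replicate <= cfg.n_replicates:
        raise ValueError(f"replicate must be in [1, {cfg.n_replicates}]")
    rng = _rng(cfg, _STREAM_READS, replicate)
    reads: list[AlignedRead] = []
    counter = 0

    def _emit(tid: str, start: int, end: int, seq: str, conv_lo: int, conv_hi: int, p: float):
        nonlocal counter
        mismatches = []
        if p > 0:
            for pos in range(max(start, conv_lo), min(end, conv_hi)):
                if seq[pos] == "T" and rng.random() < p:
                    mismatches.append((pos, "T", "C"))
        reads.append(
            AlignedRead(
                transcript_id=tid,
                start=start,
                end=end,
                mismatches=tuple(mismatches),
                replicate=replicate,
                name=f"r{replicate}_{counter:07d}",
            )
        )
        counter += 1

    for tx in transcripts:
        L = len(tx)
        for (s, e) in truth.planted_sites.get(tx.id, []):
            mid = (s + e) // 2
            for _ in range(rng.poisson(cfg.reads_per_site)):
                rl = min(_truncated_normal_length(cfg, rng), L)
                lo = max(0, mid - rl + 1)
                hi = min(mid, L - rl)
                start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, min(mid, L - rl))
                _emit(tx.id, start, start + rl, tx.sequence, s, e, cfg.conversion_prob)
        n_bg = rng.poisson(cfg.background_read_rate * L / 1000.0)
        for _ in range(n_bg):
            rl = min(_truncated_normal_length(cfg, rng), L)
            start = int(rng.integers(0, L - rl + 1))
            _emit(tx.id, start, start + rl, tx.sequence, start, start + rl, cfg.bg_conversion_prob)
    return reads


# ---------------------------------------------------------------------------
# Expression and secretome


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mu``; Poisson when dispersion -> 0."""
    mu = np.maximum(mu, 1e-9)
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_expression(truth: GroundTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Per-gene observed log2 fold change from a count-sampling model.

    Each gene draws an FPKM-like abundance, converts it to expected counts
    (``abundance * expression_depth``), samples negative-binomial counts in
    both conditions (the treated mean scaled by the true fold change) and
    reports ``log2((b + 0.5) / (a + 0.5))``. Targets have true log2fc 0 by
    construction.
    """
    if not truth.true_mrna_log2fc:
        raise ValueError("ground truth has no genes; run generate_transcriptome first")
    rng = _rng(cfg, _STREAM_EXPRESSION)
    genes = list(truth.true_mrna_log2fc)
    true_lfc = np.array([truth.true_mrna_log2fc[g] for g in genes])
    abundance = rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd, size=len(genes))
    mu = abundance * cfg.expression_depth
    a = _nb_counts(rng, mu, cfg.counts_dispersion)
    b = _nb_counts(rng, mu * np.exp2(true_lfc), cfg.counts_dispersion)
    observed = np.log2((b + 0.5) / (a + 0.5))
    return pd.DataFrame(
        {"gene": genes, "log2fc": observed, "mean_abundance": abundance}
    )


def simulate_secretome(
    truth: GroundTruth,
    crosslink_reads: dict[str, int],
    cfg: SimulationConfig,
):
    """Secretome LFQ intensities with read-proportional knockdown effects.

    Control intensities are log-normal; the knockdown group shifts target
    proteins by ``-secretome_slope * log10(1 + reads) + N(0, noise_sd)`` in
    log2 units, non-targets by 0. The deterministic part of each shift is
    recorded into ``truth.true_secretome_log2fc``. Returns an
    :class:`~parclipkit.integrate.IntensityMatrix` with
    ``lfq_samples_per_group`` columns per group.
    """
    from .integrate import IntensityMatrix

    if cfg.lfq_samples_per_group < 2:
        raise ValueError("lfq_samples_per_group must be >= 2 (within-group variance)")
    if any(v < 0 for v in crosslink_reads.values()):
        raise ValueError("crosslink read counts must be nonnegative")
    rng = _rng(cfg, _STREAM_SECRETOME)
    proteins = list(crosslink_reads)
    n = len(proteins)
    k = cfg.lfq_samples_per_group
    base = rng.normal(cfg.lfq_base_log2_mean, cfg.lfq_base_log2_sd, size=n)
    # biological effect noise applies to every protein's knockdown response;
    # the deterministic read-proportional part is target-specific
    shifts = rng.normal(0.0, cfg.secretome_noise_sd, size=n)
    for i, prot in enumerate(proteins):
        if prot in truth.target_ids:
            det = -cfg.secretome_slope * math.log10(1 + crosslink_reads[prot])
            shifts[i] += det
            truth.true_secretome_log2fc[prot] = det
        else:
            truth.true_secretome_log2fc[prot] = 0.0
    ctrl = base[:, None] + rng.normal(0.0, cfg.lfq_replicate_sd, size=(n, k))
    kd = (base + shifts)[:, None] + rng.normal(0.0, cfg.lfq_replicate_sd, size=(n, k))
    cols = [f"control_{j + 1}" for j in range(k)] + [f"knockdown_{j + 1}" for j in range(k)]
    data = pd.DataFrame(
        np.exp2(np.hstack([ctrl, kd])), index=pd.Index(proteins, name="protein"), columns=cols
    )
    groups = {c: ("control" if c.startswith("control") else "knockdown") for c in cols}
    return IntensityMatrix(data=data, groups=groups)
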