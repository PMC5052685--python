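"""Core containers shared across the pipeline stages.

Coordinates are 0-based, half-open and live in transcript space throughout;
reads are pre-collapsed onto the transcript's sense strand. Sequences are
stored as upper-case DNA (U is normalized to T on ingestion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGION_NONCODING = "noncoding"

BIOTYPES = ("mRNA", "ncRNA", "rRNA", "tRNA", "other")


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map U to T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its sequence and region structure.

    ``utr5``/``cds``/``utr3`` are contiguous, non-overlapping half-open
    intervals covering ``[0, len(sequence))`` for mRNAs. For non-mRNA
    biotypes all three are empty and the whole span is noncoding.
    """

    id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.id}")
        n = len(self.sequence)
        if self.biotype == "mRNA":
            u5, c, u3 = self.utr5, self.cds, self.utr3
            if not (u5[0] == 0 and u5[1] == c[0] and c[1] == u3[0] and u3[1] == n):
                raise ValueError(
                    f"{self.id}: regions {u5}/{c}/{u3} must tile [0, {n}) contiguously"
                )
        else:
            for iv in (self.utr5, self.cds, self.utr3):
                if iv[1] != iv[0]:
                    raise ValueError(
                        f"{self.id}: non-mRNA biotype must have empty UTR/CDS intervals"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        if self.biotype != "mRNA":
            return {REGION_NONCODING: (0, len(self))}
        return {REGION_5UTR: self.utr5, REGION_CDS: self.cds, REGION_3UTR: self.utr3}


@dataclass(frozen=True)
class AlignedRead:
    """One transcriptome-aligned read with an explicit substitution list.

    ``mismatches`` holds ``(position, ref_base, read_base)`` tuples in
    transcript coordinates; the T-to-C entries carry the crosslink signal.
    """

    transcript_id: str
    start: int
    end: int
    mismatches: tuple[tuple[int, str, str], ...] = ()
    replicate: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.name or '<unnamed>'}: start must be < end")
        mm = tuple(sorted((int(p), r.upper(), a.upper()) for p, r, a in self.mismatches))
        object.__setattr__(self, "mismatches", mm)
        for p, _, _ in mm:
            if not self.start <= p < self.end:
                raise ValueError(
                    f"read {self.name or '<unnamed>'}: mismatch at {p} outside span "
                    f"[{self.start}, {self.end})"
                )

    @property
    def tc_positions(self) -> tuple[int, ...]:
        """Positions of diagnostic T-to-C conversions in this read."""
        return tuple(p for p, r, a in self.mismatches if r == "T" and a == "C")


@dataclass
class ConversionProfile:
    """Per-position coverage and mismatch tallies for one transcript.

    ``tc_events[p]`` counts distinct reads with a T-to-C substitution at
    ``p`` (each read contributes at most one); ``other_mismatches`` counts
    the remaining substitutions; ``t_mask[p]`` marks reference T positions.
    """

    transcript_id: str
    depth: np.ndarray
    tc_events: np.ndarray
    other_mismatches: np.ndarray
    t_mask: np.ndarray


@dataclass
class Cluster:
    """A maximal union of overlapping reads on one transcript."""

    transcript_id: str
    start: int
    end: int
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class BindingSite:
    """A called crosslink interval with its conversion-read support."""

    transcript_id: str
    start: int
    end: int
    tc_read_count: int
    read_depth: int
    region: str = REGION_NONCODING
    replicates_supporting: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("binding site interval must have length >= 1")
        if self.tc_read_count < 1:
            raise ValueError("binding site requires >= 1 conversion-carrying read")
        if self.tc_read_count > self.read_depth:
            raise ValueError("tc_read_count cannot exceed read_depth")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class TargetRecord:
    """Per-transcript crosslinked-read summary used for target ranking."""

    transcript_id: str
    tc_reads_per_replicate: dict[int, int]
    total_tc_reads: int
    rank: int
    passes_min4_both: bool
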