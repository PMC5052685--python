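"""RNA recognition element discovery by windowed k-mer enrichment.

The discovery route mirrors how short-RRE RNA-binding proteins are profiled
from crosslinking data: k-mer frequencies inside binding-site sequences are
compared against composition-preserving shuffles of coding sequence, the top
k-mers are collapsed into a degenerate IUPAC motif, and the tandem
arrangement of that motif is quantified as per-spacer pair enrichment.

U and T are treated as identical throughout; sequences are upper-cased on
ingestion.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

import numpy as np

from .models import normalize_sequence

logger = logging.getLogger(__name__)

#: IUPAC nucleotide classes (DNA alphabet; U is folded into T).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}

_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i
_BASE_LUT[ord("U")] = 3
_BASE_LUT[ord("u")] = 3


@dataclass(frozen=True)
class DegenerateMotif:
    """A short motif over IUPAC nucleotide classes, e.g. ``CHHC``."""

    pattern: str

    def __post_init__(self) -> None:
        pat = normalize_sequence(self.pattern)
        for ch in pat:
            if ch not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def length(self) -> int:
        return len(self.pattern)

    def expand(self) -> frozenset[str]:
        """All concrete k-mers admitted by the motif."""
        return frozenset(
            "".join(p) for p in itertools.product(*(sorted(IUPAC_SETS[c]) for c in self.pattern))
        )

    def admits(self, kmer: str) -> bool:
        kmer = normalize_sequence(kmer)
        return len(kmer) == len(self.pattern) and all(
            b in IUPAC_SETS[c] for b, c in zip(kmer, self.pattern)
        )

    def to_regex(self) -> re.Pattern:
        return re.compile(
            "".join(f"[{''.join(sorted(IUPAC_SETS[c]))}]" for c in self.pattern)
        )


@dataclass
class KmerEnrichment:
    """Enrichment of one k-mer versus a shuffle background."""

    kmer: str
    observed_freq: float
    background_mean: float
    background_sd: float
    z_score: float
    ratio: float
    flagged: bool = False


@dataclass
class SpacerEnrichment:
    """Enrichment of tandem motif pairs at one exact spacer length."""

    spacer: int
    observed_count: int
    background_mean: float
    background_sd: float
    enrichment: float
    z_score: float


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


# ---------------------------------------------------------------------------
# Shuffled backgrounds


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving exact dinucleotide counts.

    Builds the transition multigraph of the sequence and walks a random
    Eulerian path with the original first/last residues fixed.
    """
    if len(seq) <= 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]

    def _reaches_last(v: str, last_edge: dict[str, str]) -> bool:
        seen = set()
        while v != last:
            if v in seen or v not in last_edge:
                return False
            seen.add(v)
            v = last_edge[v]
        return True

    while True:
        last_edge = {
            v: outs[rng.integers(len(outs))] for v, outs in edges.items() if v != last
        }
        if all(_reaches_last(v, last_edge) for v in last_edge):
            break

    order: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v != last:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_edge[v])
        order[v] = rest

    out = [first]
    ptr = {v: 0 for v in order}
    v = first
    for _ in range(len(seq) - 1):
        nxt = order[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def shuffle_sequences(
    seqs: list[str],
    n_shuffles: int,
    mode: str = "mono",
    seed: int = 0,
) -> list[list[str]]:
    """Build a background ensemble of composition-preserving shuffles.

    ``mode='mono'`` permutes each sequence (exact mononucleotide
    conservation); ``mode='di'`` preserves dinucleotide counts exactly.
    Returns ``n_shuffles`` shuffled copies of the input list.
    """
    if not seqs:
        raise ValueError("cannot shuffle an empty sequence set")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if mode not in ("mono", "di"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    seqs = [normalize_sequence(s) for s in seqs]
    rng = np.random.default_rng(seed)
    ensemble = []
    for _ in range(n_shuffles):
        if mode == "mono":
            shuffled = [
                rng.permutation(np.frombuffer(s.encode("ascii"), dtype=np.uint8))
                .tobytes()
                .decode("ascii")
                if len(s) > 1
                else s
                for s in seqs
            ]
        else:
            shuffled = [_dinucleotide_shuffle(s, rng) for s in seqs]
        ensemble.append(shuffled)
    return ensemble


# ---------------------------------------------------------------------------
# Windowed k-mer spectra


def _encode(seq: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer code of the k-mer starting at each position plus validity."""
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        c = codes[i : i + n]
        out = out * 4 + np.where(c == 255, 0, c)
        valid &= c != 255
    return out, valid


def spectrum_array(seqs: list[str], k: int = 4, window: int = 20) -> np.ndarray:
    """Window-averaged k-mer frequency vector over all ``4**k`` k-mers.

    Windows of length ``window`` slide with step 1 over each sequence
    (shorter sequences form a single window); per-window frequencies are
    averaged uniformly over all windows pooled across sequences, so the
    output sums to 1 for unambiguous input. Sequences shorter than ``k``
    are skipped with a warning.
    """
    if k > window:
        raise ValueError("k must be <= window")
    acc = np.zeros(4**k)
    total_windows = 0
    skipped = 0
    for seq in seqs:
        s = normalize_sequence(seq)
        L = len(s)
        if L < k:
            skipped += 1
            continue
        codes, valid = _kmer_codes(_encode(s), k)
        if L <= window:
            w = np.full(L - k + 1, 1.0 / (L - k + 1))
            n_win = 1
        else:
            n_win = L - window + 1
            p = np.arange(L - k + 1)
            cnt = np.minimum(p, L - window) - np.maximum(0, p + k - window) + 1
            w = cnt / (window - k + 1)
        acc += np.bincount(codes[valid], weights=w[valid], minlength=4**k)
        total_windows += n_win
    if skipped:
        logger.warning("kmer_spectrum: skipped %d sequences shorter than k=%d", skipped, k)
    if total_windows == 0:
        raise ValueError("no sequence of length >= k supplied")
    return acc / total_windows


def kmer_spectrum(seqs: list[str], k: int = 4, window: int = 20):
    """Window-averaged k-mer frequencies as a pandas Series indexed by k-mer."""
    import pandas as pd

    return pd.Series(spectrum_array(seqs, k=k, window=window), index=all_kmers(k))


def kmer_enrichment(
    cluster_seqs: list[str],
    background: list[list[str]],
    k: int = 4,
    window: int = 20,
) -> list[KmerEnrichment]:
    """Per-k-mer z-score and ratio of cluster sequences vs shuffle spectra.

    ``background`` is an ensemble from :func:`shuffle_sequences` (>= 2
    shuffles so the empirical sd is defined). Results are sorted by z
    descending with lexicographic k-mer tie-break. A k-mer whose background
    sd is zero is flagged and reported with z = +inf if observed > mean,
    else z = 0.
    """
    if len(background) < 2:
        raise ValueError("background must contain >= 2 shuffles")
    obs = spectrum_array(cluster_seqs, k=k, window=window)
    bg = np.array([spectrum_array(s, k=k, window=window) for s in background])
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    results = []
    for kmer, o, m, s in zip(all_kmers(k), obs, mean, sd):
        flagged = False
        if s > 0:
            z = (o - m) / s
        else:
            flagged = True
            z = np.inf if o > m else 0.0
        if m > 0:
            ratio = o / m
        else:
            ratio = np.inf if o > 0 else np.nan
        results.append(KmerEnrichment(kmer, o, m, s, z, ratio, flagged))
    results.sort(key=lambda r: (-r.z_score, r.kmer))
    return results


def collapse_kmers_to_iupac(top_kmers: list[str]) -> DegenerateMotif:
    """Collapse same-length k-mers to the minimal per-position IUPAC code."""
    if not top_kmers:
        raise ValueError("need >= 1 k-mer to collapse")
    kmers = [normalize_sequence(km) for km in top_kmers]
    if len({len(km) for km in kmers}) != 1:
        raise ValueError("k-mers must all have the same length")
    pattern = []
    for column in zip(*kmers):
        bases = frozenset(column)
        pattern.append(_SET_TO_CODE[bases])
    return DegenerateMotif("".join(pattern))


def scan_motif(seq: str, motif: DegenerateMotif) -> list[int]:
    """All (possibly overlapping) match start positions of ``motif`` in ``seq``."""
    s = normalize_sequence(seq)
    rx = re.compile(f"(?=({motif.to_regex().pattern}))")
    return [m.start() for m in rx.finditer(s)]


def _pair_counts(seqs: list[str], motif: DegenerateMotif, max_spacer: int) -> np.ndarray:
    """Count, per spacer in [0, max_spacer], pairs of matches where the
    second starts exactly len(motif)+spacer after the first. One scan per
    sequence."""
    counts = np.zeros(max_spacer + 1, dtype=np.int64)
    mlen = len(motif)
    for seq in seqs:
        hits = set(scan_motif(seq, motif))
        for p in hits:
            for s in range(max_spacer + 1):
                if p + mlen + s in hits:
                    counts[s] += 1
    return counts


def tandem_spacer_enrichment(
    cluster_seqs: list[str],
    motif: DegenerateMotif,
    max_spacer: int = 8,
    background: list[list[str]] | None = None,
) -> list[SpacerEnrichment]:
    """Per-spacer enrichment of exact tandem motif pairs versus shuffles.

    The spacer is the gap between the end of the first match and the start
    of the second; pairs at every spacer in ``[0, max_spacer]`` are counted
    (overlapping motif matches are allowed, pairs are counted left to
    right). Background counts from each shuffle are rescaled to the
    observed total sequence length so foregrounds and backgrounds of
    different size are comparable.
    """
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    obs_nt = sum(len(s) for s in cluster_seqs)
    obs = _pair_counts(cluster_seqs, motif, max_spacer)
    if background:
        scaled = np.empty((len(background), max_spacer + 1))
        for j, shuffle in enumerate(background):
            bg_nt = sum(len(q) for q in shuffle)
            c = _pair_counts(shuffle, motif, max_spacer)
            scaled[j] = c * (obs_nt / bg_nt) if bg_nt else 0.0
        mean = scaled.mean(axis=0)
        sd = scaled.std(axis=0, ddof=1) if len(background) > 1 else np.zeros(max_spacer + 1)
    else:
        mean = np.zeros(max_spacer + 1)
        sd = np.zeros(max_spacer + 1)
    results = []
    for s in range(max_spacer + 1):
        count = int(obs[s])
        m, d = float(mean[s]), float(sd[s])
        enr = count / m if m > 0 else (np.inf if count > 0 else np.nan)
        z = (count - m) / d if d > 0 else (np.inf if count > m else 0.0)
        results.append(SpacerEnrichment(s, count, m, d, enr, z))
    return results
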