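"""Integration of binding evidence with transcriptome and secretome change.

Covers the proteomics side of an RNA-binding-protein target study:
median normalization of label-free (LFQ) intensities, differential
secretion by a SAM-style moderated permutation test with fudge factor s0,
stratification of genes into top / poor / non-target classes by crosslink
read rank, ECDF comparison of fold-change distributions across strata, and
the crosslink-count versus regulation correlation.

The permutation test is a re-implementation in the spirit of the classic
significance-analysis-of-microarrays procedure: the moderated statistic is
``d_i = (mean_A - mean_B) / (s_i + s0)`` with ``s_i`` the pooled two-sample
standard error, the null distribution comes from group-label permutations,
and the FDR at a cutoff is the median permuted exceedance count over the
observed exceedance count. It is compatible in spirit with, not bit-equal
to, spreadsheet implementations of the same idea.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

logger = logging.getLogger(__name__)

STRATUM_TOP = "top"
STRATUM_POOR = "poor"
STRATUM_NON = "non"


@dataclass
class IntensityMatrix:
    """Protein x sample intensity table with a two-group design.

    ``data`` holds nonnegative intensities (NaN = missing) indexed by
    protein; ``groups`` maps each sample column to its group label. On
    construction, proteins whose missing fraction exceeds ``missing_cap``
    are dropped with a log entry.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    missing_cap: float = 0.5

    def __post_init__(self) -> None:
        if set(self.data.columns) != set(self.groups):
            raise ValueError("groups must label exactly the sample columns")
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, got {labels}")
        for g in labels:
            if sum(1 for v in self.groups.values() if v == g) < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
        frac_missing = self.data.isna().mean(axis=1)
        drop = frac_missing > self.missing_cap
        if drop.any():
            logger.info(
                "IntensityMatrix: dropping %d proteins with missing fraction > %.2f",
                int(drop.sum()),
                self.missing_cap,
            )
            self.data = self.data.loc[~drop]

    @property
    def group_labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.groups.values())))  # type: ignore[return-value]

    def samples_of(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == group]


@dataclass
class SamTestResult:
    """Moderated-statistic result for one protein."""

    protein: str
    d_statistic: float
    log2fc: float
    significant: bool
    threshold_delta: float
    fdr_target: float


@dataclass
class StrataComparison:
    """ECDFs, medians, and KS comparisons of fold changes across strata."""

    ecdfs: dict[str, ECDF]
    medians: dict[str, float]
    ks: dict[tuple[str, str], tuple[float, float]]
    flagged: set[str] = field(default_factory=set)


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Scale each sample so its median equals the grand median of sample medians."""
    med = matrix.data.median(axis=0, skipna=True)
    if med.isna().any() or (med <= 0).any():
        bad = med.index[med.isna() | (med <= 0)].tolist()
        raise ValueError(f"samples with no positive observed intensities: {bad}")
    grand = float(np.median(med.values))
    scaled = matrix.data * (grand / med)
    return IntensityMatrix(data=scaled, groups=dict(matrix.groups), missing_cap=1.0)


def log2_intensities(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform intensities; nonpositive values become missing."""
    data = matrix.data.where(matrix.data > 0)
    return IntensityMatrix(data=np.log2(data), groups=dict(matrix.groups), missing_cap=1.0)


def _group_stats(x: np.ndarray, mask: np.ndarray):
    """Count, mean and variance per protein for the columns selected by mask."""
    sub = x[:, mask]
    finite = np.isfinite(sub)
    n = finite.sum(axis=1)
    s = np.where(finite, sub, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        ss = np.where(finite, (sub - mean[:, None]) ** 2, 0.0).sum(axis=1)
        var = ss / np.maximum(n - 1, 1)
    var = np.where(n > 1, var, 0.0)
    return n, mean, var


def _d_statistic(x: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray, s0: float):
    na, ma, va = _group_stats(x, mask_a)
    nb, mb, vb = _group_stats(x, mask_b)
    diff = ma - mb
    dof = np.maximum(na + nb - 2, 1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        d = diff / (si + s0)
    # constant proteins (si = 0, diff = 0, possibly s0 = 0) -> d = 0 by convention
    d = np.where(np.isfinite(d), d, 0.0)
    return d, diff


def sam_permutation_test(
    matrix: IntensityMatrix,
    s0: float = 0.5,
    n_perm: int = 250,
    fdr: float = 0.01,
    contrast: tuple[str, str] | None = None,
    seed: int = 0,
) -> list[SamTestResult]:
    """Two-group moderated permutation test with permutation-estimated FDR.

    ``matrix`` must hold log-transformed intensities. ``contrast=(A, B)``
    orients ``d`` and the fold change as A minus B; by default the
    lexicographically later group label is the test group (e.g. knockdown
    minus control). All distinct label permutations are used when fewer
    than ``n_perm`` exist; otherwise ``n_perm`` are sampled without
    replacement. ``threshold_delta`` is the smallest |d| cutoff whose
    estimated FDR (median permuted exceedances over observed exceedances)
    is <= ``fdr``; no cutoff qualifying leaves every protein nonsignificant.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10 gives an unstable FDR estimate")
    labels = matrix.group_labels
    if contrast is None:
        contrast = (labels[1], labels[0])
    ga, gb = contrast
    if {ga, gb} != set(labels):
        raise ValueError(f"contrast {contrast} does not match groups {labels}")
    cols = list(matrix.data.columns)
    x = matrix.data.to_numpy(dtype=float)
    mask_a = np.array([matrix.groups[c] == ga for c in cols])
    mask_b = ~mask_a
    d_obs, diff = _d_statistic(x, mask_a, mask_b, s0)

    n = len(cols)
    na = int(mask_a.sum())
    all_combos = list(itertools.combinations(range(n), na))
    rng = np.random.default_rng(seed)
    if len(all_combos) <= n_perm:
        combos = all_combos
    else:
        idx = rng.choice(len(all_combos), size=n_perm, replace=False)
        combos = [all_combos[i] for i in sorted(idx)]
    perm_abs = np.empty((len(combos), x.shape[0]))
    for j, combo in enumerate(combos):
        pa = np.zeros(n, dtype=bool)
        pa[list(combo)] = True
        dp, _ = _d_statistic(x, pa, ~pa, s0)
        perm_abs[j] = np.abs(dp)

    abs_obs = np.abs(d_obs)
    order = np.sort(abs_obs)
    n_prot = order.size
    exceed = np.empty((len(combos), n_prot))
    for j in range(len(combos)):
        row = np.sort(perm_abs[j])
        exceed[j] = row.size - np.searchsorted(row, order, side="left")
    median_perm = np.median(exceed, axis=0)
    obs_exceed = n_prot - np.searchsorted(order, order, side="left")
    est_fdr = median_perm / obs_exceed
    qualifying = np.flatnonzero(est_fdr <= fdr)
    threshold = float(order[qualifying[0]]) if qualifying.size else np.inf

    results = []
    for prot, d, lfc in zip(matrix.data.index, d_obs, diff):
        lfc = float(lfc) if np.isfinite(lfc) else float("nan")
        results.append(
            SamTestResult(
                protein=str(prot),
                d_statistic=float(d),
                log2fc=lfc,
                significant=bool(abs(d) >= threshold),
                threshold_delta=threshold,
                fdr_target=fdr,
            )
        )
    return results


def stratify_by_crosslink(
    target_records,
    fold_changes: pd.DataFrame,
    top_n: int = 100,
    expression_floor: float = 2.0,
) -> pd.DataFrame:
    """Label expressed genes as top / poor / non-target by crosslink rank.

    Targets are records passing the min-reads-in-both-replicates filter;
    the ``top_n`` best-ranked of them form the "top" stratum, the remaining
    passing targets "poor", and expressed genes (abundance >=
    ``expression_floor``) never captured in both replicates "non". Genes
    below the floor are excluded entirely, so the result partitions the
    expressed genes.
    """
    passing = sorted(
        (r for r in target_records if r.passes_min4_both), key=lambda r: r.rank
    )
    if top_n > len(passing):
        logger.warning(
            "top_n=%d exceeds the %d passing targets; all targets are 'top'",
            top_n,
            len(passing),
        )
    top_ids = {r.transcript_id for r in passing[:top_n]}
    poor_ids = {r.transcript_id for r in passing[top_n:]}
    out = fold_changes[fold_changes["mean_abundance"] >= expression_floor].copy()
    out["stratum"] = [
        STRATUM_TOP if g in top_ids else STRATUM_POOR if g in poor_ids else STRATUM_NON
        for g in out["gene"]
    ]
    return out.reset_index(drop=True)


def ecdf_compare(stratified: pd.DataFrame, value_col: str = "log2fc") -> StrataComparison:
    """ECDF, median, and KS-vs-non comparison for each stratum."""
    ecdfs, medians, ks, flagged = {}, {}, {}, set()
    for stratum, sub in stratified.groupby("stratum"):
        vals = sub[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"stratum {stratum!r} is empty")
        ecdfs[stratum] = ECDF(vals)
        medians[stratum] = float(np.median(vals))
    non = stratified.loc[stratified["stratum"] == STRATUM_NON, value_col].dropna()
    for stratum in (STRATUM_TOP, STRATUM_POOR):
        if stratum not in ecdfs:
            continue
        vals = stratified.loc[stratified["stratum"] == stratum, value_col].dropna()
        if len(vals) < 3 or len(non) < 3:
            ks[(stratum, STRATUM_NON)] = (float("nan"), float("nan"))
            flagged.add(stratum)
            continue
        if np.array_equal(np.sort(vals), np.sort(non)):
            ks[(stratum, STRATUM_NON)] = (0.0, 1.0)
        else:
            res = stats.ks_2samp(vals, non)
            ks[(stratum, STRATUM_NON)] = (float(res.statistic), float(res.pvalue))
    return StrataComparison(ecdfs=ecdfs, medians=medians, ks=ks, flagged=flagged)


def correlate_regulation(
    log2fc: dict[str, float] | pd.Series,
    tc_reads: dict[str, int] | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation of secretion change with log10(1 + crosslink reads)."""
    lfc = pd.Series(log2fc, dtype=float)
    reads = pd.Series(tc_reads, dtype=float)
    common = lfc.index.intersection(reads.index)
    lfc, reads = lfc[common].dropna(), reads[common]
    common = lfc.index.intersection(reads.dropna().index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    x = np.log10(1.0 + reads[common].to_numpy())
    y = lfc[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
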