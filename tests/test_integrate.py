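"""Normalization, moderated permutation test, strata and correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import parclipkit as pk
from parclipkit.integrate import (
    STRATUM_NON,
    STRATUM_POOR,
    STRATUM_TOP,
    _d_statistic,
)
from parclipkit.models import TargetRecord


def _matrix(values, groups=None):
    df = pd.DataFrame(values)
    groups = groups or {
        c: ("A" if i < len(df.columns) / 2 else "B") for i, c in enumerate(df.columns)
    }
    return pk.IntensityMatrix(data=df, groups=groups)


class TestMedianNormalize:
    def test_two_sample_example(self):
        # medians 10 and 20, grand median 15 -> scale factors 1.5 and 0.75
        m = _matrix(
            {"s1": [5.0, 10.0, 20.0], "s3": [5.0, 10.0, 20.0],
             "s2": [10.0, 20.0, 40.0], "s4": [10.0, 20.0, 40.0]},
            {"s1": "A", "s3": "A", "s2": "B", "s4": "B"},
        )
        out = pk.median_normalize(m)
        med = out.data.median(axis=0)
        assert med.tolist() == pytest.approx([15.0] * 4)
        # sample with median 10 was scaled by 1.5, the other by 0.75
        assert out.data.loc[0, "s1"] == pytest.approx(7.5)
        assert out.data.loc[0, "s2"] == pytest.approx(7.5)

    def test_equal_medians_identity(self):
        vals = {"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0],
                "c": [2.0, 1.0, 3.0], "d": [1.0, 3.0, 2.0]}
        m = _matrix(vals, {"a": "A", "b": "A", "c": "B", "d": "B"})
        out = pk.median_normalize(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_random_matrix_medians_agree(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(200, 8)),
                          columns=[f"s{i}" for i in range(8)])
        m = pk.IntensityMatrix(df, {f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
        out = pk.median_normalize(m)
        med = out.data.median(axis=0).to_numpy()
        assert np.all(np.abs(med - med[0]) < 1e-9)


class TestSamTest:
    def test_moderated_statistic_formula(self):
        # groups of 2 with sample sd chosen so the pooled s.e. is exactly 0.5
        d = np.sqrt(0.125)
        x = np.array([[10 - d, 10 + d, 8 - d, 8 + d]])
        mask_a = np.array([True, True, False, False])
        stat, diff = _d_statistic(x, mask_a, ~mask_a, s0=0.5)
        assert diff[0] == pytest.approx(2.0)
        assert stat[0] == pytest.approx(2.0 / (0.5 + 0.5))

    def test_s0_zero_reduces_to_student_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 8))
        mask_a = np.array([True] * 4 + [False] * 4)
        stat, _ = _d_statistic(x, mask_a, ~mask_a, s0=0.0)
        t = stats.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(stat, t, rtol=1e-10)

    def test_invariant_to_orderings(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(20, 1, size=(100, 8)),
                          index=[f"P{i}" for i in range(100)],
                          columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        m = pk.IntensityMatrix(df, groups)
        res = pk.sam_permutation_test(m, n_perm=70, seed=5)
        perm_rows = df.sample(frac=1.0, random_state=1)
        perm_cols = perm_rows[["s2", "s0", "s3", "s1", "s7", "s5", "s6", "s4"]]
        res2 = pk.sam_permutation_test(pk.IntensityMatrix(perm_cols, groups),
                                       n_perm=70, seed=5)
        a = {r.protein: (round(r.d_statistic, 10), r.significant) for r in res}
        b = {r.protein: (round(r.d_statistic, 10), r.significant) for r in res2}
        assert a == b

    def test_observed_and_permuted_null_distributions_agree(self):
        """Under an exchangeable null the permuted d's look like observed d's."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(300, 8))
            mask = np.array([True] * 4 + [False] * 4)
            d_obs, _ = _d_statistic(x, mask, ~mask, s0=0.5)
            perm = rng.permutation(8)
            d_perm, _ = _d_statistic(x[:, perm], mask, ~mask, s0=0.5)
            if stats.ks_2samp(d_obs, d_perm).pvalue > 0.01:
                hits += 1
        assert hits >= 9

    def test_small_permutation_count_rejected(self):
        rng = np.random.default_rng(3)
        m = _matrix(pd.DataFrame(rng.normal(size=(10, 4)),
                                 columns=["a", "b", "c", "d"]).to_dict("list"),
                    {"a": "A", "b": "A", "c": "B", "d": "B"})
        with pytest.raises(ValueError, match="n_perm"):
            pk.sam_permutation_test(m, n_perm=5)


def _records(n, passing=None):
    recs = []
    for i in range(n):
        recs.append(TargetRecord(
            transcript_id=f"G{i:03d}",
            tc_reads_per_replicate={1: 10 * (n - i), 2: 10 * (n - i)},
            total_tc_reads=20 * (n - i),
            rank=i + 1,
            passes_min4_both=True if passing is None else (i in passing),
        ))
    return recs


class TestStratify:
    def _fc(self, genes, abundance=10.0):
        return pd.DataFrame({
            "gene": genes,
            "log2fc": np.zeros(len(genes)),
            "mean_abundance": np.full(len(genes), abundance),
        })

    def test_top_and_poor_split(self):
        recs = _records(10)
        fc = self._fc([f"G{i:03d}" for i in range(20)])
        out = pk.stratify_by_crosslink(recs, fc, top_n=3)
        counts = out["stratum"].value_counts()
        assert counts[STRATUM_TOP] == 3
        assert counts[STRATUM_POOR] == 7
        assert counts[STRATUM_NON] == 10

    def test_expression_floor_excludes(self):
        recs = _records(2)
        fc = pd.DataFrame({
            "gene": ["G000", "G001", "G002"],
            "log2fc": [0.0, 0.0, 0.0],
            "mean_abundance": [10.0, 1.9, 2.0],
        })
        out = pk.stratify_by_crosslink(recs, fc, top_n=5, expression_floor=2.0)
        assert set(out["gene"]) == {"G000", "G002"}

    def test_partition_property(self):
        recs = _records(50, passing=set(range(30)))
        genes = [f"G{i:03d}" for i in range(120)]
        fc = self._fc(genes)
        out = pk.stratify_by_crosslink(recs, fc, top_n=10)
        assert len(out) == 120
        assert out.groupby("gene")["stratum"].nunique().eq(1).all()
        assert set(out["stratum"]) == {STRATUM_TOP, STRATUM_POOR, STRATUM_NON}


class TestEcdfCompare:
    def test_identical_strata(self):
        vals = np.linspace(-1, 1, 30)
        df = pd.DataFrame({
            "stratum": [STRATUM_TOP] * 30 + [STRATUM_NON] * 30,
            "log2fc": np.concatenate([vals, vals]),
        })
        comp = pk.ecdf_compare(df)
        assert comp.ks[(STRATUM_TOP, STRATUM_NON)] == (0.0, 1.0)
        assert comp.medians[STRATUM_TOP] == comp.medians[STRATUM_NON]

    def test_unit_shift_moves_median_and_ks(self):
        rng = np.random.default_rng(4)
        non = rng.normal(0, 0.3, 400)
        df = pd.DataFrame({
            "stratum": [STRATUM_TOP] * 400 + [STRATUM_NON] * 400,
            "log2fc": np.concatenate([non - 1.0, non]),
        })
        comp = pk.ecdf_compare(df)
        assert comp.medians[STRATUM_TOP] - comp.medians[STRATUM_NON] == pytest.approx(-1.0)
        stat, p = comp.ks[(STRATUM_TOP, STRATUM_NON)]
        assert stat > 0.8 and p < 1e-10

    def test_ecdf_limits(self):
        df = pd.DataFrame({"stratum": [STRATUM_NON] * 5, "log2fc": range(5)})
        comp = pk.ecdf_compare(df)
        e = comp.ecdfs[STRATUM_NON]
        assert e(-np.inf) == 0.0 and e(np.inf) == 1.0

    def test_tiny_stratum_flagged(self):
        df = pd.DataFrame({
            "stratum": [STRATUM_TOP] * 2 + [STRATUM_NON] * 10,
            "log2fc": np.arange(12, dtype=float),
        })
        comp = pk.ecdf_compare(df)
        assert STRATUM_TOP in comp.flagged
        assert np.isnan(comp.ks[(STRATUM_TOP, STRATUM_NON)][1])


class TestCorrelateRegulation:
    def test_perfect_negative(self):
        reads = {f"P{i}": 10 * (i + 1) for i in range(10)}
        lfc = {p: -np.log10(1 + r) for p, r in reads.items()}
        r, p = pk.correlate_regulation(lfc, reads)
        assert r == pytest.approx(-1.0)

    def test_constant_values_error(self):
        reads = {f"P{i}": 10 * (i + 1) for i in range(5)}
        lfc = {p: 1.0 for p in reads}
        with pytest.raises(ValueError, match="undefined"):
            pk.correlate_regulation(lfc, reads)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            pk.correlate_regulation({"a": 1.0, "b": 2.0}, {"a": 1, "b": 2})
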