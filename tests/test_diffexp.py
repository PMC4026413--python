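import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lelpipe.diffexp import (
    DesignError,
    SelectionThresholds,
    VariancePrior,
    bh_adjust,
    de_table,
    fit_linear_paired,
    fit_variance_prior,
    moderated_t,
    select_de,
)
from lelpipe.simulate import ExpressionDataset


def _paired_dataset_from_diffs(diffs):
    """Build a dataset whose within-subject differences equal ``diffs``."""
    G, n = diffs.shape
    cols, subj, cond, values = [], [], [], []
    for s in range(n):
        ref = np.full(G, 5.0)
        cols += [f"R{s+1}_0h", f"R{s+1}_5h"]
        subj += [f"R{s+1}"] * 2
        cond += ["reference", "treated"]
        values += [ref, ref + diffs[:, s]]
    mat = pd.DataFrame(np.column_stack(values), columns=cols,
                       index=pd.Index([f"P{i:03d}" for i in range(G)],
                                      name="probe_id"))
    sheet = pd.DataFrame({"sample_id": cols, "subject_id": subj,
                          "condition": cond})
    return ExpressionDataset(mat, sheet, pd.Series(mat.index, index=mat.index))


class TestPairedFit:
    def test_unit_differences(self):
        fit = fit_linear_paired(_paired_dataset_from_diffs(np.ones((3, 4))))
        assert (fit["logFC"] == 1.0).all()
        assert (fit["s2"] == 0.0).all()
        assert (fit["df_resid"] == 3).all()

    def test_hand_computed_mean_and_variance(self):
        diffs = np.array([[2.0, 1.0, 3.0, 2.0], [0.0, 0.0, 0.0, 0.0]])
        fit = fit_linear_paired(_paired_dataset_from_diffs(diffs))
        assert fit["logFC"].iloc[0] == pytest.approx(2.0)
        assert fit["s2"].iloc[0] == pytest.approx(np.var([2, 1, 3, 2], ddof=1))
        assert fit["logFC"].iloc[1] == 0.0
        assert fit["v"].iloc[0] == pytest.approx(0.25)

    def test_unpaired_subject_is_named(self):
        ds = _paired_dataset_from_diffs(np.ones((3, 2)))
        broken = ExpressionDataset(
            ds.intensities,
            ds.sample_sheet.assign(condition=["reference", "treated",
                                              "reference", "reference"]),
            ds.probe_annotation,
        )
        with pytest.raises(DesignError, match="R2"):
            fit_linear_paired(broken)

    def test_single_subject_insufficient(self):
        ds = _paired_dataset_from_diffs(np.ones((3, 1)))
        with pytest.raises(DesignError):
            fit_linear_paired(ds)


class TestVariancePrior:
    def test_recovers_scaled_inverse_chisq_parameters(self):
        rng = np.random.default_rng(42)
        d0, s0_sq, df = 4.0, 0.05, 3
        s2 = s0_sq * (rng.chisquare(df, 10_000) / df) / (rng.chisquare(d0, 10_000) / d0)
        prior = fit_variance_prior(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_constant_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(100, 0.25), 3)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25, rel=1e-6)

    def test_mixture_has_smaller_d0_than_components(self):
        """Pooling two variance populations adds dispersion, so the pooled
        prior df must be smaller than either pure-population fit."""
        rng = np.random.default_rng(7)
        df, d0 = 3, 8.0
        lo = 0.02 * (rng.chisquare(df, 5000) / df) / (rng.chisquare(d0, 5000) / d0)
        hi = 0.50 * (rng.chisquare(df, 5000) / df) / (rng.chisquare(d0, 5000) / d0)
        pooled = fit_variance_prior(np.concatenate([lo, hi]), df)
        assert pooled.d0 < fit_variance_prior(lo, df).d0
        assert pooled.d0 < fit_variance_prior(hi, df).d0

    def test_requires_enough_variances(self):
        with pytest.raises(ValueError):
            fit_variance_prior(np.ones(5), 3)


class TestModeratedT:
    def test_closed_form_oracle(self):
        prior = VariancePrior(d0=4.0, s0_sq=0.09)
        out = moderated_t(np.array([1.0]), np.array([0.04]), 3, prior, 0.25)
        s2_post = (4 * 0.09 + 3 * 0.04) / 7
        t_expected = 1.0 / np.sqrt(s2_post * 0.25)
        assert out["t"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(t_expected, 7),
                                                 rel=1e-12)
        assert out["df_total"].iloc[0] == 7

    def test_small_d0_limit_is_ordinary_t(self):
        logFC, s2, df, v = np.array([0.8]), np.array([0.2]), 3, 0.25
        prior = VariancePrior(d0=1e-9, s0_sq=1.0)
        out = moderated_t(logFC, s2, df, prior, v)
        t_ord = logFC[0] / np.sqrt(s2[0] * v)
        assert out["t"].iloc[0] == pytest.approx(t_ord, rel=1e-6)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(t_ord, df), rel=1e-4)

    def test_infinite_d0_uses_prior_variance_and_normal_tail(self):
        prior = VariancePrior(d0=np.inf, s0_sq=0.09)
        out = moderated_t(np.array([0.6, -0.6]), np.array([0.5, 0.001]), 3,
                          prior, 0.25)
        t_expected = 0.6 / np.sqrt(0.09 * 0.25)
        assert out["t"].iloc[0] == pytest.approx(t_expected)
        assert out["t"].iloc[1] == pytest.approx(-t_expected)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(t_expected))

    def test_zero_posterior_variance_flagged(self):
        # d0 * s0_sq underflows to exactly zero, as does df * s2
        prior = VariancePrior(d0=1e-200, s0_sq=1e-200)
        out = moderated_t(np.array([1.0]), np.array([0.0]), 3, prior, 0.25)
        assert np.isinf(out["t"].iloc[0]) and out["t"].iloc[0] > 0
        assert out["p"].iloc[0] == 0.0
        assert bool(out["underflow"].iloc[0])

    def test_matches_limma_on_shared_fixture(self, tmp_path):
        """Independent cross-check: same per-probe differences through
        the reference R implementation."""
        rng = np.random.default_rng(8)
        G, n = 300, 4
        sd = np.sqrt(0.05 * 4.0 / rng.chisquare(4.0, G))
        diffs = rng.normal(0, sd[:, None], (G, n))
        diffs[:20] += 1.5
        logFC, s2 = diffs.mean(1), diffs.var(1, ddof=1)
        prior = fit_variance_prior(s2, n - 1)
        mine = moderated_t(logFC, s2, n - 1, prior, 1.0 / n)
        pd.DataFrame(diffs).to_csv(tmp_path / "diffs.tsv", sep="\t", index=False)
        script = tmp_path / "cross.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'd <- as.matrix(read.delim("{tmp_path}/diffs.tsv"))\n'
            'fit <- eBayes(lmFit(d, design=matrix(1, ncol(d), 1)))\n'
            'out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],'
            ' d0=fit$df.prior, s0=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-8)
        np.testing.assert_allclose(mine["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-8)


def _bh_oracle(p):
    """Literal step-up definition: adj_p(i) = min_{p(j) >= p(i)} min(1, m p(j)/rank(j))."""
    p = list(p)
    m = len(p)
    ranked = sorted(p)
    out = []
    for pi in p:
        candidates = [
            min(1.0, m * pj / (k + 1))
            for k, pj in enumerate(ranked)
            if pj >= pi
        ]
        out.append(min(candidates))
    return np.array(out)


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust(np.array([0.05]))[0] == pytest.approx(0.05)

    def test_all_equal_stay_equal(self):
        adj = bh_adjust(np.full(7, 0.03))
        np.testing.assert_allclose(adj, 0.03)

    def test_known_vector_matches_step_up_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), rtol=1e-12)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12))
    def test_matches_oracle_on_fuzzed_vectors(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(np.maximum(p, 1e-300)),
                                   rtol=1e-10, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestSelectDE:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "logFC", "adj_p"])

    def test_empty_table(self):
        up, down = select_de(pd.DataFrame(columns=["gene", "logFC", "adj_p"]))
        assert up.empty and down.empty

    def test_fold_change_boundary_excludes(self):
        t = self._table([["A", 0.5, 0.001]])
        up, down = select_de(t, SelectionThresholds(0.01, 1.0))
        assert up.empty and down.empty

    def test_signs_split_up_down(self):
        t = self._table([["A", 2.0, 0.001], ["B", -1.5, 0.001],
                         ["C", 1.2, 0.5], ["D", -3.0, 0.009]])
        up, down = select_de(t, SelectionThresholds(0.01, 1.0))
        assert list(up["gene"]) == ["A"]
        assert list(down["gene"]) == ["D", "B"]

    def test_gene_collapse_keeps_best_probe(self):
        t = self._table([["A", 2.0, 0.005], ["A", 3.0, 0.001]])
        up, _ = select_de(t, SelectionThresholds(0.01, 1.0), collapse_genes=True)
        assert len(up) == 1
        assert up["adj_p"].iloc[0] == 0.001
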