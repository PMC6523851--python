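"""Voom transform, moderated statistics and the FC/p selection gate."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from komix.differential import (
    DifferentialResult,
    estimate_prior,
    fit_moderated,
    run_differential,
    select_differential,
    trigamma_inverse,
    voom_transform,
)
from komix.io_formats import FeatureTable, ValidationError


def _table(values: np.ndarray, scale="log2", prefix="f") -> FeatureTable:
    n, m = values.shape
    cols = [f"A{i}" for i in range(m // 2)] + [f"B{i}" for i in range(m // 2)]
    return FeatureTable(
        values=pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(n)],
                            columns=cols),
        scale=scale,
    )


class TestVoom:
    def test_logcpm_formula_at_zero_count(self, two_group_design):
        # a zero count in a library of size 999,999 gives exactly -1
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 2000, (50, 10)).astype(float)
        counts[0, 0] = 0.0
        counts[1, 0] += 999_999 - counts[:, 0].sum()
        fit = voom_transform(_table(counts, scale="counts"), two_group_design)
        assert fit.logcpm.values.iat[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_identical_counts_give_equal_finite_weights(self, two_group_design):
        counts = np.tile(np.arange(1, 13, dtype=float)[:, None], (1, 10))
        fit = voom_transform(_table(counts, scale="counts"), two_group_design)
        w = fit.weights.to_numpy()
        assert np.all(np.isfinite(w)) and np.all(w > 0)
        assert np.allclose(w, w[0, 0])

    def test_high_count_features_get_higher_weight(self, two_group_design):
        # NB counts: the sqrt-sd trend decreases with count over the bulk,
        # so the weight of a high-count feature exceeds a low-count one
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(3, 1.5, 500))
        size = 10.0
        counts = rng.negative_binomial(size, size / (size + mu[:, None]),
                                       (500, 10)).astype(float)
        fit = voom_transform(_table(counts, scale="counts"), two_group_design)
        order = np.argsort(mu)
        w_mean = fit.weights.to_numpy().mean(axis=1)
        low = w_mean[order[:100]].mean()
        high = w_mean[order[-100:]].mean()
        assert high > low

    def test_zero_library_size_is_an_error(self, two_group_design):
        counts = np.ones((5, 10))
        counts[:, 3] = 0.0
        with pytest.raises(ValidationError) as err:
            voom_transform(_table(counts, scale="counts"), two_group_design)
        assert "A3" in str(err.value)

    def test_trend_clamped_outside_fitted_range(self, two_group_design):
        rng = np.random.default_rng(2)
        counts = rng.integers(10, 100, (40, 10)).astype(float)
        fit = voom_transform(_table(counts, scale="counts"), two_group_design)
        assert fit.trend(np.array([-100.0]))[0] == fit.trend_y[0]
        assert fit.trend(np.array([100.0]))[0] == fit.trend_y[-1]


class TestModeratedFit:
    def test_degenerate_zero_variance_is_floored(self, two_group_design):
        y = np.zeros((20, 10))
        y[:, :5] = 2.0  # beta exactly 2, no within-group noise
        rng = np.random.default_rng(3)
        y[5:] = rng.normal(0, 1, (15, 10))  # others carry noise
        res = fit_moderated(_table(y), two_group_design, ("A", "B"))
        row = res.table.iloc[0]
        assert row.log2fc == pytest.approx(2.0)
        assert np.isfinite(row.t_mod) and row.direction == "up"

    def test_prior_df_zero_equals_ordinary_t(self, two_group_design):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, (200, 10))
        res = fit_moderated(_table(y), two_group_design, ("A", "B"),
                            prior_df=0)
        mu_a, mu_b = y[:, :5].mean(1), y[:, 5:].mean(1)
        resid = np.concatenate(
            [y[:, :5] - mu_a[:, None], y[:, 5:] - mu_b[:, None]], axis=1)
        s2 = (resid**2).sum(1) / 8
        t_ord = (mu_a - mu_b) / np.sqrt(s2 * (1 / 5 + 1 / 5))
        assert np.allclose(res.table.t_mod.to_numpy(), t_ord, atol=1e-12)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), 8)
        assert np.allclose(res.table.p_raw.to_numpy(), p_ord, atol=1e-12)

    def test_infinite_prior_df_pools_variances(self, two_group_design):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (200, 10))
        res = fit_moderated(_table(y), two_group_design, ("A", "B"),
                            prior_df=np.inf)
        mu_a, mu_b = y[:, :5].mean(1), y[:, 5:].mean(1)
        resid = np.concatenate(
            [y[:, :5] - mu_a[:, None], y[:, 5:] - mu_b[:, None]], axis=1)
        s2 = (resid**2).sum(1) / 8
        _, s0_sq = estimate_prior(s2, 8)
        t_inf = (mu_a - mu_b) / np.sqrt(s0_sq * (2 / 5))
        assert np.allclose(res.table.t_mod.to_numpy(), t_inf, rtol=1e-12)

    def test_t_statistic_monotone_in_effect(self, two_group_design):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, (1, 10))
        base[0, :5] -= base[0, :5].mean()   # equal group means at shift 0
        base[0, 5:] -= base[0, 5:].mean()
        y = np.tile(base, (6, 1)).astype(float)
        shifts = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        for i, s in enumerate(shifts):
            y[i, :5] += s
        res = fit_moderated(_table(y), two_group_design, ("A", "B"))
        t_abs = np.abs(res.table.t_mod.to_numpy())
        assert np.all(np.diff(t_abs) > 0)

    def test_prior_estimation_recovers_known_df(self):
        # variances drawn from a scaled inverse chi-square with d0=8
        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 8.0, 1.3, 8
        s2_true = d0_true * s0_true / rng.chisquare(d0_true, 50_000)
        s2_obs = s2_true * rng.chisquare(d, 50_000) / d
        d0, s0 = estimate_prior(s2_obs, df=d)
        assert d0 == pytest.approx(d0_true, rel=0.1)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_trigamma_inverse_solves_trigamma(self):
        from scipy.special import polygamma
        for x in (1e-5, 0.01, 0.5, 2.0, 100.0, 1e8):
            y = trigamma_inverse(x)
            assert float(polygamma(1, y)) == pytest.approx(x, rel=1e-8)

    def test_confidence_interval_brackets_estimate(self, two_group_design):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, (500, 10))
        res = fit_moderated(_table(y), two_group_design, ("A", "B"))
        t = res.table
        assert ((t.ci_low <= t.log2fc) & (t.log2fc <= t.ci_high)).all()

    def test_matches_limma_ebayes_reference(self, two_group_design, tmp_path):
        """Moderated t, p and prior df agree with the R limma reference."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(42)
        y = rng.normal(5, 1, (50, 10))
        y[:5, :5] += 2
        table = _table(y)
        table.values.to_csv(tmp_path / "y.tsv", sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'y <- as.matrix(read.delim("{tmp_path}/y.tsv", row.names=1))\n'
            'design <- model.matrix(~0+factor(c(rep("A",5),rep("B",5)),'
            ' levels=c("A","B")))\n'
            'colnames(design) <- c("A","B")\n'
            'fit <- eBayes(contrasts.fit(lmFit(y, design),'
            ' makeContrasts(A-B, levels=design)))\n'
            'out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],'
            ' df=fit$df.total)\n'
            f'write.table(out, "{tmp_path}/r.tsv", sep="\\t",'
            ' row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        res = fit_moderated(table, two_group_design, ("A", "B"))
        assert np.allclose(res.table.t_mod, ref.t, atol=1e-10)
        assert np.allclose(res.table.p_raw, ref.p, atol=1e-10)
        assert res.table.df_total.iloc[0] == pytest.approx(ref.df.iloc[0],
                                                           rel=1e-9)


class TestSelectionGate:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (1.0, 0.049, "up"),    # exactly FC 2 with p below the gate
            (0.99, 0.001, "ns"),   # fails the fold-change gate
            (3.0, 0.051, "ns"),    # fails the p gate
            (-1.0, 0.05, "down"),  # boundary values are inclusive
        ],
    )
    def test_fc_and_p_gate(self, log2fc, p, expected):
        table = pd.DataFrame(
            [{"feature": "f", "contrast": "A-B", "log2fc": log2fc,
              "se": 0.1, "ci_low": log2fc - 0.2, "ci_high": log2fc + 0.2,
              "t_mod": 5.0, "df_total": 10.0, "p_raw": p, "fdr": p,
              "direction": ""}])
        table["direction"] = np.where(
            (table.log2fc >= 1) & (table.p_raw <= 0.05), "up",
            np.where((table.log2fc <= -1) & (table.p_raw <= 0.05),
                     "down", "ns"))
        res = DifferentialResult(table=table)
        up, down = select_differential(res)
        got = "up" if "f" in up else ("down" if "f" in down else "ns")
        assert got == expected

    def test_gate_applied_by_fit(self, two_group_design):
        y = np.zeros((3, 10))
        rng = np.random.default_rng(9)
        y += rng.normal(0, 0.05, (3, 10))
        y[0, :5] += 2.0   # clear up
        y[1, :5] -= 2.0   # clear down
        res = fit_moderated(_table(y), two_group_design, ("A", "B"))
        up, down = select_differential(res)
        assert up == {"f0"} and down == {"f1"}


class TestRunDifferential:
    def test_voom_on_log2_table_is_an_error(self, two_group_design):
        y = _table(np.random.default_rng(0).normal(0, 1, (20, 10)))
        with pytest.raises(ValidationError):
            run_differential(y, two_group_design, [("A", "B")], use_voom=True)

    def test_deterministic_and_order_invariant(self, two_group_design):
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 200, (60, 10)).astype(float)
        t = _table(counts, scale="counts")
        r1 = run_differential(t, two_group_design, [("A", "B")])
        r2 = run_differential(t, two_group_design, [("A", "B")])
        pd.testing.assert_frame_equal(r1.table, r2.table)
        # permute sample columns; design is keyed by sample id so the
        # result must not change
        perm = list(t.values.columns[::-1])
        tp = FeatureTable(values=t.values[perm], scale="counts")
        r3 = run_differential(tp, two_group_design, [("A", "B")])
        pd.testing.assert_frame_equal(r1.table, r3.table)

    def test_null_calibration_gaussian(self, two_group_design):
        rng = np.random.default_rng(11)
        y = _table(rng.normal(0, 1, (2000, 10)))
        res = run_differential(y, two_group_design, [("A", "B")])
        frac = (res.table.p_raw <= 0.05).mean()
        assert 0.03 <= frac <= 0.07
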