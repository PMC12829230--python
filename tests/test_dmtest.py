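import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from gbsmedip.dmtest import (
    adjust_pvalues,
    attach_adjusted,
    fit_f_dist,
    log2_cpm,
    mann_whitney_matrix,
    moderated_t_matrix,
    mw_exact_cdf,
    nb_lrt_matrix,
    read_external_pvalues,
    trigamma_inverse,
)


def mw_enumeration_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    u_max = n1 * len(y)
    stat_obs = min(u_obs, u_max - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = u_of(idx)
        if min(u, u_max - u) <= stat_obs:
            count += 1
        total += 1
    return count / total


def frame(rows, n1, n2):
    cols = [f"s{i}" for i in range(n1 + n2)]
    design = pd.Series(["a"] * n1 + ["b"] * n2, index=cols)
    return pd.DataFrame(np.atleast_2d(rows), columns=cols,
                        index=[f"w{i}" for i in range(np.atleast_2d(rows).shape[0])]), design


class TestMannWhitney:
    def test_perfect_separation_matches_enumeration(self):
        x, y = [1, 2, 3, 4, 5], [6, 7, 8, 9, 10]
        df, design = frame(x + y, 5, 5)
        res = mann_whitney_matrix(df, design)
        assert res.p_value[0] == pytest.approx(2 / 252)
        assert res.p_value[0] == pytest.approx(mw_enumeration_pvalue(x, y))

    def test_exact_path_matches_enumeration_generally(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.permutation(np.arange(10, dtype=float))  # tie-free
            df, design = frame(vals, 5, 5)
            res = mann_whitney_matrix(df, design)
            assert res.p_value[0] == pytest.approx(
                mw_enumeration_pvalue(vals[:5], vals[5:])
            )

    def test_identical_groups_p_one(self):
        df, design = frame([3, 1, 4, 3, 1, 4], 3, 3)
        res = mann_whitney_matrix(df, design)
        assert res.p_value[0] == 1.0

    def test_single_observation_per_group_p_one(self):
        df, design = frame([1.0, 2.0], 1, 1)
        res = mann_whitney_matrix(df, design)
        assert res.p_value[0] == 1.0

    def test_constant_window_p_one(self):
        df, design = frame([5.0] * 10, 5, 5)
        assert mann_whitney_matrix(df, design).p_value[0] == 1.0

    def test_matches_scipy_on_mixed_matrix(self, ten_sample_design):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 30, size=(200, 10)).astype(float)
        df = pd.DataFrame(x, columns=ten_sample_design.index,
                          index=[f"w{i}" for i in range(200)])
        res = mann_whitney_matrix(df, ten_sample_design)
        for i in range(200):
            g1, g2 = x[i, :5], x[i, 5:]
            if np.ptp(x[i]) == 0:
                expected = 1.0
            elif len(np.unique(x[i])) == 10:
                expected = stats.mannwhitneyu(g1, g2, method="exact").pvalue
            else:
                expected = stats.mannwhitneyu(g1, g2, method="asymptotic").pvalue
            assert res.p_value[i] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, ten_sample_design):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 5.0, size=(50, 10))
        df1 = pd.DataFrame(x, columns=ten_sample_design.index)
        df2 = pd.DataFrame(np.log1p(3 * x), columns=ten_sample_design.index)
        p1 = mann_whitney_matrix(df1, ten_sample_design).p_value
        p2 = mann_whitney_matrix(df2, ten_sample_design).p_value
        assert np.allclose(p1, p2)

    def test_label_swap_leaves_p_unchanged(self, ten_sample_design):
        rng = np.random.default_rng(9)
        x = rng.poisson(8.0, size=(40, 10)).astype(float)
        df = pd.DataFrame(x, columns=ten_sample_design.index)
        swapped = pd.Series(
            np.where(ten_sample_design == "a", "b", "a"), index=ten_sample_design.index
        )
        p1 = mann_whitney_matrix(df, ten_sample_design).p_value
        p2 = mann_whitney_matrix(df, swapped).p_value
        assert np.allclose(p1, p2)

    def test_exact_cdf_total_mass(self):
        for n1, n2 in [(3, 4), (5, 5), (2, 6)]:
            cdf = mw_exact_cdf(n1, n2)
            assert cdf[-1] == pytest.approx(1.0)
            assert len(cdf) == n1 * n2 + 1

    def test_more_than_two_groups_rejected(self):
        df, _ = frame([1, 2, 3, 4, 5, 6], 3, 3)
        design = pd.Series(["a", "a", "b", "b", "c", "c"], index=df.columns)
        with pytest.raises(ValueError, match="two groups"):
            mann_whitney_matrix(df, design)


class TestModeratedT:
    def test_zero_mean_difference_gives_p_one(self):
        rows = np.array([[4, 6, 5, 4, 6, 5]], dtype=float)
        df, design = frame(rows, 3, 3)
        eff = pd.Series(np.full(6, 100.0), index=df.columns)
        res = moderated_t_matrix(df, design, eff_sizes=eff)
        assert res.effect[0] == pytest.approx(0.0)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_unmoderated_equals_ordinary_t(self, small_counts):
        eff = small_counts.counts.sum(axis=0).astype(float)
        logcpm = log2_cpm(small_counts.counts, eff_sizes=eff).to_numpy()
        res = moderated_t_matrix(
            small_counts.counts, small_counts.design, eff_sizes=eff, moderate=False
        )
        for i in range(logcpm.shape[0]):
            t, p = stats.ttest_ind(logcpm[i, 3:], logcpm[i, :3], equal_var=True)
            assert res.p_value[i] == pytest.approx(p, abs=1e-12)

    def test_matches_formula_oracle(self, ten_sample_design):
        """Direct scalar transcription of the moderated-t formulas."""
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.3, size=(50, 10)),
            index=[f"w{i}" for i in range(50)],
            columns=ten_sample_design.index,
        )
        eff = counts.sum(axis=0).astype(float)
        res = moderated_t_matrix(counts, ten_sample_design, eff_sizes=eff)

        lib = eff.to_numpy()
        pc = 0.5 * lib / lib.mean()
        logcpm = np.log2((counts.to_numpy() + pc) / (lib + 2 * pc) * 1e6)
        d = logcpm[:, 5:].mean(axis=1) - logcpm[:, :5].mean(axis=1)
        s2 = np.array(
            [
                (
                    np.sum((logcpm[i, :5] - logcpm[i, :5].mean()) ** 2)
                    + np.sum((logcpm[i, 5:] - logcpm[i, 5:].mean()) ** 2)
                )
                / 8.0
                for i in range(50)
            ]
        )
        z = np.log(s2)
        e = z - special.digamma(4.0) + np.log(4.0)
        evar = e.var(ddof=1) - special.polygamma(1, 4.0)
        assert evar > 0  # this fixture has cross-window variance spread
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s0 + 8.0 * s2) / (d0 + 8.0)
        t = d / np.sqrt(s2_post * (1 / 5 + 1 / 5))
        p = 2 * stats.t.sf(np.abs(t), d0 + 8.0)
        assert np.allclose(res.p_value.to_numpy(), p, atol=1e-8)
        assert np.allclose(res.effect.to_numpy(), d, atol=1e-8)

    def test_matches_limma_ebayes(self, tmp_path, two_group_design):
        """Independent cross-check against limma's lmFit + eBayes."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            rng.negative_binomial(2, 0.1, size=(150, 6)) + 1,
            index=[f"w{i}" for i in range(150)],
            columns=two_group_design.index,
        )
        eff = df.sum(axis=0).astype(float)
        counts_path = tmp_path / "counts.tsv"
        df.to_csv(counts_path, sep="\t")
        script = tmp_path / "modt.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages({{library(edgeR); library(limma)}})
                x <- as.matrix(read.delim("{counts_path}", row.names=1))
                dge <- DGEList(counts=x, norm.factors=rep(1, 6))
                lcpm <- cpm(dge, log=TRUE, prior.count=0.5)
                grp <- factor(c("a","a","a","b","b","b"))
                fit <- eBayes(lmFit(lcpm, model.matrix(~grp)))
                cat(sprintf("%.12g", fit$p.value[,2]), sep="\\n")
                """
            )
        )
        res_r = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in res_r.stdout.split()])
        res = moderated_t_matrix(df, two_group_design, eff_sizes=eff)
        assert np.allclose(res.p_value.to_numpy(), expected, atol=1e-8)

    def test_trigamma_inverse_roundtrip(self):
        for y in [0.01, 0.5, 2.0, 37.0]:
            x = special.polygamma(1, y)
            assert trigamma_inverse(float(x)) == pytest.approx(y, rel=1e-8)


def nb_loglik_scalar(y, mu, r):
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + np.where(y > 0, y * np.log(mu / (r + mu)), 0.0)
        )
    )


class TestNbLrt:
    def test_identical_columns_give_null_stat(self):
        df, design = frame([[4, 4, 4, 4, 4, 4], [7, 7, 7, 7, 7, 7]], 3, 3)
        eff = pd.Series(np.ones(6), index=df.columns)
        res = nb_lrt_matrix(df, design, eff_sizes=eff)
        assert np.allclose(res.p_value, 1.0, atol=1e-6)

    def test_all_zero_window_p_one(self):
        df, design = frame([[0, 0, 0, 0, 0, 0]], 3, 3)
        eff = pd.Series(np.ones(6), index=df.columns)
        res = nb_lrt_matrix(df, design, eff_sizes=eff)
        assert res.p_value[0] == 1.0
        assert not res.converged[0]

    def test_large_fixed_dispersion_recovers_poisson_lrt(self):
        y = np.array([3.0, 5, 4, 12, 15, 9])
        df, design = frame(y, 3, 3)
        eff = pd.Series(np.ones(6), index=df.columns)
        res = nb_lrt_matrix(df, design, eff_sizes=eff, dispersion=1e8)
        m1, m2, m0 = y[:3].mean(), y[3:].mean(), y.mean()
        lrt = 2 * (np.sum(y[:3] * np.log(m1 / m0)) + np.sum(y[3:] * np.log(m2 / m0)))
        assert res.p_value[0] == pytest.approx(stats.chi2.sf(lrt, 1), rel=1e-5)

    def test_matches_profile_grid_oracle(self):
        """MLE fits agree with a brute-force profile search of the NB likelihood."""
        y = np.array([[2.0, 8, 5, 20, 11, 16]])
        df, design = frame(y, 3, 3)
        eff = pd.Series(np.ones(6), index=df.columns)
        res = nb_lrt_matrix(df, design, eff_sizes=eff)

        def prof_alt(r):
            f1 = optimize.minimize_scalar(
                lambda m: -nb_loglik_scalar(y[0, :3], m, r), bounds=(1e-3, 200), method="bounded"
            ).fun
            f2 = optimize.minimize_scalar(
                lambda m: -nb_loglik_scalar(y[0, 3:], m, r), bounds=(1e-3, 200), method="bounded"
            ).fun
            return f1 + f2

        rs = np.exp(np.linspace(-4, 12, 3000))
        vals = [prof_alt(r) for r in rs]
        r_hat = rs[int(np.argmin(vals))]
        ll_alt = -min(vals)
        ll_null = -optimize.minimize_scalar(
            lambda m: -nb_loglik_scalar(y[0], m, r_hat), bounds=(1e-3, 200), method="bounded"
        ).fun
        lrt = max(2 * (ll_alt - ll_null), 0.0)
        assert res.p_value[0] == pytest.approx(stats.chi2.sf(lrt, 1), abs=1e-4)

    def test_offsets_shift_the_null(self):
        # doubling one group's library sizes should absorb a doubled mean
        y = np.array([[5.0, 7, 6, 12, 13, 11]])
        df, design = frame(y, 3, 3)
        eff_flat = pd.Series(np.ones(6), index=df.columns)
        eff_comp = pd.Series([1, 1, 1, 2, 2, 2], index=df.columns, dtype=float)
        p_flat = nb_lrt_matrix(df, design, eff_sizes=eff_flat).p_value[0]
        p_comp = nb_lrt_matrix(df, design, eff_sizes=eff_comp).p_value[0]
        assert p_comp > p_flat  # offsets explain the difference away


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03], "BH")[0] == pytest.approx(0.03)
        assert adjust_pvalues([0.03], "bonferroni")[0] == pytest.approx(0.03)

    def test_bonferroni_direct_product(self):
        assert np.allclose(adjust_pvalues([0.03, 0.03, 0.03], "bonferroni"), 0.09)

    def test_empty_vector(self):
        assert adjust_pvalues([], "BH").size == 0

    def test_bh_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        bh = adjust_pvalues(p, "BH")
        bonf = adjust_pvalues(p, "bonferroni")
        assert (bh >= p - 1e-15).all()
        assert (bh <= bonf + 1e-15).all()

    def test_bh_restores_input_order(self):
        p = np.array([0.9, 0.001, 0.5, 0.04])
        bh = adjust_pvalues(p, "BH")
        # the smallest raw p must map to the smallest adjusted p, in place
        assert np.argmin(bh) == 1

    def test_attach_adjusted_columns(self):
        res = pd.DataFrame(
            {"window_id": ["w1", "w2"], "method": "mw", "effect": [0, 1],
             "p_value": [0.01, 0.5]}
        )
        out = attach_adjusted(res)
        assert {"p_BH", "p_bonferroni"} <= set(out.columns)
        assert (out["p_BH"] >= out["p_value"]).all()


class TestExternalAdapter:
    def test_round_trip_and_validation(self, tmp_path):
        path = tmp_path / "ext.tsv"
        pd.DataFrame(
            {"window_id": ["w1", "w2"], "method": "deseq2", "p": [0.2, 0.9]}
        ).to_csv(path, sep="\t", index=False)
        out = read_external_pvalues(path)
        assert list(out["p_value"]) == [0.2, 0.9]

    def test_rejects_out_of_range_p(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame(
            {"window_id": ["w1"], "method": "x", "p": [0.0]}
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="0, 1"):
            read_external_pvalues(path)


def test_null_simulation_fpr_within_binomial_band(ten_sample_design):
    """Under a true null (identical NB distributions in both groups, n=5+5),
    each test's p < 0.05 rate stays at or below the 3-sigma binomial band
    around 0.05 (the rank test is conservative by discreteness)."""
    rng = np.random.default_rng(77)
    m = 4000
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.25, size=(m, 10)),
        index=[f"w{i}" for i in range(m)],
        columns=ten_sample_design.index,
    )
    eff = counts.sum(axis=0).astype(float)
    band = 0.05 + 3 * np.sqrt(0.05 * 0.95 / m)
    p_mw = mann_whitney_matrix(counts.astype(float), ten_sample_design).p_value
    p_t = moderated_t_matrix(counts, ten_sample_design, eff_sizes=eff).p_value
    assert (p_mw < 0.05).mean() <= band
    assert (p_t < 0.05).mean() <= band
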