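"""Voom-style precision weights and the empirical-Bayes moderated t-test."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncdyn.spatial import SpatialDEModel, estimate_prior, voom_weights


def nb_counts(mean, disp, rng):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mean))


def null_frame(rng, n=500, reps=3, mean_range=(20, 2000), disp=0.1):
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n))
    cols = [nb_counts(mu, disp, rng) for _ in range(2 * reps)]
    return pd.DataFrame(np.column_stack(cols), index=[f"g{i}" for i in range(n)],
                        columns=[f"s{j}" for j in range(2 * reps)])


DESIGN_3V3 = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)]])
GROUPS = ["A"] * 3 + ["B"] * 3


class TestVoomWeights:
    def test_weights_positive_finite(self, rng):
        counts = null_frame(rng)
        logcpm, w = voom_weights(counts, DESIGN_3V3)
        assert np.all(w.values > 0) and np.all(np.isfinite(w.values))
        assert logcpm.shape == w.shape == counts.shape

    def test_degenerate_equal_counts(self):
        counts = pd.DataFrame(np.full((20, 6), 50.0))
        logcpm, w = voom_weights(counts, DESIGN_3V3)
        assert np.all(np.isfinite(w.values)) and np.all(w.values > 0)

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3)))
        design = np.column_stack([np.ones(3), [0, 1, 1]])
        with pytest.raises(ValueError):
            voom_weights(counts, design)

    def test_rank_deficient_design_rejected(self, rng):
        counts = null_frame(rng)
        bad = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError):
            voom_weights(counts, bad)

    def test_mean_variance_trend_decreasing_then_flat(self):
        """NB counts: sqrt-sd trend falls with log-count and levels off (20 seeds)."""
        from statsmodels.nonparametric.smoothers_lowess import lowess
        drops, tails = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = null_frame(rng, n=800, mean_range=(5, 5000))
            logcpm, _ = voom_weights(counts, DESIGN_3V3)
            pinv = np.linalg.pinv(DESIGN_3V3)
            resid = logcpm.values - (logcpm.values @ pinv.T) @ DESIGN_3V3.T
            s2 = (resid ** 2).sum(axis=1) / 4
            x = logcpm.values.mean(axis=1)
            lo = lowess(np.sqrt(np.sqrt(s2)), x, frac=0.5, return_sorted=True)
            third = len(lo) // 3
            first, mid, last = lo[:third, 1], lo[third:2 * third, 1], lo[2 * third:, 1]
            drops.append(first.mean() - mid.mean())
            tails.append(abs(mid.mean() - last.mean()))
        assert np.mean(drops) > 0          # decreasing at low counts
        assert np.mean(tails) < np.mean(drops)  # then comparatively flat


class TestPriorEstimation:
    def test_recovers_chisquare_prior(self, rng):
        d0, s0_2, d = 8.0, 2.0, 4
        sigma2 = s0_2 * d0 / rng.chisquare(d0, size=20000)
        s2 = sigma2 * rng.chisquare(d, size=20000) / d
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0_2, rel=0.1)

    def test_common_variance_gives_infinite_d0(self, rng):
        s2 = np.full(500, 1.7) * rng.chisquare(4, 500) / 4
        d0_hat, s0_hat = estimate_prior(s2, 4)
        # spread equals the chi-square noise floor: prior df diverges
        assert d0_hat > 50 or np.isinf(d0_hat)


class TestModeratedT:
    def test_known_variance_limit_equals_z(self, rng):
        """d0 -> inf with known common variance reduces to the z-statistic."""
        counts = null_frame(rng, n=200)
        model = SpatialDEModel(counts, GROUPS, "A", "B")
        res = model.fit(use_weights=False, prior_df=np.inf, prior_var=0.5)
        logcpm, _ = voom_weights(counts, DESIGN_3V3)
        y = logcpm.values
        pinv = np.linalg.pinv(DESIGN_3V3)
        beta = y @ pinv.T
        u2 = np.linalg.inv(DESIGN_3V3.T @ DESIGN_3V3)[1, 1]
        z = beta[:, 1] / np.sqrt(0.5 * u2)
        assert np.max(np.abs(res.table["t"].values - z)) < 1e-6
        assert np.max(np.abs(res.table["p_value"].values
                             - 2 * stats.norm.sf(np.abs(z)))) < 1e-9

    def test_label_swap_negates_logfc_keeps_p(self, rng):
        counts = null_frame(rng, n=300)
        res = SpatialDEModel(counts, GROUPS, "A", "B").fit()
        swapped = SpatialDEModel(counts, ["B"] * 3 + ["A"] * 3, "A", "B").fit()
        assert np.allclose(res.table.log2fc.values, -swapped.table.log2fc.values)
        assert np.allclose(res.table.p_value.values, swapped.table.p_value.values)

    def test_shrunken_variance_between_s2_and_prior(self, rng):
        counts = null_frame(rng, n=400)
        res = SpatialDEModel(counts, GROUPS, "A", "B").fit()
        t = res.table
        lo = np.minimum(t.s2, res.s0_2) - 1e-12
        hi = np.maximum(t.s2, res.s0_2) + 1e-12
        assert np.all((t.s2_post >= lo) & (t.s2_post <= hi))

    def test_equal_weights_matches_ols_ebayes_oracle(self, rng):
        """Unweighted path equals an independent per-gene OLS + shrinkage chain."""
        counts = null_frame(rng, n=200)
        model = SpatialDEModel(counts, GROUPS, "A", "B")
        res = model.fit(use_weights=False)
        logcpm, _ = voom_weights(counts, DESIGN_3V3)
        import statsmodels.api as sm
        beta1, s2 = [], []
        for i in range(len(counts)):
            ols = sm.OLS(logcpm.values[i], DESIGN_3V3).fit()
            beta1.append(ols.params[1])
            s2.append(ols.ssr / ols.df_resid)
        beta1, s2 = np.array(beta1), np.array(s2)
        d0, s0_2 = estimate_prior(s2, 4)
        s2_post = (np.full_like(s2, s0_2) if np.isinf(d0)
                   else (d0 * s0_2 + 4 * s2) / (d0 + 4))
        u2 = np.linalg.inv(DESIGN_3V3.T @ DESIGN_3V3)[1, 1]
        t = beta1 / np.sqrt(s2_post * u2)
        assert np.max(np.abs(res.table.log2fc.values - beta1)) < 1e-8
        assert np.max(np.abs(res.table["t"].values - t)) < 1e-8

    def test_enrichment_call_consistency(self, rng):
        counts = null_frame(rng, n=300)
        res = SpatialDEModel(counts, GROUPS, "A", "B").fit(alpha=0.05)
        t = res.table
        assert ((t.enriched != "none") == (t.p_value < 0.05)).all()
        assert (t.loc[t.enriched == "B", "log2fc"] > 0).all()
        assert (t.loc[t.enriched == "A", "log2fc"] < 0).all()
        assert ((t.p_value > 0) & (t.p_value <= 1)).all()

    def test_fdr_flag_adds_bh_adjustment(self, rng):
        counts = null_frame(rng, n=300)
        res = SpatialDEModel(counts, GROUPS, "A", "B").fit(fdr=True)
        from statsmodels.stats.multitest import multipletests
        expect = multipletests(res.table.p_value.values, method="fdr_bh")[1]
        assert np.allclose(res.table.p_adj.values, expect)
        assert ((res.table.enriched != "none") == (res.table.p_adj < 0.05)).all()

    def test_summary_renders(self, rng):
        res = SpatialDEModel(null_frame(rng, n=50), GROUPS, "A", "B").fit()
        text = res.summary()
        assert "prior df" in text and "enriched" in text


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
def test_agrees_with_limma_voom_reference(tmp_path, rng):
    """Independent oracle: Bioconductor limma-voom on the same counts.

    Property-level parity: matching fold-changes, near-identical p-value
    ranking and the same calls at alpha=0.05.
    """
    mu = np.exp(rng.uniform(np.log(20), np.log(2000), 300))
    fc = np.ones(300)
    fc[:30], fc[30:60] = 4.0, 0.25
    counts = np.column_stack([nb_counts(mu, 0.1, rng) for _ in range(3)]
                             + [nb_counts(mu * fc, 0.1, rng) for _ in range(3)])
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(300)],
                      columns=[f"s{j}" for j in range(6)])
    df.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f'counts <- as.matrix(read.delim("{tmp_path / "counts.tsv"}", row.names=1))\n'
        'group <- factor(c("A","A","A","B","B","B"), levels=c("A","B"))\n'
        'design <- model.matrix(~group)\n'
        'fit <- eBayes(lmFit(voom(counts, design), design))\n'
        'tab <- topTable(fit, coef=2, number=Inf, sort.by="none")\n'
        f'write.table(data.frame(id=rownames(tab), logFC=tab$logFC, P=tab$P.Value),\n'
        f'            "{tmp_path / "limma.tsv"}", sep="\\t", row.names=FALSE, quote=FALSE)\n')
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
    res = SpatialDEModel(df, GROUPS, "A", "B").fit()
    mine = res.table.loc[lim.index]
    assert np.corrcoef(lim.logFC, mine.log2fc)[0, 1] > 0.999
    assert np.max(np.abs(lim.logFC - mine.log2fc)) < 0.05
    assert stats.spearmanr(lim.P, mine.p_value)[0] > 0.99
    assert ((lim.P < 0.05) == (mine.p_value < 0.05)).mean() >= 0.98
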