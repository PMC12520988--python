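import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteoflow import diffabund, synth
from proteoflow.io import IntensityMatrix, SampleMetadata


def two_group_matrix(rng, n_proteins=100, n=5, delta=0.0, sigma=0.5):
    cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    y = rng.normal(20, 2, size=(n_proteins, 1)) + rng.normal(0, sigma, (n_proteins, 2 * n))
    y[:, :n] += delta
    values = pd.DataFrame(y, index=[f"P{i}" for i in range(n_proteins)], columns=cols)
    meta = SampleMetadata(pd.DataFrame(
        {"group": ["A"] * n + ["B"] * n,
         "age": rng.integers(40, 70, 2 * n),
         "sex": rng.choice(["F", "M"], 2 * n)},
        index=pd.Index(cols, name="sample_id")))
    return IntensityMatrix(values, scale="log2"), meta


class TestFitLinearModels:
    def test_logfc_is_group_mean_difference(self):
        values = pd.DataFrame({"a1": [12.0], "a2": [12.0], "b1": [10.0], "b2": [10.0]})
        m = IntensityMatrix(values, scale="log2")
        meta = SampleMetadata(pd.DataFrame({"group": ["A", "A", "B", "B"]},
                                           index=values.columns))
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        assert fit.coefficients.at[0, "A-B"] == pytest.approx(2.0)
        assert fit.amean.iloc[0] == pytest.approx(11.0)

    def test_orthogonal_covariate_leaves_logfc_unchanged(self, rng):
        m, meta = two_group_matrix(rng, 50, n=6)
        # covariate perfectly balanced across groups => orthogonal to contrast
        meta.table["cov"] = np.tile([-1.0, 0.0, 1.0], 4)
        d0 = diffabund.build_design(meta, "group", ("A", "B"))
        d1 = diffabund.build_design(meta, "group", ("A", "B"), covariates=["cov"])
        f0 = diffabund.fit_linear_models(m, d0)
        f1 = diffabund.fit_linear_models(m, d1)
        assert np.allclose(f0.coefficients["A-B"], f1.coefficients["A-B"])

    def test_underobserved_protein_excluded_and_flagged(self, rng):
        m, meta = two_group_matrix(rng, 5, n=3)
        values = m.values.copy()
        values.iloc[0, 1:] = np.nan  # observed in a single sample
        m = IntensityMatrix(values, scale="log2")
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        assert "P0" in fit.excluded
        assert np.isnan(fit.sigma2.loc["P0"])

    def test_rank_deficient_design_names_aliased_column(self, rng):
        m, meta = two_group_matrix(rng, 5, n=3)
        meta.table["dup"] = (meta.table["group"] == "A").astype(float)
        with pytest.raises(ValueError, match="dup"):
            diffabund.build_design(meta, "group", ("A", "B"), covariates=["dup"])


class TestModeration:
    def test_prior_df_zero_recovers_ordinary_t(self, rng):
        m, meta = two_group_matrix(rng, 80)
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        res = diffabund.moderate_statistics(fit, trend=False, prior_df=0.0)
        ordinary = fit.coefficients["A-B"] / (np.sqrt(fit.sigma2) * fit.stdev_unscaled)
        assert np.allclose(res.table["t"], ordinary)

    def test_prior_df_infinite_recovers_fully_shrunk_t(self, rng):
        m, meta = two_group_matrix(rng, 80)
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        res = diffabund.moderate_statistics(fit, trend=False, prior_df=np.inf)
        s20 = res.hyper.s2_prior
        limit = fit.coefficients["A-B"] / (np.sqrt(s20) * fit.stdev_unscaled)
        assert np.allclose(res.table["t"], limit)

    def test_moderated_t_magnitude_between_limits(self, rng):
        """s2_post is a convex combination of s2 and s2_prior, so |t| lies
        between the ordinary and fully shrunk statistics."""
        m, meta = two_group_matrix(rng, 200, sigma=0.7)
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        mod = diffabund.moderate_statistics(fit, trend=False).table["t"].abs()
        raw = diffabund.moderate_statistics(fit, trend=False, prior_df=0).table["t"].abs()
        lim = diffabund.moderate_statistics(fit, trend=False, prior_df=np.inf).table["t"].abs()
        lo = np.minimum(raw, lim) - 1e-12
        hi = np.maximum(raw, lim) + 1e-12
        assert ((mod >= lo) & (mod <= hi)).all()

    def test_power_monotone_in_effect_size(self):
        sens = []
        for lfc in (0.5, 1.0, 2.0):
            design = synth.two_group_design(600, 8, seed=21)
            eff = synth.SimEffects(var_individual=0, var_workflow=0, var_fixation=0,
                                   var_residual=0.25, de_fraction=0.2, de_log2fc=lfc)
            m, truth = synth.simulate_intensity_dataset(design, eff)
            d = diffabund.build_design(design.metadata(), "group", ("case", "control"))
            res = diffabund.moderate_statistics(diffabund.fit_linear_models(m, d))
            de = truth.per_protein["true_lfc"] != 0
            sig = res.table["adj.P.Val"] < 0.05
            sens.append((sig & de).sum() / de.sum())
        assert sens[0] <= sens[1] <= sens[2]

    def test_all_zero_variances_rejected(self):
        values = pd.DataFrame(np.tile([[1.0, 1, 2, 2]], (12, 1)),
                              columns=list("abcd"))
        m = IntensityMatrix(values, scale="log2")
        meta = SampleMetadata(pd.DataFrame({"group": list("AABB")}, index=list("abcd")))
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        with pytest.raises(ValueError):
            diffabund.moderate_statistics(fit, trend=False)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaOracle:
    def test_moderated_t_matches_limma(self, tmp_path, rng):
        """Independent cross-check of the moderation pipeline against the
        reference Bioconductor implementation on a small synthetic matrix."""
        m, meta = two_group_matrix(rng, 150, n=5, delta=0.3, sigma=0.6)
        m.values.to_csv(tmp_path / "mat.tsv", sep="\t")
        meta.table[["group"]].to_csv(tmp_path / "meta.tsv", sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'mat <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))\n'
            f'meta <- read.delim("{tmp_path}/meta.tsv", row.names=1)\n'
            'X <- model.matrix(~factor(meta$group, levels=c("B","A")))\n'
            'fe <- eBayes(lmFit(mat, X), trend=FALSE)\n'
            'tt <- topTable(fe, coef=2, number=Inf, sort.by="none")\n'
            'write.table(data.frame(id=rownames(tt), t=tt$t, p=tt$P.Value),\n'
            f'  "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)\n')
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        design = diffabund.build_design(meta, "group", ("A", "B"))
        fit = diffabund.fit_linear_models(m, design)
        res = diffabund.moderate_statistics(fit, trend=False)
        assert np.abs(res.table["t"] - oracle["t"]).max() < 1e-4
        assert np.abs(res.table["P.Value"] - oracle["p"]).max() < 1e-6


class TestConsensusCorrelation:
    @staticmethod
    def blocked_matrix(rng, rho, n_proteins=600, n_blocks=6, reps=2):
        cols = [f"b{b}_r{r}" for b in range(n_blocks) for r in range(reps)]
        blocks = np.repeat(np.arange(n_blocks), reps)
        u = rng.normal(size=(n_proteins, n_blocks))
        y = (np.sqrt(rho) * u[:, blocks]
             + np.sqrt(1 - rho) * rng.normal(size=(n_proteins, len(cols))) + 20)
        m = IntensityMatrix(pd.DataFrame(y, index=[f"P{i}" for i in range(n_proteins)],
                                         columns=cols), scale="log2")
        design = diffabund.Design(np.ones((len(cols), 1)), ["Intercept"], cols,
                                  "Intercept", block=blocks)
        return m, design

    @pytest.mark.parametrize("rho", [0.5, 0.0])
    def test_recovers_simulated_block_correlation(self, rng, rho):
        m, design = self.blocked_matrix(rng, rho)
        est = diffabund.estimate_consensus_correlation(m, design)
        assert est == pytest.approx(rho, abs=0.05)

    def test_singleton_blocks_rejected(self, rng):
        m, design = self.blocked_matrix(rng, 0.3, n_proteins=5, n_blocks=4, reps=1)
        with pytest.raises(ValueError):
            diffabund.estimate_consensus_correlation(m, design)

    def test_gls_with_correlation_changes_inference_not_estimate(self, rng):
        m, design = self.blocked_matrix(rng, 0.6, n_proteins=40)
        f_ols = diffabund.fit_linear_models(m, design)
        f_gls = diffabund.fit_linear_models(m, design, correlation=0.6)
        # intercept-only model: the estimate is a weighted mean, close to OLS
        assert np.allclose(f_ols.coefficients["Intercept"],
                           f_gls.coefficients["Intercept"], atol=0.5)
        assert not np.allclose(f_ols.sigma2, f_gls.sigma2)


class TestAdjustBH:
    def test_printed_vectors_match_enumeration(self):
        """Step-up oracle: adj_i = min_{j>=i} min(1, p_(j) * n / j)."""
        def enumerate_bh(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * n / (rank + 1))
                adj[i] = running
            return adj

        for p in ([0.01, 0.02, 0.03, 0.04], [0.005, 0.1], [0.2],
                  [0.04, 0.01, 0.03, 0.02]):
            assert np.allclose(diffabund.adjust_bh(p), enumerate_bh(np.asarray(p)))
        assert np.allclose(diffabund.adjust_bh([0.01, 0.02, 0.03, 0.04]), 0.04)
        assert np.allclose(diffabund.adjust_bh([0.005, 0.1]), [0.01, 0.1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            diffabund.adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            diffabund.adjust_bh([-0.1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_adjusted_dominates_raw_and_stays_in_unit_interval(self, p):
        adj = diffabund.adjust_bh(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert ((adj >= 0) & (adj <= 1)).all()


class TestCompareTStatistics:
    def test_identical_and_negated(self, rng):
        m, meta = two_group_matrix(rng, 30)
        design = diffabund.build_design(meta, "group", ("A", "B"))
        res = diffabund.moderate_statistics(diffabund.fit_linear_models(m, design),
                                            trend=False)
        assert diffabund.compare_tstatistics(res, res) == pytest.approx(1.0)
        flipped = diffabund.DEResult(res.table.assign(t=-res.table["t"]), res.hyper)
        assert diffabund.compare_tstatistics(res, flipped) == pytest.approx(-1.0)

    def test_covariate_free_vs_covariate_model_concordant(self, rng):
        m, meta = two_group_matrix(rng, 300, n=6, delta=0.5)
        meta.table["cov"] = np.tile([-1.0, 0.0, 1.0], 4)
        d0 = diffabund.build_design(meta, "group", ("A", "B"))
        d1 = diffabund.build_design(meta, "group", ("A", "B"), covariates=["cov"])
        r0 = diffabund.moderate_statistics(diffabund.fit_linear_models(m, d0))
        r1 = diffabund.moderate_statistics(diffabund.fit_linear_models(m, d1))
        assert diffabund.compare_tstatistics(r0, r1) >= 0.99

    def test_too_few_shared_proteins_rejected(self, rng):
        m, meta = two_group_matrix(rng, 30)
        design = diffabund.build_design(meta, "group", ("A", "B"))
        res = diffabund.moderate_statistics(diffabund.fit_linear_models(m, design),
                                            trend=False)
        tiny = diffabund.DEResult(res.table.iloc[:2], res.hyper)
        with pytest.raises(ValueError):
            diffabund.compare_tstatistics(res, tiny)
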