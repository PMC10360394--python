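"""Burden regressions, BH-FDR, locus permutation FWER, sex LRT."""

import numpy as np
import pandas as pd
import pytest

from cnvcohort import bh_fdr, geneset_burden, global_burden, locus_burden, select_top_gene_sets, sex_burden_lrt
from cnvcohort.burden import BurdenModelSpec, _ols
from cnvcohort.genes import BurdenMatrix, _main_columns


def _matrix(main, gene_sets=None, genes=None):
    idx = main.index
    return BurdenMatrix(
        main=main,
        gene_sets=gene_sets if gene_sets is not None else pd.DataFrame(index=idx),
        genes=genes if genes is not None else pd.DataFrame(index=idx),
    )


def _main_frame(n, rng, del_rate=0.8):
    idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
    main = pd.DataFrame(0, index=idx, columns=_main_columns(), dtype=float)
    main["gene_count_DEL_rare"] = rng.poisson(del_rate, n)
    main["gene_count_DUP_rare"] = rng.poisson(del_rate, n)
    main["gene_count_total"] = main["gene_count_DEL_rare"] + main["gene_count_DUP_rare"]
    main["total_length_DEL"] = rng.exponential(2e5, n) * (main["gene_count_DEL_rare"] > 0)
    main["total_length_DUP"] = rng.exponential(2e5, n) * (main["gene_count_DUP_rare"] > 0)
    return main


class TestBhFdr:
    def test_stepup_hand_computed(self):
        q = bh_fdr(pd.Series([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr(pd.Series([0.3])).iloc[0] == pytest.approx(0.3)
        assert bh_fdr(pd.Series([1.0])).iloc[0] == pytest.approx(1.0)

    def test_nan_propagates(self):
        q = bh_fdr(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(q.iloc[1]) and q.notna().sum() == 2

    def test_families_adjusted_separately(self):
        p = pd.Series([0.01, 0.02, 0.01, 0.02])
        fam = pd.Series(["x", "x", "y", "y"])
        q = bh_fdr(p, fam)
        assert np.allclose(q, [0.02, 0.02, 0.02, 0.02])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = np.sort(rng.random(int(rng.integers(2, 10))))
        # independent brute-force BH step-up
        m = len(p)
        q_expected = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, p[i] * m / (i + 1))
            q_expected[i] = running
        q = bh_fdr(pd.Series(p))
        assert np.allclose(q, q_expected, atol=1e-12)
        assert (np.diff(q) >= -1e-12).all()  # monotone in rank order


class TestOlsAgainstNormalEquations:
    @pytest.mark.parametrize("seed", range(3))
    def test_small_design_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        X = pd.DataFrame({"x": rng.normal(size=n), "c1": rng.normal(size=n)})
        y = pd.Series(1.0 + 0.5 * X["x"] - 0.2 * X["c1"] + rng.normal(size=n))
        res = _ols(y, X, "x")
        # direct normal-equations solve
        A = np.column_stack([np.ones(n), X["x"], X["c1"]])
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert res.estimate == pytest.approx(beta[1], abs=1e-8)

    def test_constant_predictor_flagged(self):
        X = pd.DataFrame({"x": np.zeros(30), "c": np.arange(30.0)})
        y = pd.Series(np.random.default_rng(0).normal(size=30))
        res = _ols(y, X, "x")
        assert "constant_predictor" in res.flags

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        X = pd.DataFrame({"x": x, "c1": x * 2.0, "c2": rng.normal(size=40)})
        with pytest.raises(ValueError, match="collinear"):
            _ols(pd.Series(rng.normal(size=40)), X, "x")


class TestGlobalBurden:
    def test_planted_beta_recovered(self, rng):
        n = 5000
        main = _main_frame(n, rng)
        beta = 0.15
        y = beta * main["gene_count_DEL_rare"] + rng.normal(0, 1, n)
        pheno = pd.DataFrame({"trait": y}, index=main.index)
        spec = BurdenModelSpec(outcome="trait", predictor="gene_count_DEL_rare")
        res = global_burden(spec, _matrix(main), pheno)
        assert res.ci_low < beta < res.ci_high

    def test_permuted_outcome_is_null(self, rng):
        n = 2000
        main = _main_frame(n, rng)
        y = 0.3 * main["gene_count_DEL_rare"] + rng.normal(0, 1, n)
        pheno = pd.DataFrame({"trait": rng.permutation(y.to_numpy())}, index=main.index)
        res = global_burden(BurdenModelSpec("trait", "gene_count_DEL_rare"), _matrix(main), pheno)
        assert res.ci_low < 0 < res.ci_high

    def test_confounder_adjustment_removes_bias(self, rng):
        n = 4000
        main = _main_frame(n, rng)
        conf = rng.normal(size=n)  # drives both burden and trait
        main["gene_count_DEL_rare"] = main["gene_count_DEL_rare"] + np.round(
            np.clip(conf, 0, None) * 2
        )
        y = 1.0 * conf + rng.normal(0, 1, n)  # no direct burden effect
        pheno = pd.DataFrame({"trait": y}, index=main.index)
        cov = pd.DataFrame({"PC1": conf}, index=main.index)
        spec = BurdenModelSpec("trait", "gene_count_DEL_rare")
        biased = global_burden(spec, _matrix(main), pheno)
        adjusted = global_burden(spec, _matrix(main), pheno, covariates=cov)
        assert biased.estimate > adjusted.estimate
        assert adjusted.ci_low < 0 < adjusted.ci_high
        assert not (biased.ci_low < 0 < biased.ci_high)

    def test_unknown_predictor_rejected(self, rng):
        main = _main_frame(50, rng)
        with pytest.raises(KeyError):
            global_burden(BurdenModelSpec("t", "no_such_column"), _matrix(main),
                          pd.DataFrame({"t": np.zeros(50)}, index=main.index))


def _geneset_cohort(rng, n=4000, n_sets=6, beta=0.4, inflate=0.0):
    """Direct generator of set counts with one causal set and a global load."""
    idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
    main = pd.DataFrame(0, index=idx, columns=_main_columns(), dtype=float)
    counts = {}
    for j in range(n_sets):
        counts[f"s{j}|DEL|rare"] = rng.poisson(0.3, n)
    gs = pd.DataFrame(counts, index=idx, dtype=float)
    total = gs.to_numpy().sum(axis=1)
    main["gene_count_DEL_rare"] = total
    main["gene_count_total"] = total
    y = beta * gs["s0|DEL|rare"] + inflate * total + rng.normal(0, 1, n)
    pheno = pd.DataFrame({"trait": y}, index=idx)
    return _matrix(main, gene_sets=gs), pheno


class TestGenesetBurden:
    def test_causal_set_has_smallest_q(self, rng):
        matrix, pheno = _geneset_cohort(rng)
        out = geneset_burden(matrix, pheno, "trait")
        best = out.loc[out["q"].idxmin()]
        assert best["gene_set"] == "s0"
        assert best["beta"] > 0

    def test_control_set_is_null(self, rng):
        matrix, pheno = _geneset_cohort(rng)
        out = geneset_burden(matrix, pheno, "trait").set_index("gene_set")
        assert out.loc["s5", "ci_low"] < 0 < out.loc["s5", "ci_high"]

    def test_global_correction_separates_nonspecific_inflation(self, rng):
        # trait driven by TOTAL burden only: with correction no set stands out,
        # without it every set shows a spurious positive effect
        matrix, pheno = _geneset_cohort(rng, beta=0.0, inflate=0.3)
        corrected = geneset_burden(matrix, pheno, "trait")
        assert (corrected["p"] < 0.05).sum() <= 1
        uncorr = []
        y = pheno["trait"]
        for col in matrix.gene_sets.columns:
            res = _ols(y, pd.DataFrame({"set_count": matrix.gene_sets[col]}), "set_count")
            uncorr.append(res.p)
        assert (np.array(uncorr) < 0.05).sum() >= 4

    def test_zero_carrier_set_skipped(self, rng):
        matrix, pheno = _geneset_cohort(rng, n=200)
        matrix.gene_sets["dead|DEL|rare"] = 0.0
        out = geneset_burden(matrix, pheno, "trait").set_index("gene_set")
        assert bool(out.loc["dead", "skipped"])

    def test_top_set_selection_thresholds(self):
        res = pd.DataFrame(
            {"gene_set": ["a", "b", "c"], "p": [0.01, 0.04, 0.2], "q": [0.1, 0.5, 0.9]}
        )
        assert select_top_gene_sets(res) == ["a"]


class TestLocusBurden:
    def _cohort(self, rng, n=3000, causal_carriers=25, effect=2.0, n_null_genes=15):
        idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
        main = pd.DataFrame(0, index=idx, columns=_main_columns(), dtype=float)
        genes = {}
        for j in range(n_null_genes):
            k = int(rng.integers(3, 12))
            col = np.zeros(n)
            col[rng.choice(n, k, replace=False)] = 1
            genes[f"null{j}|DEL"] = col
        causal = np.zeros(n)
        causal[rng.choice(n, causal_carriers, replace=False)] = 1
        genes["causal|DEL"] = causal
        genes["twocarrier|DEL"] = np.zeros(n)
        genes["twocarrier|DEL"][:2] = 1
        gmat = pd.DataFrame(genes, index=idx)
        y = effect * causal + rng.normal(0, 1, n)
        pheno = pd.DataFrame({"trait": y}, index=idx)
        return _matrix(main, genes=gmat), pheno

    def test_min_carrier_filter_excludes_two_carrier_gene(self, rng):
        matrix, pheno = self._cohort(rng)
        out, _ = locus_burden(matrix, pheno, "trait", None, n_permutations=200, seed=1)
        assert "twocarrier" not in set(out["gene"])

    def test_planted_gene_passes_fwer(self, rng):
        matrix, pheno = self._cohort(rng)
        out, info = locus_burden(matrix, pheno, "trait", None, n_permutations=500, seed=1)
        row = out.set_index("gene").loc["causal"]
        assert row["p"] < 0.05 and row["p_fwer"] < 0.05
        assert info["t_threshold_fwer05"] > 0

    def test_gene_universe_restriction(self, rng):
        matrix, pheno = self._cohort(rng)
        out, _ = locus_burden(matrix, pheno, "trait", {"causal"}, n_permutations=100, seed=1)
        assert set(out["gene"]) == {"causal"}

    def test_no_qualifying_genes_returns_reason(self, rng):
        matrix, pheno = self._cohort(rng)
        out, info = locus_burden(matrix, pheno, "trait", {"absent_gene"}, n_permutations=100, seed=1)
        assert out.empty and "reason" in info


class TestSexLrt:
    def test_null_and_planted_effects(self, rng):
        n = 5000
        main = _main_frame(n, rng)
        sex = pd.Series(rng.choice(["male", "female"], n), index=main.index)
        out_null = sex_burden_lrt(_matrix(main), sex).set_index("outcome")
        assert (out_null["lrt"] >= 0).all()  # deviance difference non-negativity
        # plant +20% male deletion length
        main2 = main.copy()
        male = (sex == "male").to_numpy()
        main2.loc[male, "total_length_DEL"] *= 1.5
        out = sex_burden_lrt(_matrix(main2), sex).set_index("outcome")
        assert out.loc["total_length_DEL", "p"] < 0.05
        assert out_null.loc["total_length_DUP", "p"] > 0.01

    def test_single_sex_skipped(self, rng):
        main = _main_frame(100, rng)
        out = sex_burden_lrt(_matrix(main), pd.Series(["male"] * 100, index=main.index))
        assert out.iloc[0]["note"] == "single-sex cohort"
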