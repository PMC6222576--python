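"""Inclusion filter, per-site model fits, and the genome scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resistscan import (
    CategoryCounts,
    MISSING,
    PlantedLocus,
    SimConfig,
    candidate_table,
    category_counts,
    fit_binomial_glmm,
    fit_lognormal_aft,
    gwas_scan,
    impute_missing,
    filter_sites,
    infer_resistant_allele,
    nested_scan,
    simulate_binomial,
    simulate_panel,
    simulate_survival,
    site_passes_filter,
)
from conftest import make_binomial, make_survival


class TestCategoryCounts:
    def test_basic_cross_tab(self):
        g = np.array([0] * 5 + [1] * 5)
        w = np.array([True] * 5 + [False] * 5)
        c = category_counts(g, w)
        assert c.as_tuple() == (5, 0, 0, 5)

    def test_all_missing(self):
        g = np.full(6, MISSING)
        w = np.array([True, False] * 3)
        assert category_counts(g, w).as_tuple() == (0, 0, 0, 0)

    def test_matches_loop_recount(self):
        rng = np.random.default_rng(5)
        g = rng.choice([0, 1, MISSING], size=200)
        w = rng.random(200) < 0.5
        c = category_counts(g, w)
        expected = [0, 0, 0, 0]
        for gi, wi in zip(g, w):
            if gi == MISSING:
                continue
            expected[(0 if wi else 2) + gi] += 1
        assert list(c.as_tuple()) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CategoryCounts(-1, 0, 0, 0)


class TestSitePassesFilter:
    @pytest.mark.parametrize(
        "counts, ok, reason",
        [
            ((5, 5, 5, 5), True, "ok"),
            ((5, 5, 5, 2), True, "ok"),
            ((5, 5, 4, 4), False, "sparse"),
            ((100, 0, 0, 94), False, "collinear"),
            ((0, 100, 94, 0), False, "collinear"),
            ((100, 0, 94, 0), False, "sparse"),  # zero column is not diagonal
            ((5, 5, 0, 0), False, "sparse"),  # zero row falls through to sparsity
            ((5, 5, 5, 0), True, "ok"),
        ],
    )
    def test_verdicts(self, counts, ok, reason):
        verdict, why = site_passes_filter(CategoryCounts(*counts))
        assert verdict is ok
        assert why == reason

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_pure_function_of_counts(self, counts):
        a = site_passes_filter(CategoryCounts(*counts))
        b = site_passes_filter(CategoryCounts(*counts))
        assert a == b
        # verdict logic is internally consistent
        verdict, why = a
        if verdict:
            assert why == "ok"
        else:
            assert why in ("collinear", "sparse")


class TestLognormalAft:
    def test_intercept_only_closed_form(self):
        # 10 deaths at 5h + 10 at 24h, no censoring, no covariates, no REs:
        # MLE is the mean / ML variance of log t
        table = make_survival([["L1", "e1", "v1", 20, 0, 10, 0, 10, 0]])
        fit = fit_lognormal_aft(table, metadata=None, snp=None, random_effects=())
        logt = np.log(np.array([5.0] * 10 + [24.0] * 10))
        assert fit.coefficients["intercept"] == pytest.approx(logt.mean(), abs=1e-8)
        assert fit.scale == pytest.approx(logt.std(), abs=1e-8)

    def test_two_group_shift_closed_form(self):
        table = make_survival(
            [
                ["A", "e1", "v1", 20, 5, 10, 5, 0, 0],
                ["B", "e1", "v1", 20, 0, 5, 10, 5, 0],
            ]
        )
        fit = fit_lognormal_aft(
            table, metadata=None, snp=pd.Series({"A": 0, "B": 1}), random_effects=()
        )
        la = np.log(np.r_[[2.5] * 5, [5] * 10, [11] * 5])
        lb = np.log(np.r_[[5] * 5, [11] * 10, [24] * 5])
        assert fit.coefficients["snp"] == pytest.approx(lb.mean() - la.mean(), abs=1e-6)

    def test_censoring_shifts_estimate_up(self):
        uncens = make_survival([["A", "e1", "v1", 20, 0, 0, 10, 10, 0]])
        cens = make_survival([["A", "e1", "v1", 25, 0, 0, 10, 10, 0]])  # 5 censored
        f0 = fit_lognormal_aft(uncens, metadata=None, random_effects=())
        f1 = fit_lognormal_aft(cens, metadata=None, random_effects=())
        assert f1.coefficients["intercept"] > f0.coefficients["intercept"]

    def test_allele_relabel_flips_beta_keeps_p(self):
        cfg = SimConfig(
            n_lines=60, n_sites_per_arm=10, seed=17,
            resistance_loci=[
                PlantedLocus("2R", 250_000, 0.4, effect_survival=0.8, tag="major")
            ],
        )
        panel, meta, truth = simulate_panel(cfg)
        table = simulate_survival(panel, meta, truth, seed=17)
        j = panel.site_index("2R", 250_000)
        g = pd.Series(panel.calls[:, j].astype(int), index=panel.lines)
        fit1 = fit_lognormal_aft(table, meta, snp=g, include_interaction=False)
        fit2 = fit_lognormal_aft(table, meta, snp=1 - g, include_interaction=False)
        assert fit1.coefficients["snp"] == pytest.approx(
            -fit2.coefficients["snp"], rel=1e-4
        )
        assert np.log(fit1.p_snp) == pytest.approx(np.log(fit2.p_snp), abs=1e-3)

    def test_all_carriers_censored_flagged_separation(self):
        rows = [
            ["A", "e1", "v1", 10, 0, 5, 5, 0, 0],
            ["B", "e1", "v1", 10, 0, 4, 6, 0, 0],
            ["C", "e1", "v1", 10, 0, 0, 0, 0, 0],  # all censored, carrier
        ]
        table = make_survival(rows)
        fit = fit_lognormal_aft(
            table, metadata=None, snp=pd.Series({"A": 0, "B": 0, "C": 1}),
            random_effects=(),
        )
        assert fit.status == "separation"


class TestBinomialGlmm:
    def test_sigma_zero_equals_logistic_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 60
        lines = [f"L{i}" for i in range(n)]
        w = rng.random(n) < 0.5
        g = (rng.random(n) < 0.4).astype(int)
        p = 1 / (1 + np.exp(-(0.3 + 0.5 * w - 1.0 * g)))
        dead = rng.binomial(20, p)
        table = make_binomial(
            [[l, "e1", 20 - d, d] for l, d in zip(lines, dead)]
        )
        meta = pd.DataFrame({"line_id": lines, "wolbachia": w, "population": "X"})
        fit = fit_binomial_glmm(
            table, meta, snp=pd.Series(g, index=lines), var_line=0.0
        )
        X = np.column_stack([np.ones(n), w.astype(float), g.astype(float)])
        glm = sm.GLM(
            np.column_stack([dead, 20 - dead]), X, family=sm.families.Binomial()
        ).fit()
        for i, name in enumerate(["intercept", "wolbachia", "snp"]):
            assert fit.coefficients[name] == pytest.approx(glm.params[i], abs=1e-6)
            assert fit.se[name] == pytest.approx(glm.bse[i], abs=1e-4)

    def test_single_line_intercept_is_logit(self):
        table = make_binomial([["A", "e1", 15, 5]])
        fit = fit_binomial_glmm(table, metadata=None, snp=None, var_line=0.0)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(5 / 15), abs=1e-6)

    def test_mixed_loglik_dominates_logistic(self):
        # extra variance parameter can only raise the maximized likelihood
        cfg = SimConfig(n_lines=80, n_sites_per_arm=10, seed=3)
        panel, meta, truth = simulate_panel(cfg)
        table = simulate_binomial(panel, meta, truth, sigma_line=1.0, seed=3)
        mixed = fit_binomial_glmm(table, meta)
        plain = fit_binomial_glmm(table, meta, var_line=0.0)
        assert mixed.loglik >= plain.loglik - 1e-6

    def test_beta_recovery_over_seeds(self):
        betas = []
        for seed in range(12):
            cfg = SimConfig(
                n_lines=200, n_sites_per_arm=10, seed=seed,
                resistance_loci=[
                    PlantedLocus("2R", 250_000, 0.4, effect_binomial=-1.5, tag="major")
                ],
            )
            panel, meta, truth = simulate_panel(cfg)
            table = simulate_binomial(panel, meta, truth, sigma_line=1.0, seed=seed)
            j = panel.site_index("2R", 250_000)
            g = pd.Series(panel.calls[:, j].astype(int), index=panel.lines)
            betas.append(fit_binomial_glmm(table, meta, snp=g).coefficients["snp"])
        assert abs(np.mean(betas) - (-1.5)) < 0.15


@pytest.fixture(scope="module")
def two_locus_binomial():
    """Panel with a dominant major locus masking a secondary locus."""
    cfg = SimConfig(
        n_lines=200, n_sites_per_arm=120, seed=77,
        resistance_loci=[
            PlantedLocus("2R", 300_000, 0.40, effect_binomial=-3.0, tag="major"),
            PlantedLocus("2R", 700_000, 0.30, effect_binomial=-1.5, tag="secondary"),
        ],
    )
    panel, meta, truth = simulate_panel(cfg)
    panel = impute_missing(filter_sites(panel))
    table = simulate_binomial(panel, meta, truth, sigma_line=1.0, seed=77)
    return panel, meta, truth, table


class TestScan:
    def test_major_locus_is_top_hit(self, two_locus_binomial):
        panel, meta, truth, table = two_locus_binomial
        result = gwas_scan(panel, table, meta, model="binomial")
        top = result.top_hit()
        assert (top["chrom"], int(top["pos"])) == ("2R", 300_000)

    def test_threshold_counts_match_brute_force(self, two_locus_binomial):
        panel, meta, truth, table = two_locus_binomial
        result = gwas_scan(panel, table, meta, model="binomial")
        mlp = result.table["minus_log10_p"].to_numpy(dtype=float)
        for t in (4.0, 5.0, 8.0):
            assert result.threshold_counts[t] == int(np.nansum(mlp > t))

    def test_nested_unmasks_secondary(self, two_locus_binomial):
        panel, meta, truth, table = two_locus_binomial
        nested = nested_scan(
            panel, table, meta, top_variant=("2R", 300_000), model="binomial"
        )
        top = nested.top_hit()
        assert (top["chrom"], int(top["pos"])) == ("2R", 700_000)
        # carriers of the major resistant allele are gone
        j = panel.site_index("2R", 300_000)
        n_noncarriers = int((panel.calls[:, j] == 0).sum())
        assert nested.table["n_Wp_ref"].iloc[0] + nested.table["n_Wp_alt"].iloc[0] \
            + nested.table["n_Wm_ref"].iloc[0] + nested.table["n_Wm_alt"].iloc[0] \
            <= n_noncarriers

    def test_resistant_allele_inference(self, two_locus_binomial):
        panel, meta, truth, table = two_locus_binomial
        allele = infer_resistant_allele(
            panel, table, meta, ("2R", 300_000), model="binomial"
        )
        assert allele == 1  # planted protective alt allele

    def test_resistant_allele_carried_by_all_lines_empties_subset(self):
        from conftest import make_panel

        calls = np.ones((6, 2), dtype=np.int8)
        calls[:3, 1] = 0
        panel = make_panel(calls, positions=[100, 200])
        lines = panel.lines
        meta = pd.DataFrame(
            {"line_id": lines, "wolbachia": [True, False] * 3, "population": "X"}
        )
        table = make_binomial([[l, "e1", 10, 10] for l in lines])
        result = nested_scan(
            panel, table, meta, top_variant=("2R", 100),
            resistant_allele=1, model="binomial",
        )
        assert result.status == "empty_subset"
        assert len(result.table) == 0

    def test_permuting_phenotype_lines_destroys_signal(self, two_locus_binomial):
        panel, meta, truth, table = two_locus_binomial
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.lines)
        mapping = dict(zip(panel.lines, perm))
        shuffled = table.data.copy()
        shuffled["line_id"] = shuffled["line_id"].map(mapping)
        from resistscan import BinomialTable

        result = gwas_scan(panel, BinomialTable(shuffled), meta, model="binomial")
        top = result.top_hit()
        assert top["minus_log10_p"] < 4.0


class TestCandidateTable:
    def _result_from_pvals(self, pvals):
        from resistscan.assoc import AssociationResult, _SCAN_COLUMNS

        rows = []
        for i, p in enumerate(pvals):
            rows.append(
                {
                    "chrom": "2R", "pos": 100 + i, "ref": "A", "alt": "T",
                    "n_Wp_ref": 5, "n_Wp_alt": 5, "n_Wm_ref": 5, "n_Wm_alt": 5,
                    "beta_snp": 0.0, "se_snp": 1.0, "p_snp": p,
                    "p_interaction": np.nan,
                    "minus_log10_p": -np.log10(p), "q_bh": np.nan, "status": "ok",
                }
            )
        return AssociationResult(
            table=pd.DataFrame(rows, columns=_SCAN_COLUMNS), model="binomial"
        )

    def test_all_null_empty(self):
        result = self._result_from_pvals([0.5] * 10)
        assert len(candidate_table(result)) == 0

    def test_threshold_arithmetic(self):
        result = self._result_from_pvals([1e-9, 5e-5, 2e-4])
        cand = candidate_table(result)
        assert cand["p_snp"].tolist() == [1e-9, 5e-5]

    def test_threshold_counts_equal_recount(self):
        rng = np.random.default_rng(2)
        pvals = 10 ** (-rng.uniform(0, 10, size=50))
        result = self._result_from_pvals(pvals)
        cand = candidate_table(result)
        for t in (4.0, 5.0, 8.0):
            assert cand.attrs["threshold_counts"][t] == int(
                np.sum(-np.log10(pvals) > t)
            )
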