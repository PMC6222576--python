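"""Synthetic panel and phenotype generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resistscan import (
    CHECKPOINTS,
    ConfigError,
    MISSING,
    PlantedLocus,
    SimConfig,
    SweepConfig,
    plant_sweep,
    planted_linear_predictor,
    simulate_binomial,
    simulate_panel,
    simulate_survival,
)


class TestSimulatePanel:
    def test_determinism_and_structure(self):
        cfg = SimConfig(n_lines=40, n_sites_per_arm=100, seed=9)
        p1, m1, t1 = simulate_panel(cfg)
        p2, m2, t2 = simulate_panel(cfg)
        np.testing.assert_array_equal(p1.calls, p2.calls)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1 == t2
        # changing the seed changes realizations, not shapes
        p3, _, _ = simulate_panel(SimConfig(n_lines=40, n_sites_per_arm=100, seed=10))
        assert p3.calls.shape == p1.calls.shape
        assert not np.array_equal(p3.calls, p1.calls)

    def test_planted_locus_carrier_count(self):
        cfg = SimConfig(
            n_lines=200, n_sites_per_arm=50, seed=4,
            resistance_loci=[PlantedLocus("2R", 123_456, 0.30, tag="major")],
        )
        panel, _, truth = simulate_panel(cfg)
        j = panel.site_index("2R", 123_456)
        n_carriers = int((panel.calls[:, j] == 1).sum())
        assert abs(n_carriers - 60) <= 1
        assert sorted(truth["loci"][0]["carriers"]) == sorted(
            l for l, c in zip(panel.lines, panel.calls[:, j]) if c == 1
        )

    def test_allele_frequency_law(self):
        # realized per-site alt counts over n lines follow the exact
        # Beta(0.2, 0.2)-Binomial mixture; chi-square GoF at alpha = 0.01
        n = 500
        cfg = SimConfig(n_lines=n, n_sites_per_arm=10_000, missing_rate=0.0, seed=2)
        panel, _, _ = simulate_panel(cfg)
        k = (panel.calls == 1).sum(axis=0)
        bb = stats.betabinom(n, 0.2, 0.2)
        edges = [0, 1, 5, 25, 100, 250, 400, 476, 496, 500, 501]
        obs = np.histogram(k, bins=edges)[0]
        probs = np.diff(np.r_[0, [bb.cdf(e - 1) for e in edges[1:]]])
        expected = probs * len(k)
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(
                n_lines=10, n_sites_per_arm=10,
                resistance_loci=[PlantedLocus("2R", 10, 0.01, effect_binomial=-1.0)],
            )
        with pytest.raises(ConfigError):
            SimConfig(
                n_lines=10, n_sites_per_arm=10,
                resistance_loci=[
                    PlantedLocus("2R", 10, 0.5, tag="major"),
                    PlantedLocus("2R", 20, 0.5, tag="major"),
                ],
            )

    def test_wolbachia_fraction(self):
        cfg = SimConfig(n_lines=200, n_sites_per_arm=10, wolbachia_fraction=0.5, seed=1)
        _, meta, _ = simulate_panel(cfg)
        assert meta["wolbachia"].sum() == 100


class TestPlantSweep:
    def _swept(self, n_origins, noise, seed=5):
        cfg = SimConfig(
            n_lines=60, arms={"2R": 100_000}, n_sites_per_arm=400,
            missing_rate=0.0, seed=seed,
            resistance_loci=[PlantedLocus("2R", 50_000, 0.5, tag="major")],
        )
        panel, _, _ = simulate_panel(cfg)
        swept = plant_sweep(
            panel, SweepConfig("2R", 50_000, halfwidth_bp=20_000,
                               n_origins=n_origins, noise_rate=noise),
            seed=seed,
        )
        j = panel.site_index("2R", 50_000)
        carriers = np.flatnonzero(panel.calls[:, j] == 1)
        pos = panel.variants["pos"].to_numpy()
        window = np.flatnonzero((pos >= 30_000) & (pos <= 70_000))
        return panel, swept, carriers, window

    def test_single_origin_no_noise_identical(self):
        panel, swept, carriers, window = self._swept(1, 0.0)
        haps = swept.calls[np.ix_(carriers, window)]
        assert len({h.tobytes() for h in haps}) == 1

    def test_two_origins_at_most_two_haplotypes(self):
        panel, swept, carriers, window = self._swept(2, 0.0)
        haps = swept.calls[np.ix_(carriers, window)]
        assert len({h.tobytes() for h in haps}) <= 2

    def test_non_carriers_untouched(self):
        panel, swept, carriers, window = self._swept(2, 0.1)
        non = np.setdiff1d(np.arange(panel.n_lines), carriers)
        np.testing.assert_array_equal(panel.calls[non], swept.calls[non])

    def test_focal_allele_preserved(self):
        panel, swept, carriers, _ = self._swept(3, 0.3)
        j = panel.site_index("2R", 50_000)
        assert (swept.calls[carriers, j] == 1).all()


class TestSimulateSurvival:
    def _null_parts(self, seed=0, n_lines=30):
        cfg = SimConfig(n_lines=n_lines, n_sites_per_arm=10, seed=seed)
        return simulate_panel(cfg)

    def test_deterministic_binning_no_variance(self):
        panel, meta, truth = self._null_parts()
        table = simulate_survival(
            panel, meta, truth, sigma_line=0.0, sigma_exp=0.0, sigma_noise=0.0,
            baseline_mu=float(np.log(10.0)), seed=3,
        )
        # e^mu = 10 h falls in (5, 11]; every death recorded at the 11h checkpoint
        deaths = table.data[[f"deaths_{c:g}" for c in CHECKPOINTS]].to_numpy()
        assert (deaths[:, 2] == table.data["n_start"]).all()
        assert deaths[:, [0, 1, 3, 4]].sum() == 0

    def test_times_beyond_horizon_censored(self):
        panel, meta, truth = self._null_parts()
        table = simulate_survival(
            panel, meta, truth, sigma_line=0.0, sigma_exp=0.0, sigma_noise=0.0,
            baseline_mu=float(np.log(60.0)), seed=3,
        )
        assert (table.survivors_48() == table.data["n_start"]).all()

    def test_major_effect_raises_carrier_censoring(self):
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                n_lines=60, n_sites_per_arm=10, seed=seed,
                resistance_loci=[
                    PlantedLocus("2R", 250_000, 0.4, effect_survival=2.0, tag="major")
                ],
            )
            panel, meta, truth = simulate_panel(cfg)
            table = simulate_survival(panel, meta, truth, seed=seed)
            carriers = set(truth["loci"][0]["carriers"])
            frac = table.survivors_48() / table.data["n_start"].to_numpy()
            in_c = table.data["line_id"].isin(carriers).to_numpy()
            wins += frac[in_c].mean() > frac[~in_c].mean()
        assert wins == 10

    def test_line_variance_recovered(self):
        # no planted effects: among-line variance of mean log death time
        # tracks sigma_line^2 (binning adds a little distortion)
        ratios = []
        for seed in range(10):
            panel, meta, truth = self._null_parts(seed=seed, n_lines=150)
            table = simulate_survival(
                panel, meta, truth, sigma_line=0.4, sigma_exp=0.0,
                sigma_noise=0.05, baseline_mu=float(np.log(10.0)), seed=seed,
            )
            df = table.data
            hours = np.array([2.5, 5, 11, 24, 48])
            deaths = df[[f"deaths_{c:g}" for c in CHECKPOINTS]].to_numpy()
            tot_logt = (deaths * np.log(hours)).sum(axis=1) + (
                df["n_start"].to_numpy() - deaths.sum(axis=1)
            ) * np.log(48.0)
            mean_logt = (
                pd.DataFrame({"l": df["line_id"], "v": tot_logt / df["n_start"]})
                .groupby("l")["v"].mean()
            )
            ratios.append(mean_logt.var(ddof=1) / 0.16)
        # binning inflates the checkpoint-scale variance somewhat; the
        # among-line component should still be of the right order
        assert 0.8 < np.mean(ratios) < 1.6

    def test_adding_experiments_preserves_earlier_draws(self):
        panel, meta, truth = self._null_parts()
        t5 = simulate_survival(panel, meta, truth, n_experiments=5, seed=11)
        t6 = simulate_survival(panel, meta, truth, n_experiments=6, seed=11)
        first5 = t6.data[t6.data["experiment_id"].isin(
            [f"exp_{i}" for i in range(1, 6)]
        )].reset_index(drop=True)
        pd.testing.assert_frame_equal(first5, t5.data)


class TestSimulateBinomial:
    def test_symmetric_baseline(self):
        cfg = SimConfig(n_lines=100, n_sites_per_arm=10, seed=8)
        panel, meta, truth = simulate_panel(cfg)
        table = simulate_binomial(
            panel, meta, truth, sigma_line=0.0, baseline_logit=0.0, seed=8
        )
        dead = table.data["dead_48"].sum()
        total = dead + table.data["alive_48"].sum()
        se = np.sqrt(0.25 / total)
        assert abs(dead / total - 0.5) < 3 * se

    def test_protective_allele_lowers_mortality(self):
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                n_lines=60, n_sites_per_arm=10, seed=seed,
                resistance_loci=[
                    PlantedLocus("2R", 250_000, 0.4, effect_binomial=-2.0, tag="major")
                ],
            )
            panel, meta, truth = simulate_panel(cfg)
            table = simulate_binomial(panel, meta, truth, seed=seed)
            carriers = set(truth["loci"][0]["carriers"])
            df = table.data
            mort = df["dead_48"] / (df["dead_48"] + df["alive_48"])
            in_c = df["line_id"].isin(carriers).to_numpy()
            wins += mort[in_c].mean() < mort[~in_c].mean()
        assert wins == 10

    def test_no_line_variance_is_pure_binomial(self):
        cfg = SimConfig(n_lines=150, n_sites_per_arm=10, seed=14)
        panel, meta, truth = simulate_panel(cfg)
        table = simulate_binomial(
            panel, meta, truth, sigma_line=0.0, baseline_logit=0.0, seed=14
        )
        # line-level dispersion statistic ~ 1 under pure binomial sampling
        df = table.data
        agg = df.groupby("line_id").agg(
            dead=("dead_48", "sum"), tot=("dead_48", "size")
        )
        n_flies = 20
        p_hat = df["dead_48"].sum() / (len(df) * n_flies)
        expected = agg["tot"] * n_flies * p_hat
        var = agg["tot"] * n_flies * p_hat * (1 - p_hat)
        chi2 = float((((agg["dead"] - expected) ** 2) / var).sum())
        dispersion = chi2 / len(agg)
        assert 0.8 < dispersion < 1.2

    def test_wolbachia_interaction_applies_only_in_class(self):
        cfg = SimConfig(
            n_lines=80, n_sites_per_arm=10, seed=21,
            resistance_loci=[
                PlantedLocus(
                    "2R", 250_000, 0.5, effect_binomial=0.0,
                    w_interaction_effect=-3.0, w_interaction_class="Wminus",
                    tag="major",
                )
            ],
        )
        panel, meta, truth = simulate_panel(cfg)
        lp = planted_linear_predictor(truth, meta, "binomial", baseline=0.0)
        carriers = set(truth["loci"][0]["carriers"])
        wolb = dict(zip(meta["line_id"], meta["wolbachia"]))
        for line in meta["line_id"]:
            expected = -3.0 if (line in carriers and not wolb[line]) else 0.0
            assert lp[line] == expected
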