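"""Synthetic inbred-panel generator.

Emulates the statistical structure of a DGRP-style study panel: ~200 fully
homozygous lines, biallelic sites with U-shaped allele frequencies and
moderate missingness, roughly half the lines carrying the *Wolbachia*
endosymbiont, a planted major-effect resistance locus plus minor loci (some
interacting with symbiont status), lognormal time-to-death observed at fixed
checkpoints, binomial 48-h mortality, and soft sweeps with a configurable
number of founder resistant haplotypes.

Genotypes are simulated site-independently outside sweep windows: there is no
background linkage disequilibrium.  That is sufficient to exercise the site
filters, the association scans and the sweep-contrast statistics, but it is
not a population-genetic model of the panel.

All randomness flows through named sub-streams of a single seed, split per
(stream, line, experiment), so enlarging the design does not perturb draws
already made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    CENSOR_HOUR,
    CHECKPOINTS,
    MISSING,
    SURVIVAL_DEATH_COLS,
    BinomialTable,
    GenotypePanel,
    SurvivalTable,
)

logger = logging.getLogger("resistscan")

# Named RNG stream ids (spawn-key prefixes).
_S_GENO, _S_MISS, _S_META, _S_LOCI, _S_SWEEP = 0, 1, 2, 3, 4
_S_SURV_LINE, _S_SURV_EXP, _S_SURV_NOISE = 10, 11, 12
_S_BIN_LINE, _S_BIN_NOISE = 20, 21


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedLocus:
    """A causal resistance locus planted into the simulated panel.

    ``effect_survival`` shifts the mean log time-to-death (log-hours) of
    alternate-allele carriers; positive values mean longer survival, i.e.
    resistance.  ``effect_binomial`` shifts the log-odds of death at 48 h;
    negative values are protective.  ``w_interaction_effect`` is an extra
    effect applying only to carriers in the stated *Wolbachia* class,
    modelling symbiont-conditional resistance.
    """

    arm: str
    pos: int
    target_freq: float
    effect_survival: float = 0.0
    effect_binomial: float = 0.0
    w_interaction_effect: float = 0.0
    w_interaction_class: Literal["Wplus", "Wminus", None] = None
    tag: str = "minor"  # at most one locus tagged "major"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_freq <= 1.0:
            raise ConfigError(f"target_freq must be in [0,1], got {self.target_freq}")
        for v in (self.effect_survival, self.effect_binomial, self.w_interaction_effect):
            if not np.isfinite(v):
                raise ConfigError("locus effects must be finite")
        if self.w_interaction_effect != 0.0 and self.w_interaction_class is None:
            raise ConfigError("w_interaction_class required with a nonzero interaction")


@dataclass(frozen=True)
class SweepConfig:
    """A soft sweep at a focal locus: carriers descend from few founders."""

    arm: str
    pos: int
    halfwidth_bp: int = 200_000
    n_origins: int = 3
    # per-site flip rate after founder copy; calibrated so haplotypes within
    # a sweep cluster differ at a handful of sites across a dense 200-kb
    # window, the "short genetic distances within clusters" regime
    noise_rate: float = 5e-4

    def __post_init__(self) -> None:
        if self.n_origins < 1:
            raise ConfigError("n_origins must be >= 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ConfigError("noise_rate must be in [0,1)")


@dataclass
class SimConfig:
    """Study-panel generator settings.

    Defaults mirror the study conditions: ~200 homozygous lines, half of
    them *Wolbachia*-positive, U-shaped Beta(0.2, 0.2) alternate-allele
    frequencies and 5% missing calls.
    """

    n_lines: int = 200
    arms: dict[str, int] = field(default_factory=lambda: {"2R": 1_000_000})
    n_sites_per_arm: int = 2000
    beta_a: float = 0.2
    beta_b: float = 0.2
    missing_rate: float = 0.05
    wolbachia_fraction: float = 0.5
    resistance_loci: list[PlantedLocus] = field(default_factory=list)
    sweep: SweepConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.missing_rate, self.wolbachia_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0,1]")
        majors = [l for l in self.resistance_loci if l.tag == "major"]
        if len(majors) > 1:
            raise ConfigError("at most one locus may be tagged 'major'")
        for locus in self.resistance_loci:
            n_carriers = round(locus.target_freq * self.n_lines)
            has_effect = (
                locus.effect_survival != 0
                or locus.effect_binomial != 0
                or locus.w_interaction_effect != 0
            )
            if n_carriers == 0 and has_effect:
                raise ConfigError(
                    f"locus {locus.arm}:{locus.pos} has an effect but its target "
                    f"frequency yields zero carrier lines"
                )
            if locus.arm not in self.arms:
                raise ConfigError(f"locus arm {locus.arm!r} not among arms")
            if not 1 <= locus.pos <= self.arms[locus.arm]:
                raise ConfigError(f"locus position {locus.pos} outside arm")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        d = dict(d)
        loci = [PlantedLocus(**l) for l in d.pop("resistance_loci", [])]
        sweep = d.pop("sweep", None)
        return cls(
            resistance_loci=loci,
            sweep=SweepConfig(**sweep) if sweep else None,
            **d,
        )


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypePanel, pd.DataFrame, dict[str, Any]]:
    """Simulate a genotype panel with metadata and a ground-truth record.

    Returns ``(panel, metadata, truth)``.  The truth record is JSON-able and
    lists every planted locus with its carrier lines and effects, which is
    sufficient to recompute each line's planted linear predictor exactly.
    """
    seed = config.seed
    n = config.n_lines
    lines = [f"line_{i:03d}" for i in range(n)]

    frames: list[pd.DataFrame] = []
    call_blocks: list[np.ndarray] = []
    planted_cols: dict[tuple[str, int], np.ndarray] = {}

    # carrier assignment for planted loci (exact count by rounding)
    rng_loci = _rng(seed, _S_LOCI)
    truth_loci: list[dict[str, Any]] = []
    for locus in config.resistance_loci:
        n_carriers = int(round(locus.target_freq * n))
        carriers = rng_loci.choice(n, size=n_carriers, replace=False)
        col = np.zeros(n, dtype=np.int8)
        col[carriers] = 1
        planted_cols[(locus.arm, locus.pos)] = col
        truth_loci.append(
            {
                "arm": locus.arm,
                "pos": int(locus.pos),
                "tag": locus.tag,
                "target_freq": locus.target_freq,
                "carriers": sorted(lines[i] for i in carriers),
                "effect_survival": locus.effect_survival,
                "effect_binomial": locus.effect_binomial,
                "w_interaction_effect": locus.w_interaction_effect,
                "w_interaction_class": locus.w_interaction_class,
            }
        )

    for arm_idx, (arm, length) in enumerate(sorted(config.arms.items())):
        rng_g = _rng(seed, _S_GENO, arm_idx)
        n_sites = config.n_sites_per_arm
        planted_here = sorted(
            pos for (a, pos) in planted_cols if a == arm
        )
        n_random = max(n_sites - len(planted_here), 0)
        pos_pool = rng_g.choice(length, size=min(length, n_sites * 2), replace=False) + 1
        pos_pool = pos_pool[~np.isin(pos_pool, np.array(planted_here, dtype=np.int64))]
        positions = np.sort(
            np.concatenate(
                [pos_pool[:n_random], np.array(planted_here, dtype=np.int64)]
            )
        )
        freqs = rng_g.beta(config.beta_a, config.beta_b, size=positions.size)
        calls = (rng_g.random((n, positions.size)) < freqs[None, :]).astype(np.int8)
        # missingness, then overwrite planted columns (kept fully observed)
        rng_m = _rng(seed, _S_MISS, arm_idx)
        miss = rng_m.random((n, positions.size)) < config.missing_rate
        calls[miss] = MISSING
        planted_mask = np.isin(positions, np.array(planted_here, dtype=np.int64))
        for j in np.flatnonzero(planted_mask):
            calls[:, j] = planted_cols[(arm, int(positions[j]))]
        refs = np.array(["A"] * positions.size)
        alts = np.array(["T"] * positions.size)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": arm,
                    "pos": positions.astype(int),
                    "ref": refs,
                    "alt": alts,
                    "vclass": "snp",
                }
            )
        )
        call_blocks.append(calls)

    variants = pd.concat(frames, ignore_index=True)
    calls = np.concatenate(call_blocks, axis=1) if call_blocks else np.empty((n, 0), np.int8)
    panel = GenotypePanel(lines=lines, variants=variants, calls=calls)

    rng_meta = _rng(seed, _S_META)
    n_wplus = int(round(config.wolbachia_fraction * n))
    wplus_idx = rng_meta.choice(n, size=n_wplus, replace=False)
    wolb = np.zeros(n, dtype=bool)
    wolb[wplus_idx] = True
    metadata = pd.DataFrame(
        {"line_id": lines, "wolbachia": wolb, "population": "SIM"}
    )

    truth: dict[str, Any] = {
        "seed": seed,
        "n_lines": n,
        "loci": truth_loci,
        "wolbachia_positive": sorted(lines[i] for i in wplus_idx),
    }

    if config.sweep is not None:
        panel = plant_sweep(panel, config.sweep, seed=seed)
        truth["sweep"] = {
            "arm": config.sweep.arm,
            "pos": int(config.sweep.pos),
            "halfwidth_bp": config.sweep.halfwidth_bp,
            "n_origins": config.sweep.n_origins,
            "noise_rate": config.sweep.noise_rate,
        }
    return panel, metadata, truth


def plant_sweep(
    panel: GenotypePanel, sweep: SweepConfig, seed: int
) -> GenotypePanel:
    """Overwrite carrier haplotypes around the focal locus with few founders.

    Every line carrying the alternate allele at the focal site has its
    haplotype across the window replaced by one of ``n_origins`` founder
    haplotypes (drawn from the current carrier haplotypes, assigned
    uniformly), followed by independent per-site flips at the noise rate.
    Non-carrier lines are untouched; the focal allele itself is preserved.
    """
    focal = panel.site_index(sweep.arm, sweep.pos)
    carriers = np.flatnonzero(panel.calls[:, focal] == 1)
    if carriers.size == 0:
        raise ConfigError(f"no carriers at focal locus {sweep.arm}:{sweep.pos}")

    arm_mask = (panel.variants["chrom"] == sweep.arm).to_numpy()
    pos = panel.variants["pos"].to_numpy()
    lo, hi = sweep.pos - sweep.halfwidth_bp, sweep.pos + sweep.halfwidth_bp
    arm_pos = pos[arm_mask]
    if lo < arm_pos.min() or hi > arm_pos.max():
        logger.warning(
            "plant_sweep: window [%d, %d] exceeds arm site range [%d, %d]; truncated",
            lo, hi, arm_pos.min(), arm_pos.max(),
        )
    window = np.flatnonzero(arm_mask & (pos >= lo) & (pos <= hi))

    rng = _rng(seed, _S_SWEEP)
    n_origins = min(sweep.n_origins, carriers.size)
    founder_rows = rng.choice(carriers, size=n_origins, replace=False)
    founders = panel.calls[founder_rows][:, window].copy()
    founders[founders == MISSING] = 0

    calls = panel.calls.copy()
    assign = rng.integers(0, n_origins, size=carriers.size)
    hap = founders[assign]
    if sweep.noise_rate > 0:
        flips = rng.random(hap.shape) < sweep.noise_rate
        hap = np.where(flips, 1 - hap, hap)
    calls[np.ix_(carriers, window)] = hap
    calls[carriers, focal] = 1
    return GenotypePanel(lines=list(panel.lines), variants=panel.variants.copy(), calls=calls)


# ---------------------------------------------------------------------------
# Planted linear predictors
# ---------------------------------------------------------------------------

def _planted_effects(
    truth: Mapping[str, Any],
    lines: Sequence[str],
    wolbachia: np.ndarray,
    which: Literal["survival", "binomial"],
) -> np.ndarray:
    """Per-line sum of planted effects (including symbiont interactions)."""
    eff = np.zeros(len(lines), dtype=float)
    index = {l: i for i, l in enumerate(lines)}
    key = "effect_survival" if which == "survival" else "effect_binomial"
    for locus in truth["loci"]:
        rows = np.array([index[l] for l in locus["carriers"] if l in index], dtype=int)
        if rows.size == 0:
            continue
        eff[rows] += locus[key]
        w_eff = locus["w_interaction_effect"]
        if w_eff:
            in_class = (
                wolbachia[rows]
                if locus["w_interaction_class"] == "Wplus"
                else ~wolbachia[rows]
            )
            eff[rows[in_class]] += w_eff
    return eff


def planted_linear_predictor(
    truth: Mapping[str, Any],
    metadata: pd.DataFrame,
    which: Literal["survival", "binomial"],
    baseline: float,
) -> pd.Series:
    """Exact planted per-line linear predictor (baseline + locus effects)."""
    lines = metadata["line_id"].tolist()
    wolb = metadata["wolbachia"].to_numpy(dtype=bool)
    return pd.Series(
        baseline + _planted_effects(truth, lines, wolb, which), index=lines
    )


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def _bin_to_checkpoint(hours: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map continuous death times to the first checkpoint >= t.

    Returns (checkpoint_index, censored flag); times beyond the last
    checkpoint are right-censored.
    """
    cps = np.asarray(CHECKPOINTS)
    idx = np.searchsorted(cps, hours, side="left")
    censored = idx >= len(cps)
    idx = np.clip(idx, 0, len(cps) - 1)
    return idx, censored


def simulate_survival(
    panel: GenotypePanel,
    metadata: pd.DataFrame,
    truth: Mapping[str, Any],
    n_experiments: int = 5,
    n_flies: int = 20,
    sigma_line: float = 0.5,
    sigma_exp: float = 0.1,
    sigma_noise: float = 0.3,
    baseline_mu: float = float(np.log(10.0)),
    seed: int = 0,
) -> SurvivalTable:
    """Simulate checkpointed time-to-death data.

    Per fly, log time-to-death is baseline + planted locus effects (including
    *Wolbachia* interactions) + line effect ~ N(0, sigma_line^2) + experiment
    effect ~ N(0, sigma_exp^2) + N(0, sigma_noise^2) residual.  Times are
    binned up to the next inspection checkpoint; times beyond 48 h are
    right-censored.  Default variances put the broad-sense heritability of
    the trait in the 0.6-0.9 band typical of these assays.
    """
    lines = metadata["line_id"].tolist()
    wolb = metadata["wolbachia"].to_numpy(dtype=bool)
    eff = _planted_effects(truth, lines, wolb, "survival")

    b_line = np.array(
        [_rng(seed, _S_SURV_LINE, i).normal(0.0, sigma_line) for i in range(len(lines))]
    )
    b_exp = np.array(
        [_rng(seed, _S_SURV_EXP, j).normal(0.0, sigma_exp) for j in range(n_experiments)]
    )

    rows = []
    for i, line in enumerate(lines):
        for j in range(n_experiments):
            rng = _rng(seed, _S_SURV_NOISE, i, j)
            logt = (
                baseline_mu
                + eff[i]
                + b_line[i]
                + b_exp[j]
                + rng.normal(0.0, sigma_noise, size=n_flies)
            )
            hours = np.exp(logt)
            idx, censored = _bin_to_checkpoint(hours)
            deaths = np.zeros(len(CHECKPOINTS), dtype=int)
            for k in idx[~censored]:
                deaths[k] += 1
            rows.append(
                [line, f"exp_{j + 1}", "vial_1", n_flies, *deaths.tolist()]
            )
    df = pd.DataFrame(
        rows, columns=["line_id", "experiment_id", "vial_id", "n_start"] + SURVIVAL_DEATH_COLS
    )
    return SurvivalTable(df)


def simulate_binomial(
    panel: GenotypePanel,
    metadata: pd.DataFrame,
    truth: Mapping[str, Any],
    n_experiments: int = 5,
    n_flies: int = 20,
    sigma_line: float = 1.5,
    baseline_logit: float = 0.0,
    seed: int = 0,
) -> BinomialTable:
    """Simulate alive/dead counts at 48 h.

    Per vial, dead ~ Binomial(n_flies, logistic(baseline + planted effects +
    line effect ~ N(0, sigma_line^2))) on the log-odds-of-death scale.
    """
    lines = metadata["line_id"].tolist()
    wolb = metadata["wolbachia"].to_numpy(dtype=bool)
    eff = _planted_effects(truth, lines, wolb, "binomial")
    b_line = np.array(
        [_rng(seed, _S_BIN_LINE, i).normal(0.0, sigma_line) for i in range(len(lines))]
    )
    rows = []
    for i, line in enumerate(lines):
        p_dead = 1.0 / (1.0 + np.exp(-(baseline_logit + eff[i] + b_line[i])))
        for j in range(n_experiments):
            rng = _rng(seed, _S_BIN_NOISE, i, j)
            dead = int(rng.binomial(n_flies, p_dead))
            rows.append([line, f"exp_{j + 1}", n_flies - dead, dead])
    df = pd.DataFrame(rows, columns=["line_id", "experiment_id", "alive_48", "dead_48"])
    return BinomialTable(df)
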