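"""Panel-level summaries: broad-sense heritability, resistance-combination
frequencies across populations, and cross-phenotype rank correlation.

Heritability uses one-way random-effects ANOVA with method-of-moments
variance components: Ve is the within-line mean square, Vg = (MSB - MSW)/n0
with the standard unbalanced-design coefficient n0, and h2 = Vg/(Vg + Ve)
— the usual broad-sense estimator for fully inbred line panels, where the
among-line variance is entirely genetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import (
    MISSING,
    SURVIVAL_DEATH_COLS,
    BinomialTable,
    GenotypePanel,
    SurvivalTable,
)
from .njtree import combo_string

logger = logging.getLogger("resistscan")

_CP_HOURS = np.array([2.5, 5.0, 11.0, 24.0, 48.0])


@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA variance partition of a line-replicated phenotype."""

    ve: float  # environmental (within-line)
    vg: float  # genetic (among-line); clamped at 0
    h2: float  # vg / (vg + ve)
    n_lines: int
    n_individuals: int

    @classmethod
    def from_components(cls, ve: float, vg: float,
                        n_lines: int = 0, n_individuals: int = 0
                        ) -> "VarianceComponents":
        """Assemble from already-computed components (e.g. a published table)."""
        ve = float(ve)
        vg = max(float(vg), 0.0)
        h2 = vg / (vg + ve) if (vg + ve) > 0 else 0.0
        return cls(ve=ve, vg=vg, h2=h2, n_lines=n_lines, n_individuals=n_individuals)


def variance_components(values: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components from per-line replicates.

    ``values`` has columns ``line_id`` and ``value`` (one row per replicate
    measurement).  A negative among-line moment estimate is clamped to 0.
    """
    if not {"line_id", "value"}.issubset(values.columns):
        raise ValueError("expected columns line_id, value")
    grp = values.groupby("line_id")["value"]
    k = grp.ngroups
    if k < 2:
        raise ValueError("need at least 2 lines")
    n_i = grp.size().to_numpy(dtype=float)
    N = float(n_i.sum())
    means = grp.mean().to_numpy()
    grand = float(values["value"].mean())
    msb = float(np.sum(n_i * (means - grand) ** 2) / (k - 1))
    within_ss = float(((values["value"] - grp.transform("mean")) ** 2).sum())
    dfw = N - k
    if dfw <= 0:
        raise ValueError("no within-line replication")
    msw = within_ss / dfw
    n0 = (N - float(np.sum(n_i**2)) / N) / (k - 1)
    vg = max((msb - msw) / n0, 0.0)
    ve = msw
    h2 = vg / (vg + ve) if (vg + ve) > 0 else 0.0
    return VarianceComponents(
        ve=ve, vg=vg, h2=h2, n_lines=int(k), n_individuals=int(N)
    )


def line_replicate_values(
    table: SurvivalTable | BinomialTable,
    scale: Literal["death_hour", "proportion_alive"] = "death_hour",
) -> pd.DataFrame:
    """Expand a phenotype table to per-replicate values for the ANOVA.

    ``death_hour`` expands survival data to one value per fly: the checkpoint
    hour of death, with 48-h survivors scored at the censoring horizon.
    ``proportion_alive`` yields one value per vial: the fraction alive at
    48 h (works for both table kinds).  The scale is a parameter because
    published variance tables rarely state it.
    """
    df = table.data
    if scale == "proportion_alive":
        if isinstance(table, SurvivalTable):
            prop = table.survivors_48() / df["n_start"].to_numpy()
        else:
            tot = df["alive_48"] + df["dead_48"]
            prop = (df["alive_48"] / tot).to_numpy()
        return pd.DataFrame({"line_id": df["line_id"], "value": prop})
    if scale == "death_hour":
        if not isinstance(table, SurvivalTable):
            raise ValueError("death_hour scale needs a SurvivalTable")
        deaths = df[SURVIVAL_DEATH_COLS].to_numpy(dtype=int)
        rows_line: list[str] = []
        rows_val: list[float] = []
        for r in range(len(df)):
            line = df.iloc[r]["line_id"]
            for k, cnt in enumerate(deaths[r]):
                rows_line.extend([line] * int(cnt))
                rows_val.extend([_CP_HOURS[k]] * int(cnt))
            n_cens = int(df.iloc[r]["n_start"]) - int(deaths[r].sum())
            rows_line.extend([line] * n_cens)
            rows_val.extend([48.0] * n_cens)
        return pd.DataFrame({"line_id": rows_line, "value": rows_val})
    raise ValueError(f"unknown scale {scale!r}")


def combo_frequencies(
    panel: GenotypePanel, metadata: pd.DataFrame, locus_set: pd.DataFrame
) -> pd.DataFrame:
    """Per-population frequencies of resistance-mutation combination strings.

    Lines with a missing genotype at any set locus are tallied separately
    under combo ``"?"`` and excluded from the frequency denominator, so the
    frequencies of observed combinations sum to 1 within each population.
    """
    cols = [panel.site_index(r.arm, int(r.pos)) for r in locus_set.itertuples()]
    res = locus_set["resistant_allele"].to_numpy(dtype=int)
    line_row = {l: i for i, l in enumerate(panel.lines)}
    rows = []
    for pop, grp in metadata.groupby("population"):
        members = [l for l in grp["line_id"] if l in line_row]
        if not members:
            logger.warning("combo_frequencies: population %r has no lines; skipped", pop)
            continue
        combos = [
            combo_string(panel.calls[line_row[l], cols], res) for l in members
        ]
        counts = pd.Series(combos).value_counts()
        observed = {c: n for c, n in counts.items() if "?" not in c}
        n_missing = int(sum(n for c, n in counts.items() if "?" in c))
        denom = sum(observed.values())
        for combo, n in sorted(observed.items()):
            rows.append((pop, combo, int(n), n / denom if denom else np.nan))
        if n_missing:
            rows.append((pop, "?", n_missing, np.nan))
    return pd.DataFrame(rows, columns=["population", "combo", "count", "frequency"])


def spearman_correlation(
    pheno_a: pd.Series, pheno_b: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation between two per-line phenotypes.

    Series are matched on their index (line IDs); needs >= 3 shared lines.
    Ties take mid-ranks; the p-value uses the t approximation.  A constant
    input makes the correlation undefined and raises.
    """
    shared = pheno_a.index.intersection(pheno_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared lines, got {len(shared)}")
    a = pheno_a.loc[shared].to_numpy(dtype=float)
    b = pheno_b.loc[shared].to_numpy(dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
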