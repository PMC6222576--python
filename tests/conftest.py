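import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from resistscan import (
    BinomialTable,
    GenotypePanel,
    SimConfig,
    PlantedLocus,
    SurvivalTable,
    simulate_panel,
)
from resistscan.panel_io import SURVIVAL_DEATH_COLS

SURV_COLS = ["line_id", "experiment_id", "vial_id", "n_start"] + SURVIVAL_DEATH_COLS


def make_panel(calls, positions=None, chrom="2R", lines=None, vclass="snp"):
    """Build a small GenotypePanel from a call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_sites = calls.shape
    if positions is None:
        positions = list(range(1000, 1000 + 100 * n_sites, 100))
    if lines is None:
        lines = [f"L{i}" for i in range(n_lines)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T" if vclass == "snp" else "TTT",
            "vclass": vclass,
        }
    )
    return GenotypePanel(lines=lines, variants=variants, calls=calls)


def make_survival(rows):
    """rows: (line, exp, vial, n_start, d2.5, d5, d11, d24, d48)."""
    return SurvivalTable(pd.DataFrame(rows, columns=SURV_COLS))


def make_binomial(rows):
    return BinomialTable(
        pd.DataFrame(rows, columns=["line_id", "experiment_id", "alive_48", "dead_48"])
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 60-line simulated panel with a planted protective locus."""
    cfg = SimConfig(
        n_lines=60,
        arms={"2R": 500_000},
        n_sites_per_arm=120,
        seed=42,
        resistance_loci=[
            PlantedLocus(
                "2R", 250_000, 0.4, effect_survival=1.0,
                effect_binomial=-2.0, tag="major",
            )
        ],
    )
    return simulate_panel(cfg)
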