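"""Haplotype-homozygosity (H1/H12) soft-sweep scans.

H1 = sum p_i^2 over the frequencies of distinct haplotypes in a window;
H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2 pools the two most frequent haplotype
classes, which boosts power against soft sweeps where several resistant
haplotypes rise together.  Windows are defined in segregating-site index
space (800 sites by default, centred on each focal site); each inbred line
contributes a single haplotype.

The split-sample contrast re-runs the scan separately on lines carrying at
least one resistance allele at a defined locus set and on lines carrying
none, after down-sampling the larger class to equal size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypePanel

logger = logging.getLogger("resistscan")

DEFAULT_WINDOW_SITES = 800


@dataclass
class H12Result:
    """Haplotype frequency spectrum and homozygosity statistics for a window."""

    chrom: str
    focal_pos: int
    spectrum: np.ndarray  # sorted descending, sums to 1
    h1: float
    h12: float
    n_haplotypes: int
    window_start_idx: int = 0
    window_stop_idx: int = 0  # half-open in segregating-site index space


def _spectrum_stats(spectrum: np.ndarray) -> tuple[float, float]:
    p = np.sort(np.asarray(spectrum, dtype=float))[::-1]
    h1 = float(np.sum(p * p))
    if p.size >= 2:
        h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    else:
        h12 = h1
    return h1, h12


def h12(haplotypes: np.ndarray | Sequence[str], chrom: str = "", focal_pos: int = 0
        ) -> H12Result:
    """Compute H1/H12 from complete haplotypes (rows = lines).

    Accepts a lines x sites 0/1 matrix or a sequence of equal-length
    haplotype strings.  Identity is exact string match; input must be
    complete (imputed) data.
    """
    if isinstance(haplotypes, np.ndarray):
        mat = np.asarray(haplotypes)
        if mat.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if np.any(mat == MISSING):
            raise ValueError("haplotypes contain missing calls; impute first")
        keys = [row.tobytes() for row in np.ascontiguousarray(mat, dtype=np.int8)]
    else:
        lengths = {len(h) for h in haplotypes}
        if len(lengths) > 1:
            raise ValueError("haplotype strings have heterogeneous lengths")
        keys = list(haplotypes)
    n = len(keys)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts = pd.Series(keys).value_counts().to_numpy(dtype=float)
    spectrum = np.sort(counts / n)[::-1]
    h1, h12_ = _spectrum_stats(spectrum)
    return H12Result(
        chrom=chrom, focal_pos=focal_pos, spectrum=spectrum,
        h1=h1, h12=h12_, n_haplotypes=int(spectrum.size),
    )


def segregating_sites(panel: GenotypePanel, chrom: str) -> np.ndarray:
    """Column indices of sites on ``chrom`` segregating within the panel."""
    arm = (panel.variants["chrom"] == chrom).to_numpy()
    has_ref = (panel.calls == 0).any(axis=0)
    has_alt = (panel.calls == 1).any(axis=0)
    return np.flatnonzero(arm & has_ref & has_alt)


def h12_scan(
    panel: GenotypePanel,
    chrom: str,
    window_sites: int = DEFAULT_WINDOW_SITES,
    step_sites: int = 1,
) -> pd.DataFrame:
    """Scan an arm: one H12 window per focal segregating site at the stride.

    Windows are ``[i - w//2, i + w - w//2)`` in segregating-site index space
    (length exactly ``window_sites``); edge windows that would fall off the
    arm are skipped.  Requires complete (imputed) calls at the scanned sites.

    Returns a frame with columns chrom, focal_pos_bp, H1, H12,
    n_distinct_haplotypes (empty with ``attrs["status"]`` set when the arm
    has too few segregating sites).
    """
    seg = segregating_sites(panel, chrom)
    cols = ["chrom", "focal_pos_bp", "H1", "H12", "n_distinct_haplotypes"]
    if seg.size < window_sites:
        out = pd.DataFrame(columns=cols)
        out.attrs["status"] = (
            f"too_few_sites: {seg.size} segregating < window {window_sites}"
        )
        return out
    calls = panel.calls[:, seg]
    if np.any(calls == MISSING):
        raise ValueError("panel has missing calls on scanned sites; impute first")
    pos = panel.variants["pos"].to_numpy()[seg]
    half = window_sites // 2
    rows = []
    first = half
    last = seg.size - (window_sites - half)  # inclusive focal bound
    mat = np.ascontiguousarray(calls, dtype=np.int8)
    for i in range(first, last + 1, step_sites):
        lo, hi = i - half, i - half + window_sites
        window = mat[:, lo:hi]
        counts = pd.Series([r.tobytes() for r in window]).value_counts().to_numpy(float)
        spectrum = counts / counts.sum()
        h1, h12_ = _spectrum_stats(np.sort(spectrum)[::-1])
        rows.append((chrom, int(pos[i]), h1, h12_, counts.size))
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["status"] = "ok"
    return out


def scan_value_at(scan: pd.DataFrame, pos: int) -> pd.Series:
    """Scan row whose focal position is nearest ``pos`` (bp)."""
    if scan.empty:
        raise ValueError("empty scan")
    i = (scan["focal_pos_bp"] - pos).abs().idxmin()
    return scan.loc[i]


# ---------------------------------------------------------------------------
# Resistance locus sets and the split-sample contrast
# ---------------------------------------------------------------------------

def read_locus_set(path: str | Path) -> pd.DataFrame:
    """Read a resistance locus set: TSV (arm, pos, resistant_allele, group)."""
    df = pd.read_csv(path, sep="\t")
    required = {"arm", "pos", "resistant_allele", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus set lacks columns {sorted(missing)}")
    df["resistant_allele"] = df["resistant_allele"].astype(int)
    return df


def write_locus_set(locus_set: pd.DataFrame, path: str | Path) -> None:
    locus_set.to_csv(path, sep="\t", index=False)


def classify_haplotypes(
    panel: GenotypePanel, locus_set: pd.DataFrame
) -> tuple[list[str], list[str], list[str]]:
    """Partition lines into (resistant, susceptible, excluded).

    Resistant lines carry the resistant allele at >= 1 locus of the set;
    susceptible lines carry none; lines with a missing genotype at any set
    locus are excluded (logged).
    """
    if len(locus_set) == 0:
        raise ValueError("empty locus set")
    cols = [panel.site_index(r.arm, int(r.pos)) for r in locus_set.itertuples()]
    res_alleles = locus_set["resistant_allele"].to_numpy(dtype=int)
    calls = panel.calls[:, cols].astype(int)
    any_missing = (calls == MISSING).any(axis=1)
    carries = ((calls == res_alleles[None, :]) & (calls != MISSING)).any(axis=1)
    resistant, susceptible, excluded = [], [], []
    for i, line in enumerate(panel.lines):
        if any_missing[i]:
            excluded.append(line)
        elif carries[i]:
            resistant.append(line)
        else:
            susceptible.append(line)
    if excluded:
        logger.info(
            "classify_haplotypes: excluded %d lines with missing set-locus calls",
            len(excluded),
        )
    return resistant, susceptible, excluded


def split_h12(
    panel: GenotypePanel,
    chrom: str,
    locus_set: pd.DataFrame,
    window_sites: int = DEFAULT_WINDOW_SITES,
    seed: int = 0,
    step_sites: int = 1,
) -> pd.DataFrame:
    """Paired H12 scans on resistant vs susceptible line classes.

    The larger class is down-sampled uniformly without replacement (seeded)
    to the smaller class's size so the two scans are comparable; classes of
    equal size are left untouched.  Output stacks both scans with a ``class``
    column.
    """
    resistant, susceptible, _ = classify_haplotypes(panel, locus_set)
    if len(resistant) < 2 or len(susceptible) < 2:
        raise ValueError(
            f"both classes need >= 2 lines (resistant={len(resistant)}, "
            f"susceptible={len(susceptible)})"
        )
    rng = np.random.default_rng(seed)
    n = min(len(resistant), len(susceptible))
    if len(resistant) > n:
        resistant = sorted(rng.choice(resistant, size=n, replace=False).tolist())
    elif len(susceptible) > n:
        susceptible = sorted(rng.choice(susceptible, size=n, replace=False).tolist())

    frames = []
    for label, members in (("resistant", resistant), ("susceptible", susceptible)):
        scan = h12_scan(
            panel.take_lines(members), chrom,
            window_sites=window_sites, step_sites=step_sites,
        )
        scan.insert(0, "class", label)
        frames.append(scan)
    non_empty = [f for f in frames if len(f)]
    out = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else frames[0].iloc[0:0]
    )
    out.attrs["n_per_class"] = n
    return out
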