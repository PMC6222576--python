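"""Genotype panels, phenotype tables and their on-disk formats.

Genotypes live in a :class:`GenotypePanel`: a lines x variants matrix of
haploid calls (0 = reference, 1 = alternate, -1 = missing).  Inbred panel
lines are treated as single genomes, so homozygous diploid VCF genotypes
collapse to one call per line; heterozygous residues are conservatively
treated as missing.

Phenotypes come in two shapes: a :class:`SurvivalTable` of per-vial death
counts at fixed inspection checkpoints (2.5, 5, 11, 24, 48 h), and a
:class:`BinomialTable` of alive/dead counts at 48 h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("resistscan")

#: Inspection checkpoints, in hours post exposure.
CHECKPOINTS: tuple[float, ...] = (2.5, 5.0, 11.0, 24.0, 48.0)

#: Right-censoring horizon: survivors at the last checkpoint are censored.
CENSOR_HOUR: float = 48.0

MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries the offending line number."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: chromosome arm, 1-based position, alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: Literal["snp", "indel"] = "snp"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}"


def _vclass(ref: str, alt: str) -> str:
    return "snp" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass
class GenotypePanel:
    """Line-by-variant call matrix for a fully inbred panel.

    ``calls[i, j]`` is the call of line ``i`` at variant ``j``:
    0 (reference), 1 (alternate) or -1 (missing).
    """

    lines: list[str]
    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, vclass
    calls: np.ndarray  # int8, shape (n_lines, n_variants)

    _REQUIRED = ("chrom", "pos", "ref", "alt", "vclass")

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.variants)} variants"
            )
        missing_cols = [c for c in self._REQUIRED if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variants table lacks columns {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(r.chrom, int(r.pos), r.ref, r.alt, r.vclass)
            for r in self.variants.itertuples(index=False)
        ]

    def site_index(self, chrom: str, pos: int) -> int:
        """Column index of the variant at ``chrom:pos``; KeyError if absent."""
        mask = (self.variants["chrom"] == chrom) & (self.variants["pos"] == pos)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"no variant at {chrom}:{pos}")
        return int(idx[0])

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypePanel":
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            lines=list(self.lines),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )

    def take_lines(self, line_ids: Sequence[str]) -> "GenotypePanel":
        lookup = {l: i for i, l in enumerate(self.lines)}
        rows = np.array([lookup[l] for l in line_ids], dtype=int)
        return GenotypePanel(
            lines=list(line_ids),
            variants=self.variants.copy(),
            calls=self.calls[rows, :].copy(),
        )


# ---------------------------------------------------------------------------
# Line metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-line metadata: columns line_id, wolbachia (1/0), population."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    required = {"line_id", "wolbachia", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file lacks columns {sorted(missing)}")
    df["wolbachia"] = df["wolbachia"].astype(int).astype(bool)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out["wolbachia"] = out["wolbachia"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, keep_indels: bool = True) -> GenotypePanel:
    """Read a VCF of (mostly) homozygous lines into a :class:`GenotypePanel`.

    Homozygous 0/0 maps to 0, homozygous 1/1 to 1; heterozygous and missing
    genotypes both map to missing.  Multi-allelic records are dropped with a
    logged count.

    Parameters
    ----------
    path:
        VCF 4.x file with GT fields.
    keep_indels:
        When false, records whose ref or alt allele is longer than one base
        are skipped at read time.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib message passthrough
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has zero samples")

    rows: list[tuple[str, int, str, str, str]] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_multi += 1
                continue
            ref, alt = rec.REF, rec.ALT[0]
            vc = _vclass(ref, alt)
            if vc == "indel" and not keep_indels:
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types
            col = np.full(len(samples), MISSING, dtype=np.int8)
            col[gt == 0] = 0
            col[gt == 3] = 1
            rows.append((rec.CHROM, rec.POS, ref, alt, vc))
            cols.append(col)
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF near data line {len(rows) + n_multi + 1}: {exc}"
        ) from exc
    if n_multi:
        logger.warning("read_vcf: dropped %d multi-allelic records", n_multi)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"])
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypePanel(lines=samples, variants=variants, calls=calls)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed VCF 4.2 file (GT only, ./. missing)."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            arm = panel.variants[panel.variants["chrom"] == chrom]
            length = int(arm["pos"].max()) + 1000 if len(arm) else 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.lines)
            + "\n"
        )
        for j, rec in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site filtering and imputation
# ---------------------------------------------------------------------------

def filter_sites(
    panel: GenotypePanel,
    max_missing: float = 0.18,
    biallelic_only: bool = True,
    drop_indels: bool = False,
) -> GenotypePanel:
    """Apply the standard site filters.

    Sites with a missing-call fraction *strictly greater* than ``max_missing``
    are removed (a site at exactly the boundary is kept).  With
    ``biallelic_only`` the site must show both alleles among the observed
    calls; ``drop_indels`` removes indel records.
    """
    # "> max_missing removed" is strict: compare via integer counts with a
    # small slack so a site at exactly the boundary survives float rounding
    n_missing = (panel.calls == MISSING).sum(axis=0)
    keep = n_missing <= max_missing * panel.n_lines + 1e-9
    if drop_indels:
        keep &= (panel.variants["vclass"] == "snp").to_numpy()
    if biallelic_only:
        has_ref = (panel.calls == 0).any(axis=0)
        has_alt = (panel.calls == 1).any(axis=0)
        keep &= has_ref & has_alt
    kept_idx = np.flatnonzero(keep)
    n_removed = panel.n_variants - kept_idx.size
    if n_removed:
        logger.info("filter_sites: removed %d of %d sites", n_removed, panel.n_variants)
    return panel.take_sites(kept_idx)


def impute_missing(
    panel: GenotypePanel,
    mode: Literal["major_allele", "frequency"] = "major_allele",
    seed: int | None = None,
) -> GenotypePanel:
    """Fill missing calls so haplotype statistics see complete data.

    ``major_allele`` fills every missing call with the per-site modal observed
    allele (ties broken toward the reference) and is fully deterministic.
    ``frequency`` draws the alternate allele with probability equal to the
    observed alternate frequency, under ``seed``.
    """
    calls = panel.calls.copy()
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = np.flatnonzero(n_obs == 0)[:5]
        raise ValueError(
            f"cannot impute sites with all calls missing (e.g. column {bad.tolist()})"
        )
    n_alt = (calls == 1).sum(axis=0)
    if mode == "major_allele":
        fill = (n_alt * 2 > n_obs).astype(np.int8)  # tie (==) falls to ref
        fill_matrix = np.broadcast_to(fill, calls.shape)
        calls = np.where(obs, calls, fill_matrix)
    elif mode == "frequency":
        rng = np.random.default_rng(seed)
        freq = n_alt / n_obs
        draws = (rng.random(calls.shape) < freq[None, :]).astype(np.int8)
        calls = np.where(obs, calls, draws)
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    return GenotypePanel(
        lines=list(panel.lines), variants=panel.variants.copy(), calls=calls
    )


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

_SURV_FIXED = ["line_id", "experiment_id", "vial_id", "n_start"]
_BIN_COLS = ["line_id", "experiment_id", "alive_48", "dead_48"]


def _checkpoint_col(hour: float) -> str:
    s = f"{hour:g}"
    return f"deaths_{s}"


SURVIVAL_DEATH_COLS = [_checkpoint_col(h) for h in CHECKPOINTS]


@dataclass
class SurvivalTable:
    """Per line x experiment x vial death counts at fixed checkpoints."""

    data: pd.DataFrame  # _SURV_FIXED + SURVIVAL_DEATH_COLS

    def __post_init__(self) -> None:
        df = self.data
        for c in _SURV_FIXED + SURVIVAL_DEATH_COLS:
            if c not in df.columns:
                raise ValueError(f"survival table lacks column {c!r}")
        extra = [
            c
            for c in df.columns
            if c.startswith("deaths_") and c not in SURVIVAL_DEATH_COLS
        ]
        if extra:
            raise ValueError(
                f"unknown checkpoint columns {extra}; allowed checkpoints are "
                f"{list(CHECKPOINTS)}"
            )
        deaths = df[SURVIVAL_DEATH_COLS].to_numpy()
        total = deaths.sum(axis=1)
        over = total > df["n_start"].to_numpy()
        if over.any():
            row = int(np.flatnonzero(over)[0])
            raise ValueError(
                f"survival table row {row} ({df.iloc[row]['line_id']}): total "
                f"deaths {int(total[row])} exceed n_start {int(df.iloc[row]['n_start'])}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.data["line_id"]))

    def survivors_48(self) -> np.ndarray:
        """Right-censored survivor count per vial."""
        return (
            self.data["n_start"].to_numpy()
            - self.data[SURVIVAL_DEATH_COLS].to_numpy().sum(axis=1)
        )


@dataclass
class BinomialTable:
    """Per line x experiment alive/dead counts at 48 h."""

    data: pd.DataFrame  # _BIN_COLS

    def __post_init__(self) -> None:
        df = self.data
        for c in _BIN_COLS:
            if c not in df.columns:
                raise ValueError(f"binomial table lacks column {c!r}")
        tot = df["alive_48"].to_numpy() + df["dead_48"].to_numpy()
        if (tot <= 0).any():
            row = int(np.flatnonzero(tot <= 0)[0])
            raise ValueError(f"binomial table row {row}: alive_48 + dead_48 must be > 0")
        self.data = df.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.data["line_id"]))


def read_phenotypes(
    path: str | Path, kind: Literal["survival", "binomial"]
) -> SurvivalTable | BinomialTable:
    """Read a tab-separated phenotype table of the given kind."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    if kind == "survival":
        return SurvivalTable(df)
    if kind == "binomial":
        return BinomialTable(df)
    raise ValueError(f"unknown phenotype kind {kind!r}")


def write_phenotypes(table: SurvivalTable | BinomialTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def survival_proportion_48h(table: SurvivalTable | BinomialTable) -> pd.DataFrame:
    """Per-line mean +/- SE of the proportion of flies alive at 48 h.

    The proportion is computed per replicate vial and averaged per line; the
    SE is the standard error over replicates (0 for a single replicate).
    Output is sorted by decreasing mean survival, as in a ranked-line plot.
    """
    df = table.data
    if isinstance(table, SurvivalTable):
        prop = table.survivors_48() / df["n_start"].to_numpy()
    else:
        tot = df["alive_48"].to_numpy() + df["dead_48"].to_numpy()
        prop = df["alive_48"].to_numpy() / tot
    per_vial = pd.DataFrame({"line_id": df["line_id"], "prop": prop})
    grouped = per_vial.groupby("line_id")["prop"]
    out = grouped.agg(mean="mean", n="size").reset_index()
    sd = grouped.std(ddof=1).fillna(0.0).to_numpy()
    out["se"] = np.where(out["n"] > 1, sd / np.sqrt(out["n"]), 0.0)
    empty = out["n"] == 0
    if empty.any():  # pragma: no cover - groupby cannot produce empty groups
        logger.warning("survival_proportion_48h: excluding lines with zero vials")
        out = out[~empty]
    return out.sort_values("mean", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
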