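"""End-to-end run orchestration.

A :class:`RunConfig` (usually loaded from YAML) either points at input files
(VCF genotypes, phenotype TSV, metadata TSV, resistance locus set) or embeds
a ``simulate`` block; :func:`run_pipeline` then executes

    ingest/simulate -> filter -> impute -> association scan -> nested scan
    -> H12 scan -> split H12 -> NJ tree -> heritability -> combo frequencies

writing every artifact plus a machine-readable manifest (artifact paths,
SHA-256 digests, config hash, per-stage seeds) into the output directory.
Outputs are byte-stable under a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from . import assoc, njtree, panel_io, popsummaries, simulate, sweepscan

logger = logging.getLogger("resistscan")

_STAGES = (
    "ingest", "filter", "impute", "gwas", "nested_gwas",
    "h12", "split_h12", "nj_tree", "heritability", "freqs",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline settings; exactly one of ``inputs`` / ``simulate`` is set."""

    outdir: str
    seed: int = 0
    model: Literal["survival", "binomial"] = "binomial"
    inputs: dict[str, str] | None = None  # vcf, phenotypes, metadata, locus_set
    simulate: dict[str, Any] | None = None
    p_candidate: float = 1e-4
    window_sites: int = 800
    tree_width_bp: int = 200_000
    h12_step_sites: int = 1
    max_missing: float = 0.18

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of inputs/simulate must be present")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "model": self.model,
            "inputs": self.inputs,
            "simulate": self.simulate,
            "p_candidate": self.p_candidate,
            "window_sites": self.window_sites,
            "tree_width_bp": self.tree_width_bp,
            "h12_step_sites": self.h12_step_sites,
            "max_missing": self.max_missing,
        }


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(1000 + idx,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Any stage error raises :class:`PipelineError` naming the stage; artifacts
    written before the failure are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict[str, str]] = []
    seeds = {s: stage_seed(config.seed, s) for s in _STAGES}

    def record(name: str, path: Path) -> None:
        artifacts.append(
            {"name": name, "path": path.name, "sha256": _sha256(path)}
        )

    truth: dict[str, Any] | None = None
    locus_set: pd.DataFrame | None = None

    # ---- ingest / simulate ------------------------------------------------
    try:
        if config.simulate is not None:
            sim_block = dict(config.simulate)
            pheno_block = sim_block.pop("phenotype", {})
            sim_cfg = simulate.SimConfig.from_dict(
                {**sim_block, "seed": seeds["ingest"]}
            )
            panel, metadata, truth = simulate.simulate_panel(sim_cfg)
            if config.model == "survival":
                phenotypes: panel_io.SurvivalTable | panel_io.BinomialTable = (
                    simulate.simulate_survival(
                        panel, metadata, truth, seed=seeds["ingest"], **pheno_block
                    )
                )
            else:
                phenotypes = simulate.simulate_binomial(
                    panel, metadata, truth, seed=seeds["ingest"], **pheno_block
                )
            p = outdir / "panel.vcf"
            panel_io.write_vcf(panel, p)
            record("genotypes_vcf", p)
            p = outdir / "metadata.tsv"
            panel_io.write_metadata(metadata, p)
            record("metadata_tsv", p)
            p = outdir / "phenotypes.tsv"
            panel_io.write_phenotypes(phenotypes, p)
            record("phenotypes_tsv", p)
            p = outdir / "truth.json"
            with open(p, "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
            record("truth_json", p)
            planted = [l for l in truth["loci"]]
            if planted:
                locus_set = pd.DataFrame(
                    {
                        "arm": [l["arm"] for l in planted],
                        "pos": [l["pos"] for l in planted],
                        "resistant_allele": 1,
                        "group": [l["tag"] for l in planted],
                    }
                )
        else:
            inputs = config.inputs or {}
            panel = panel_io.read_vcf(inputs["vcf"])
            metadata = panel_io.read_metadata(inputs["metadata"])
            kind = "survival" if config.model == "survival" else "binomial"
            phenotypes = panel_io.read_phenotypes(inputs["phenotypes"], kind)
            if inputs.get("locus_set"):
                locus_set = sweepscan.read_locus_set(inputs["locus_set"])
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    # ---- filter + impute --------------------------------------------------
    try:
        panel_f = panel_io.filter_sites(panel, max_missing=config.max_missing)
    except Exception as exc:
        raise PipelineError("filter", exc) from exc
    try:
        panel_i = panel_io.impute_missing(panel_f, mode="major_allele")
    except Exception as exc:
        raise PipelineError("impute", exc) from exc

    # ---- association scan -------------------------------------------------
    try:
        result = assoc.gwas_scan(panel_i, phenotypes, metadata, model=config.model)
        p = outdir / "gwas.tsv"
        result.to_tsv(p)
        record("gwas_tsv", p)
        cand = assoc.candidate_table(result, threshold_p=config.p_candidate)
        p = outdir / "gwas_candidates.tsv"
        cand.to_csv(p, sep="\t", index=False)
        record("gwas_candidates_tsv", p)
    except Exception as exc:
        raise PipelineError("gwas", exc) from exc

    # ---- nested scan ------------------------------------------------------
    try:
        top = result.top_hit()
        if top is not None:
            nested = assoc.nested_scan(
                panel_i, phenotypes, metadata,
                top_variant=(str(top["chrom"]), int(top["pos"])),
                model=config.model,
            )
            p = outdir / "nested_gwas.tsv"
            nested.to_tsv(p)
            record("nested_gwas_tsv", p)
    except Exception as exc:
        raise PipelineError("nested_gwas", exc) from exc

    # ---- H12 scan ---------------------------------------------------------
    try:
        frames = []
        for arm in pd.unique(panel_i.variants["chrom"]):
            scan = sweepscan.h12_scan(
                panel_i, arm,
                window_sites=config.window_sites,
                step_sites=config.h12_step_sites,
            )
            frames.append(scan)
        h12_all = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame()
        )
        p = outdir / "h12_scan.tsv"
        h12_all.to_csv(p, sep="\t", index=False)
        record("h12_scan_tsv", p)
    except Exception as exc:
        raise PipelineError("h12", exc) from exc

    # ---- split H12 --------------------------------------------------------
    try:
        if locus_set is not None and len(locus_set):
            arm = locus_set.iloc[0]["arm"]
            try:
                split = sweepscan.split_h12(
                    panel_i, arm, locus_set,
                    window_sites=config.window_sites,
                    seed=seeds["split_h12"],
                    step_sites=config.h12_step_sites,
                )
                p = outdir / "split_h12.tsv"
                split.to_csv(p, sep="\t", index=False)
                record("split_h12_tsv", p)
            except ValueError as exc:
                logger.warning("split_h12 skipped: %s", exc)
    except Exception as exc:
        raise PipelineError("split_h12", exc) from exc

    # ---- NJ tree ----------------------------------------------------------
    try:
        if locus_set is not None and len(locus_set):
            arm = locus_set.iloc[0]["arm"]
            center = int(locus_set.iloc[0]["pos"])
        else:
            arm = panel_i.variants.iloc[0]["chrom"]
            arm_pos = panel_i.variants.loc[
                panel_i.variants["chrom"] == arm, "pos"
            ]
            center = int(arm_pos.median())
        D = njtree.window_distances(
            panel_i, arm, center, width_bp=config.tree_width_bp
        )
        tree = njtree.neighbor_joining(D)
        if locus_set is not None and len(locus_set):
            arm_loci = locus_set[locus_set["arm"] == arm]
            njtree.label_leaves(tree, panel_i, arm_loci)
        p = outdir / "haplotype_tree.nwk"
        p.write_text(njtree.write_newick(tree) + "\n")
        record("haplotype_tree_newick", p)
    except Exception as exc:
        raise PipelineError("nj_tree", exc) from exc

    # ---- heritability -----------------------------------------------------
    try:
        scale = "death_hour" if config.model == "survival" else "proportion_alive"
        reps = popsummaries.line_replicate_values(phenotypes, scale=scale)
        vc = popsummaries.variance_components(reps)
        p = outdir / "heritability.json"
        with open(p, "w") as fh:
            json.dump(
                {
                    "scale": scale,
                    "Ve": vc.ve,
                    "Vg": vc.vg,
                    "h2": vc.h2,
                    "n_lines": vc.n_lines,
                    "n_individuals": vc.n_individuals,
                },
                fh, indent=1, sort_keys=True,
            )
        record("heritability_json", p)
    except Exception as exc:
        raise PipelineError("heritability", exc) from exc

    # ---- combination frequencies ------------------------------------------
    try:
        if locus_set is not None and len(locus_set):
            freqs = popsummaries.combo_frequencies(panel_i, metadata, locus_set)
            p = outdir / "combo_freqs.tsv"
            freqs.to_csv(p, sep="\t", index=False)
            record("combo_freqs_tsv", p)
    except Exception as exc:
        raise PipelineError("freqs", exc) from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "artifacts": sorted(artifacts, key=lambda a: a["name"]),
    }
    p = outdir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("run_pipeline: wrote %d artifacts to %s", len(artifacts), outdir)
    return outdir
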