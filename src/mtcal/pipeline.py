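"""End-to-end pipeline: simulate/load -> classify -> CAL -> diff -> report.

One structured YAML config drives every stage; outputs are TSVs plus a
reproducibility manifest (tool version, config hash, per-stage row counts,
sha256 digest of every output file). Reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cal import (
    annotate_dna_regions,
    annotate_rna_genes,
    cal_table,
    per_gene_condition_contrast,
    region_cal_table,
)
from .contacts import categorize_pairs, read_pairs, write_pairs, write_tsv
from .diffassoc import (
    deg_concordance,
    deg_direction,
    gene_set_enrichment,
    promoter_diff_test,
    read_deg_table,
)
from .genome import GeneIndex, read_bed, read_gtf
from .numt import classify_pairs, read_numts_fasta
from .simulate import (
    SNC_GENE_ID,
    SynthConfig,
    make_toy_genome,
    simulate_deg_tables,
    simulate_pairs,
    write_bundle,
)

logger = logging.getLogger("mtcal")

STAGES = [
    "simulate",
    "classify_numt",
    "categorize",
    "cal",
    "region_cal",
    "diff_promoter",
    "enrich",
    "concordance",
    "report",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    config_hash: str
    seed: int
    stages: List[str] = field(default_factory=list)
    row_counts: Dict[str, int] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def config_hash(config: dict) -> str:
    """Stable hash of a config dict (invariant to key order)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} did not parse to a mapping")
    return cfg


def run_pipeline(
    config: dict | str,
    outdir: str,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run every stage in dependency order; any failure aborts stage-named."""
    if isinstance(config, str):
        config = load_config(config)
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(__version__, config_hash(cfg), int(cfg["seed"]))
    meta = {"config_hash": manifest.config_hash, "seed": str(cfg["seed"])}

    def emit(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(outdir, name)
        write_tsv(df, path, meta)
        manifest.row_counts[name] = int(len(df))
        return path

    rng = np.random.default_rng(int(cfg["seed"]))

    # ---- stage: simulate (or load external inputs) ------------------------
    stage = "simulate"
    try:
        sim_cfg = dict(cfg.get("simulate", {}))
        inputs = cfg.get("inputs")
        deg_cfg = dict(cfg.get("deg", {}))
        if inputs:
            genes = read_gtf(inputs["genes_gtf"], mt_chrom=inputs.get("mt_chrom", "chrM"))
            enhancers = read_bed(inputs["enhancers_bed"]) if "enhancers_bed" in inputs else []
            ses = read_bed(inputs["super_enhancers_bed"]) if "super_enhancers_bed" in inputs else []
            induced = []
            if "induced_genes" in inputs:
                with open(inputs["induced_genes"]) as fh:
                    induced = [l.strip() for l in fh if l.strip()]
            from .genome import build_region_partition

            partition = build_region_partition(
                genes, enhancers, ses, induced,
                promoter_window=tuple(inputs.get("promoter_window", (2000, 500))),
            )
            frame, _ = read_pairs(
                inputs["pairs"], dialect=inputs.get("dialect", "pairs_4dn")
            )
            numts = read_numts_fasta(inputs["numts_fasta"]) if "numts_fasta" in inputs else []
            deg_tables = {
                lab: read_deg_table(p, lab)
                for lab, p in inputs.get("deg_tables", {}).items()
            }
            junction_kmer = inputs.get("junction_kmer")
            mt_chrom = inputs.get("mt_chrom", "chrM")
            bundle = None
        else:
            sim_cfg.setdefault("seed", int(cfg["seed"]))
            synth = SynthConfig.from_dict(sim_cfg)
            bundle = make_toy_genome(synth, rng=rng)
            genes = bundle.genes
            partition = bundle.partition
            numts = bundle.numts
            mt_chrom = bundle.mt_chrom
            junction_kmer = bundle.junction_kmer
            induced = bundle.induced_gene_ids
            frame, truth = simulate_pairs(bundle, synth, rng=rng)
            paths = write_bundle(bundle, outdir)
            manifest.files.update(
                {os.path.basename(p): "" for p in paths.values()}
            )
            write_pairs(
                frame, os.path.join(outdir, "pairs.pairs"),
                chrom_sizes={**bundle.chrom_sizes, mt_chrom: 16569},
            )
            emit("truth.tsv", truth.labels)
            nuclear_ids = [g.gene_id for g in bundle.nuclear_genes]
            n_planted = int(deg_cfg.get("planted_down_n", 40))
            planted_down = sorted(
                rng.choice(nuclear_ids, size=min(n_planted, len(nuclear_ids)),
                           replace=False).tolist()
            )
            deg_tables, _ = simulate_deg_tables(
                nuclear_ids,
                planted_down=planted_down,
                gainer_set=induced,
                planted_or=float(deg_cfg.get("planted_or", 4.0)),
                reduced_rate=float(deg_cfg.get("reduced_rate", 0.05)),
                rng=rng,
            )
            for lab, df in deg_tables.items():
                emit(f"deg_{lab}.tsv", df)
        manifest.stages.append(stage)
        manifest.row_counts["pairs"] = int(len(frame))
        logger.info("stage=%s pairs=%d", stage, len(frame))
    except (KeyError, FileNotFoundError, OSError, ValueError) as e:
        raise PipelineError(stage, str(e)) from e

    # annotate once for all downstream stages
    annotated = annotate_rna_genes(
        frame, genes, junction_kmer=junction_kmer, junction_gene=SNC_GENE_ID
    )
    annotated = annotate_dna_regions(annotated, partition, mt_chrom)
    annotated["rna_group"] = np.where(
        annotated["rna_class"].astype(str).str.startswith("mt_"), "mt",
        np.where(annotated["rna_class"].notna(), "nuclear", None),
    )

    # ---- stage: classify_numt ---------------------------------------------
    stage = "classify_numt"
    try:
        numt_cfg = dict(cfg.get("numt", {}))
        mt_pairs = annotated[annotated["rna_group"] == "mt"]
        has_seq = mt_pairs["rna_seq"].map(lambda s: isinstance(s, str) and bool(s))
        if numts and has_seq.any():
            calls, summary = classify_pairs(
                mt_pairs[has_seq],
                numts,
                threshold=int(numt_cfg.get("threshold", 5)),
                seed_k=int(numt_cfg.get("seed_k", 12)),
            )
            emit("numt_calls.tsv", calls)
            emit("numt_summary.tsv", pd.DataFrame([summary]))
        else:
            logger.warning("stage=%s skipped: no NUMTs or no sequences", stage)
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: categorize -------------------------------------------------
    stage = "categorize"
    try:
        gene_index = GeneIndex([g for g in genes if g.gene_id != SNC_GENE_ID])
        counts, per_lib = categorize_pairs(annotated, gene_index, mt_chrom)
        emit("pair_categories.tsv", per_lib)
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: cal --------------------------------------------------------
    stage = "cal"
    try:
        emit("cal_class.tsv", cal_table(annotated, genes, scope="class"))
        emit("cal_gene.tsv", cal_table(annotated, genes, scope="gene"))
        conds = sorted(annotated["condition"].unique())
        if len(conds) == 2:
            den, num = conds
            if "HT" in conds:  # treatment as numerator when recognisable
                num = "HT"
                den = [c for c in conds if c != "HT"][0]
            contrast = per_gene_condition_contrast(
                annotated, genes, num, den, mt_chrom=mt_chrom
            )
            emit(f"cal_contrast_{num}_vs_{den}.tsv", contrast)
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: region_cal -------------------------------------------------
    stage = "region_cal"
    try:
        rc = region_cal_table(annotated, partition, genes, scope="class",
                              mt_chrom=mt_chrom)
        emit("region_cal.tsv", rc)
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: diff_promoter ----------------------------------------------
    stage = "diff_promoter"
    diff_res = None
    try:
        diff_cfg = dict(cfg.get("diff", {}))
        focal = str(diff_cfg.get("focal", "class:mt"))
        if ":" in focal:
            kind, name = focal.split(":", 1)
        else:
            kind, name = "gene", focal
        focal_key = {"gene": "gene_id", "class": "rna_class"}.get(kind, "gene_id")
        if kind == "class" and name == "mt":
            focal_key = "rna_group"
        conds = sorted(annotated["condition"].unique())
        if len(conds) == 2:
            nm, ht = conds[0], conds[1]
            if "HT" in conds:
                ht = "HT"
                nm = [c for c in conds if c != "HT"][0]
            diff_res = promoter_diff_test(
                annotated[annotated["condition"] == nm],
                annotated[annotated["condition"] == ht],
                name,
                partition,
                focal_key=focal_key,
                test=str(diff_cfg.get("test", "fisher_2x2")),
                alternative=str(diff_cfg.get("alternative", "greater")),
                mt_chrom=mt_chrom,
            )
            emit("diff_promoter.tsv", diff_res)
        else:
            logger.warning("stage=%s skipped: need exactly 2 conditions", stage)
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: enrich -----------------------------------------------------
    stage = "enrich"
    try:
        enr_cfg = dict(cfg.get("enrich", {}))
        alpha = float(enr_cfg.get("alpha", 0.05))
        kd_label = str(enr_cfg.get("kd_table", sorted(deg_tables)[0] if deg_tables else ""))
        if diff_res is not None and deg_tables and kd_label in deg_tables:
            kd = deg_tables[kd_label]
            universe = set(kd["gene"])
            gainers = set(
                diff_res.loc[
                    (diff_res["q_value"] < alpha) & (diff_res["log2_effect"] > 0),
                    "gene_id",
                ]
            ) & universe
            reduced = deg_direction(kd, "down", float(enr_cfg.get("padj_threshold", 0.05)))
            res = gene_set_enrichment(gainers, reduced, universe)
            emit("enrichment.tsv", pd.DataFrame([res.__dict__]))
        else:
            logger.warning("stage=%s skipped: missing diff results or DEG table", stage)
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: concordance ------------------------------------------------
    stage = "concordance"
    try:
        if len(deg_tables) >= 2:
            conc = deg_concordance(deg_tables)
            rows = [
                {"metric": "kway_down_n", "pair": "all", "value": conc["kway_n"]},
                {"metric": "n_scc_genes", "pair": "all", "value": conc["n_scc_genes"]},
            ]
            for (a, b), v in sorted(conc["pairwise_n"].items()):
                rows.append({"metric": "pairwise_down_n", "pair": f"{a}|{b}", "value": v})
            for (a, b), v in sorted(conc["pairwise_scc"].items()):
                rows.append({"metric": "spearman_log2fc", "pair": f"{a}|{b}", "value": v})
            emit("concordance.tsv", pd.DataFrame(rows))
        manifest.stages.append(stage)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage: report -----------------------------------------------------
    stage = "report"
    lines = [
        f"# mtcal run report",
        "",
        f"- tool version: {__version__}",
        f"- config hash: {manifest.config_hash}",
        f"- seed: {manifest.seed}",
        f"- stages completed: {', '.join(manifest.stages + [stage])}",
        "",
        "| output | rows |",
        "|---|---|",
    ]
    for name, n in sorted(manifest.row_counts.items()):
        lines.append(f"| {name} | {n} |")
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    manifest.stages.append(stage)

    # digests over every output file
    for fname in sorted(os.listdir(outdir)):
        fpath = os.path.join(outdir, fname)
        if os.path.isfile(fpath) and fname != "manifest.json":
            manifest.files[fname] = sha256_file(fpath)
    manifest.to_json(os.path.join(outdir, "manifest.json"))
    return manifest
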