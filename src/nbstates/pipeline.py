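"""End-to-end pipeline orchestration and the reproducibility manifest.

``run_pipeline`` executes the stages in their natural order — normalize,
differential expression of each clone against the parental line, multi-clone
intersection, pre-ranked GSEA, ADRN/MES signature scores, and (when a
single-cell reference is configured) lineage correlation mapping,
exclusivity tests and hierarchical clustering — writing every artifact as
TSV/Newick into a run directory together with a manifest recording the
configuration, input checksums, seed, per-stage row counts and warnings.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import (
    DEConfig,
    call_de_genes,
    estimate_size_factors,
    intersect_de_across_clones,
    normalize,
    wald_de_test,
)
from .gsea import gsea_preranked, make_ranked_list, read_gmt
from .io import (
    atomic_write_text,
    read_cell_annotations,
    read_condition_table,
    read_count_matrix,
    read_ortholog_map,
    read_signature_list,
)
from .lineage import (
    binarize_expression,
    correlate_clones_to_cells,
    exclusivity_test,
    hierarchical_cluster,
    map_orthologs,
    mean_correlation_by_type,
)
from .signatures import SignaturePair, score_clones

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts: str = ""
    conditions: str = ""
    reference_group: str = "parental"
    mes_signature: str = ""
    adrn_signature: str = ""
    gmt: str = ""
    sc_counts: str = ""
    sc_annotations: str = ""
    orthologs: str = ""
    exclusivity_pairs: list[list[str]] = field(default_factory=list)
    # clone comparisons whose DE lists are intersected (e.g. the KO clones,
    # excluding an overexpressor whose response runs the opposite way);
    # empty = all non-reference groups
    intersect_groups: list[str] = field(default_factory=list)
    lfc_threshold: float = 2.0
    alpha: float = 0.01
    min_total_count: int = 10
    gsea_transform: str = "absolute"
    n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    use_log: bool = True
    linkage: str = "complete"
    seed: int = 0
    out_dir: str = "nbstates_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def de_config(self) -> DEConfig:
        return DEConfig(
            lfc_threshold=self.lfc_threshold,
            alpha=self.alpha,
            min_total_count=self.min_total_count,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary.

    Stages needing unconfigured inputs (GSEA without a GMT, lineage without
    a reference) are marked "skipped" in the manifest.  Any stage error
    aborts the run, removes the partially written run directory, and
    re-raises as PipelineError naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "input_checksums": {},
        "stages": {},
        "warnings": [],
    }
    for key in ("counts", "conditions", "mes_signature", "adrn_signature",
                "gmt", "sc_counts", "sc_annotations", "orthologs"):
        path = getattr(cfg, key)
        if path:
            if not Path(path).exists():
                raise PipelineError("config", f"input file {path} does not exist")
            manifest["input_checksums"][key] = _sha256(path)

    try:
        stage = "load"
        condition = read_condition_table(cfg.conditions)
        fmt = "mtx" if str(cfg.counts).endswith(".mtx") else "tsv"
        cm = read_count_matrix(cfg.counts, fmt=fmt, condition=condition)
        manifest["stages"]["load"] = {"n_genes": cm.shape[0], "n_samples": cm.shape[1]}

        stage = "normalize"
        sf = estimate_size_factors(cm)
        norm = normalize(cm, sf)
        sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
        manifest["stages"]["normalize"] = {"size_factors": sf.round(6).to_dict()}

        stage = "de"
        de_cfg = cfg.de_config()
        groups = [g for g in condition.unique() if g != cfg.reference_group]
        up_lists: dict[str, list[str]] = {}
        down_lists: dict[str, list[str]] = {}
        tables: dict[str, pd.DataFrame] = {}
        for group in groups:
            table = wald_de_test(cm, cfg.reference_group, group, de_cfg, size_factors=sf)
            table.index.name = "gene"
            table.to_csv(out / f"de_{group}_vs_{cfg.reference_group}.tsv", sep="\t")
            up_lists[group], down_lists[group] = call_de_genes(table, de_cfg)
            tables[group] = table
        manifest["stages"]["de"] = {
            g: {"n_up": len(up_lists[g]), "n_down": len(down_lists[g]),
                "n_tested": len(tables[g])}
            for g in groups
        }

        stage = "intersect"
        inter_groups = [
            g for g in (cfg.intersect_groups or groups) if g in up_lists
        ]
        if len(inter_groups) >= 2:
            inter = intersect_de_across_clones(
                {g: up_lists[g] for g in inter_groups},
                {g: down_lists[g] for g in inter_groups},
            )
            atomic_write_text(
                out / "common_de_genes.tsv",
                "gene\tdirection\n"
                + "".join(f"{g}\tup\n" for g in inter.common_up)
                + "".join(f"{g}\tdown\n" for g in inter.common_down),
            )
            manifest["stages"]["intersect"] = {
                "n_common_up": len(inter.common_up),
                "n_common_down": len(inter.common_down),
            }
        else:
            manifest["stages"]["intersect"] = "skipped"

        stage = "gsea"
        if cfg.gmt:
            collection = read_gmt(cfg.gmt)
            for group, table in tables.items():
                ranked = make_ranked_list(table, transform=cfg.gsea_transform)
                result, skipped_sets = gsea_preranked(
                    ranked, collection, n_perm=cfg.n_perm, seed=cfg.seed,
                    min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
                )
                result.to_csv(out / f"gsea_{group}.tsv", sep="\t")
                manifest["stages"].setdefault("gsea", {})[group] = {
                    "n_sets_tested": len(result),
                    "n_sets_skipped": len(skipped_sets),
                }
        else:
            manifest["stages"]["gsea"] = "skipped"

        stage = "signatures"
        if cfg.mes_signature and cfg.adrn_signature:
            pair = SignaturePair(
                adrn_genes=read_signature_list(cfg.adrn_signature),
                mes_genes=read_signature_list(cfg.mes_signature),
            )
            scores, medians = score_clones(norm, pair, condition)
            scores.index.name = "sample"
            scores.to_csv(out / "signature_scores.tsv", sep="\t")
            medians.to_csv(out / "signature_score_medians.tsv", sep="\t")
            manifest["stages"]["signatures"] = {"n_samples": len(scores)}
        else:
            manifest["stages"]["signatures"] = "skipped"

        stage = "lineage"
        if cfg.sc_counts and cfg.sc_annotations:
            sc_fmt = "mtx" if str(cfg.sc_counts).endswith(".mtx") else "tsv"
            sc = read_count_matrix(cfg.sc_counts, fmt=sc_fmt)
            annot = read_cell_annotations(cfg.sc_annotations)
            ortho = read_ortholog_map(cfg.orthologs) if cfg.orthologs else None
            mapped, report = map_orthologs(sc.counts, ortho)
            sc_sf = estimate_size_factors(mapped, positive_geomean_fallback=True)
            sc_norm = normalize(mapped, sc_sf)
            cmap = correlate_clones_to_cells(
                norm, sc_norm, annot, clone_groups=condition, use_log=cfg.use_log
            )
            cmap.r.index.name = "cell_id"
            cmap.r.to_csv(out / "correlation_map.tsv", sep="\t")
            by_type = mean_correlation_by_type(cmap)
            by_type.to_csv(out / "mean_correlation_by_type.tsv", sep="\t")
            manifest["stages"]["lineage"] = {
                "n_genes_used": cmap.n_genes_used,
                "n_unmapped": len(report.unmapped),
                "n_cells": cmap.r.shape[0],
            }

            binary = binarize_expression(mapped)
            rows = []
            for pair_ab in cfg.exclusivity_pairs:
                res = exclusivity_test(binary, pair_ab[0], pair_ab[1])
                (a, b), (c, d) = res.table
                rows.append(
                    (res.gene_a, res.gene_b, a, b, c, d, res.odds_ratio,
                     res.pvalue, res.direction)
                )
            if rows:
                pd.DataFrame(
                    rows,
                    columns=["geneA", "geneB", "a", "b", "c", "d",
                             "odds_ratio", "pvalue", "direction"],
                ).to_csv(out / "exclusivity.tsv", sep="\t", index=False)
            manifest["stages"]["exclusivity"] = {"n_pairs": len(rows)}

            stage = "clustering"
            cells_tree = hierarchical_cluster(cmap.r, axis="rows", method=cfg.linkage)
            clones_tree = hierarchical_cluster(cmap.r, axis="columns", method=cfg.linkage)
            atomic_write_text(out / "cells_dendrogram.nwk", cells_tree.newick + "\n")
            atomic_write_text(out / "clones_dendrogram.nwk", clones_tree.newick + "\n")
            manifest["stages"]["clustering"] = {
                "cell_leaves": len(cells_tree.labels),
                "clone_leaves": len(clones_tree.labels),
            }
        else:
            manifest["stages"]["lineage"] = "skipped"
            manifest["stages"]["exclusivity"] = "skipped"
            manifest["stages"]["clustering"] = "skipped"
    except PipelineError:
        shutil.rmtree(out, ignore_errors=True)
        raise
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(stage, str(exc)) from exc

    atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
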