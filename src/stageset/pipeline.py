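"""End-to-end orchestration: simulate/load -> DE -> selective sets ->
clustering -> enrichment -> cross-talk, with a deterministic run manifest.

The comparator scheme follows the two-axis design of the four-population
study: each condition is compared against the same cell type at the other
stage and the other cell type at the same stage (G9 vs {G22, S9}, etc.).
For condition vocabularies where that rule does not parse, every other
condition is a comparator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from .cluster import cluster, heatmap_order, to_newick
from .crosstalk import demo_pair_table, find_crosstalk
from .diffexpr import (
    DEConfig,
    concordance_select,
    detection_call,
    pairwise_change_calls,
    summarize_signal,
)
from .enrich import EnrichConfig, enrich
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    PairTable,
    read_expression_matrix,
    read_gene_sets,
    read_pair_table,
    write_expression_matrix,
    write_gene_sets,
    write_results,
    write_sample_sheet,
)
from .selective import build_selective, check_disjoint, pairwise_up_list

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "report", "default_comparators"]

_STAGE_PAIR = {"G9": ("G22", "S9"), "S9": ("S22", "G9"), "G22": ("G9", "S22"), "S22": ("S9", "G22")}


def default_comparators(conditions: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    """Same-cell-type-other-stage + same-stage-other-cell-type, when the
    labels carry the <cell><stage> structure; otherwise all-vs-rest."""
    if set(conditions) == set(_STAGE_PAIR):
        return {c: _STAGE_PAIR[c] for c in conditions}
    return {c: tuple(o for o in conditions if o != c) for c in conditions}


@dataclass
class PipelineConfig:
    out_dir: str | Path = "stageset_run"
    seed: int = 0
    # simulation mode (default) or matrix/sample-sheet paths
    synthetic: sim.SyntheticSpec | None = None
    matrix_path: str | Path | None = None
    samples_path: str | Path | None = None
    categories_path: str | Path | None = None
    lr_pairs_path: str | Path | None = None
    de: DEConfig = field(default_factory=DEConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    comparators: dict[str, tuple[str, ...]] | None = None
    crosstalk_pair: tuple[str, str] = ("G9", "S9")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "planted_blocks" in syn:
                syn["planted_blocks"] = tuple(
                    sim.PlantedBlock(
                        name=b["name"],
                        conditions=tuple(b["conditions"]),
                        n_genes=int(b["n_genes"]),
                        log2_effect=float(b["log2_effect"]),
                    )
                    for b in syn["planted_blocks"]
                )
            if "categories" in syn:
                syn["categories"] = tuple(
                    sim.CategorySpec(
                        name=c["name"],
                        size=int(c["size"]),
                        enriched_block=c.get("enriched_block"),
                    )
                    for c in syn["categories"]
                )
            if "conditions" in syn:
                syn["conditions"] = tuple(syn["conditions"])
            kwargs["synthetic"] = sim.SyntheticSpec(**syn)
        elif kwargs.get("synthetic", "absent") is None or (
            "matrix_path" not in kwargs and "synthetic" not in kwargs
        ):
            kwargs["synthetic"] = sim.default_spec(seed=int(kwargs.get("seed", 0)))
        if "de" in kwargs:
            kwargs["de"] = DEConfig(**kwargs["de"])
        if "enrich" in kwargs:
            kwargs["enrich"] = EnrichConfig(**kwargs["enrich"])
        if "comparators" in kwargs and kwargs["comparators"] is not None:
            kwargs["comparators"] = {
                k: tuple(v) for k, v in kwargs["comparators"].items()
            }
        if "crosstalk_pair" in kwargs:
            kwargs["crosstalk_pair"] = tuple(kwargs["crosstalk_pair"])
        return cls(**kwargs)


def _config_hash(cfg: PipelineConfig) -> str:
    # hash the analysis parameters only, not where the outputs land
    parts = {k: v for k, v in vars(cfg).items() if k not in ("out_dir", "log_level")}
    blob = repr(sorted(parts.items(), key=lambda kv: kv[0])).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _validate(cfg: PipelineConfig, conditions: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    comps = cfg.comparators or default_comparators(conditions)
    for cond, others in comps.items():
        if cond not in conditions:
            raise ValueError(f"comparator scheme names unknown condition {cond!r}")
        bad = set(others) - set(conditions)
        if bad:
            raise ValueError(f"comparators of {cond!r} include unknown conditions {bad}")
        if not others:
            raise ValueError(f"condition {cond!r} has no comparators")
    for c in cfg.crosstalk_pair:
        if c not in conditions:
            raise ValueError(f"crosstalk condition {c!r} not in {conditions}")
    return comps


def run(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed, "stages": {}}
    t_all = time.perf_counter()

    def stage_done(name: str, rows: int) -> None:
        manifest["stages"][name] = {
            "rows": rows,
            "seconds": round(time.perf_counter() - t_stage, 3),
        }

    # --- inputs -----------------------------------------------------------
    t_stage = time.perf_counter()
    truth = None
    categories: GeneSetCollection | None = None
    if cfg.synthetic is not None:
        spec = cfg.synthetic
        if spec.seed != cfg.seed:
            spec = sim.SyntheticSpec(**{**spec.__dict__, "seed": cfg.seed})
        matrix, truth, categories = sim.generate(spec)
        write_expression_matrix(matrix, out / "matrix.tsv")
        write_sample_sheet(matrix.samples, out / "samples.tsv")
        truth.genes.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_gene_sets(categories, out / "categories.gmt")
        background = spec.background_level
    else:
        if cfg.matrix_path is None or cfg.samples_path is None:
            raise ValueError("matrix_path and samples_path required without simulation")
        matrix = read_expression_matrix(cfg.matrix_path, cfg.samples_path)
        background = 16.0
        if cfg.categories_path:
            categories = read_gene_sets(cfg.categories_path, format="gmt")
    conditions = matrix.samples.condition_labels
    comps = _validate(cfg, conditions)
    stage_done("input", matrix.values.shape[0])

    # --- signals & detection ---------------------------------------------
    t_stage = time.perf_counter()
    signals = summarize_signal(matrix, cfg.de.signal_summary)
    detections = detection_call(matrix, background, cfg.de)
    write_results({"detection_calls": detections}, out)
    stage_done("detection", len(detections))

    # --- differential expression -----------------------------------------
    t_stage = time.perf_counter()
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    n_de_rows = 0
    for cond, others in comps.items():
        for ref in others:
            calls = pairwise_change_calls(matrix, cond, ref, cfg.de)
            rec = concordance_select(
                calls, signals, cond, ref, matrix.samples, cfg.de, detections
            )
            de_tables[(cond, ref)] = rec
            rec.to_csv(out / f"de_{cond}_vs_{ref}.tsv", sep="\t", index=False)
            n_de_rows += len(rec)
    stage_done("diff_expression", n_de_rows)

    # --- selective sets ---------------------------------------------------
    t_stage = time.perf_counter()
    results = []
    for cond, others in comps.items():
        up_lists = {ref: pairwise_up_list(de_tables[(cond, ref)]) for ref in others}
        results.append(build_selective(cond, up_lists))
    overlaps = check_disjoint(results)
    selective_sets = GeneSetCollection(
        sets={f"{r.condition}_sel": r.selective for r in results}
    )
    write_gene_sets(selective_sets, out / "selective_sets.gmt")
    venn_rows = [
        {"condition": r.condition, "region": pat, "count": cnt}
        for r in results
        for pat, cnt in sorted(r.venn_counts.items())
    ]
    write_results(
        {
            "venn_counts": pd.DataFrame.from_records(
                venn_rows, columns=["condition", "region", "count"]
            ),
            "selective_overlaps": overlaps,
        },
        out,
    )
    stage_done("selective_sets", sum(len(r.selective) for r in results))

    # --- clustering -------------------------------------------------------
    t_stage = time.perf_counter()
    sample_tree = cluster(signals, axis="samples")
    (out / "sample_tree.nwk").write_text(to_newick(sample_tree) + "\n", "utf-8")
    de_union = sorted(set().union(*(r.selective for r in results)))
    gene_tree = None
    if len(de_union) >= 2:
        gene_tree = cluster(signals.loc[de_union], axis="genes")
        (out / "gene_tree.nwk").write_text(to_newick(gene_tree) + "\n", "utf-8")
        ordered = signals.loc[heatmap_order(gene_tree), heatmap_order(sample_tree)]
        ordered.rename_axis("feature_id").to_csv(out / "heatmap_matrix.tsv", sep="\t")
    stage_done("clustering", len(de_union))

    # --- enrichment -------------------------------------------------------
    t_stage = time.perf_counter()
    enrichment = pd.DataFrame()
    if categories is not None and len(categories):
        enrichment = enrich(selective_sets, categories, cfg=cfg.enrich)
        write_results({"enrichment": enrichment}, out)
    stage_done("enrichment", len(enrichment))

    # --- crosstalk --------------------------------------------------------
    t_stage = time.perf_counter()
    pairs = read_pair_table(cfg.lr_pairs_path) if cfg.lr_pairs_path else demo_pair_table()
    ca, cb = cfg.crosstalk_pair
    universe = frozenset(matrix.gene_ids)
    xt = find_crosstalk(
        selective_sets[f"{ca}_sel"], ca, selective_sets[f"{cb}_sel"], cb, pairs, universe
    )
    write_results({"crosstalk_hits": xt.hits, "crosstalk_stats": xt.stats}, out)
    stage_done("crosstalk", len(xt.hits))

    # --- report -----------------------------------------------------------
    manifest["selective_sizes"] = {
        f"{r.condition}_sel": len(r.selective) for r in results
    }
    manifest["selective_overlap_rows"] = len(overlaps)
    manifest["crosstalk_hits"] = len(xt.hits)
    if not enrichment.empty:
        manifest["enriched_flags"] = int((enrichment["flag"] == "enriched").sum())
    if truth is not None:
        planted_conds = set(truth.genes["selective_condition"]) - {""}
        scoreable = GeneSetCollection(
            sets={
                name: selective_sets[name]
                for name in selective_sets.names()
                if name.removesuffix("_sel") in planted_conds
            }
        )
        confusion = sim.truth_confusion(truth, scoreable)
        confusion.to_csv(out / "recovery.tsv", sep="\t", index=False)
        manifest["recovery"] = {
            row["set_name"]: {
                "sensitivity": row["sensitivity"],
                "fdp": row["fdp"],
            }
            for _, row in confusion.iterrows()
        }
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    return manifest


def report(manifest: dict) -> pd.DataFrame:
    """Flat summary table of a run manifest."""
    rows = [
        {"metric": f"selective_size:{k}", "value": v}
        for k, v in manifest.get("selective_sizes", {}).items()
    ]
    rows.append({"metric": "selective_overlap_rows", "value": manifest.get("selective_overlap_rows", 0)})
    rows.append({"metric": "crosstalk_hits", "value": manifest.get("crosstalk_hits", 0)})
    if "enriched_flags" in manifest:
        rows.append({"metric": "enriched_flags", "value": manifest["enriched_flags"]})
    for name, rec in manifest.get("recovery", {}).items():
        rows.append({"metric": f"sensitivity:{name}", "value": rec["sensitivity"]})
        rows.append({"metric": f"fdp:{name}", "value": rec["fdp"]})
    return pd.DataFrame.from_records(rows)
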