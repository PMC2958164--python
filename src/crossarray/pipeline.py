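"""End-to-end orchestration: filter -> normalize -> select -> enrich -> compare.

One YAML config (or an equivalent dict) drives the whole run. Inputs come
either from files (``inputs:`` block) or from the synthetic generator
(``simulation:`` block); a single top-level seed governs every stochastic
stage. All intermediates are written to ``out_dir`` so every number in the
report can be re-derived from the stage outputs on disk, and a JSON report
summarises counts, the Venn partition of the three differential lists, and
the per-contrast enrichment tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .differential import pairwise_comparisons, venn_partition
from .enrichment import (
    compare_enrichment_across_contrasts,
    enrich,
    read_gmt,
)
from .errors import ParameterError, PipelineStageError
from .io import (
    filter_present_on_all,
    read_annotation,
    read_expression_matrix,
    write_expression_matrix,
)
from .normalize import build_reference_distribution, quantile_normalize

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "threshold": 4.0,
    "jackknife_iterations": 4,
    "smooth": True,
    "smooth_window": 7,
    "sg_order": 2,
    "universe": "detected",
    "q_cutoff": 0.05,
    "top_k": 10,
    "plots": True,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    counts: dict
    venn: dict
    enrichment: dict = field(repr=False)
    parameters: dict = field(repr=False)
    seed: int = 0
    recovery: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "counts": self.counts,
            "venn": self.venn,
            "enrichment": self.enrichment,
            "parameters": self.parameters,
            "seed": self.seed,
        }
        if self.recovery is not None:
            out["recovery"] = self.recovery
        return _jsonable(out)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ParameterError("config must be a mapping or a path to a YAML mapping")
    return config


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise ParameterError(f"config field '{where}.{key}' is missing")
    return block[key]


class _Stage:
    """Context manager that tags stage failures and logs timings."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
            return False
        if isinstance(exc, PipelineStageError):
            return False
        raise PipelineStageError(self.name, exc) from exc


def run_pipeline(config, out_dir=None) -> PipelineReport:
    """Run the full pipeline from a config mapping or YAML path.

    The config has a ``simulation:`` or an ``inputs:`` block, an optional
    ``params:`` block (defaults: J5 threshold 4, 4 jackknife iterations,
    7-point order-2 smoothing, detected universe, q cutoff 0.05), a
    ``seed`` and an ``out_dir``. Returns the report; all intermediates and
    ``report.json`` are written under ``out_dir``.
    """
    config = _load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir or config.get("out_dir", "crossarray_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ParameterError(f"unknown params: {sorted(unknown)}")
    if params["universe"] not in ("detected", "full"):
        raise ParameterError("params.universe must be 'detected' or 'full'")

    has_sim = "simulation" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise ParameterError("config needs exactly one of 'simulation' or 'inputs'")

    truth = None
    if has_sim:
        with _Stage("simulate"):
            sim_block = dict(config["simulation"] or {})
            sim_block["seed"] = seed
            if "groups" in sim_block:
                sim_block["groups"] = tuple(
                    (str(g), int(r)) for g, r in sim_block["groups"]
                )
            for key in ("pathway_size", "effect_multipliers"):
                if key in sim_block:
                    sim_block[key] = tuple(sim_block[key])
            cfg = sim.SyntheticConfig(**sim_block)
            gsc, pmap = sim.generate_gene_universe(cfg)
            matrix, truth = sim.generate_experiment(cfg, gsc, pmap)
            group_order = cfg.group_order
            inputs_dir = out_dir / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            write_expression_matrix(
                matrix,
                inputs_dir / "matrix.tsv",
                calls_path=inputs_dir / "calls.tsv",
                groups_path=inputs_dir / "groups.tsv",
            )
            sim.write_annotation(pmap, inputs_dir / "annotation.csv")
            sim.write_gmt(gsc, inputs_dir / "gene_sets.gmt")
            truth.to_json(inputs_dir / "truth.json")
    else:
        inputs = config["inputs"] or {}
        matrix_path = _require(inputs, "matrix", "inputs")
        groups_path = _require(inputs, "groups", "inputs")
        annotation_path = _require(inputs, "annotation", "inputs")
        gmt_path = _require(inputs, "gene_sets", "inputs")
        with _Stage("read_inputs"):
            matrix = read_expression_matrix(
                matrix_path, groups_path, calls_path=inputs.get("calls")
            )
            pmap = read_annotation(annotation_path)
            gsc = read_gmt(gmt_path)
            group_order = tuple(config.get("group_order") or matrix.group_labels)
    if len(group_order) != 3:
        raise ParameterError("group_order must name exactly three groups")

    with _Stage("presence_filter"):
        filtered = filter_present_on_all(matrix)
        write_expression_matrix(filtered, out_dir / "filtered.tsv")

    with _Stage("normalize"):
        ref = build_reference_distribution(
            filtered,
            smooth=params["smooth"],
            window=params["smooth_window"],
            order=params["sg_order"],
        )
        normalized = quantile_normalize(filtered, ref)
        write_expression_matrix(normalized, out_dir / "normalized.tsv")
        if params["plots"]:
            from .plots import plot_normalization_boxplots

            plot_normalization_boxplots(filtered, normalized, out_dir / "qc_boxplots.png")

    with _Stage("differential"):
        results = pairwise_comparisons(
            normalized,
            group_order=tuple(group_order),
            threshold=params["threshold"],
            iterations=params["jackknife_iterations"],
            seed=seed,
        )
        for key, res in results.items():
            res.to_frame().to_csv(out_dir / f"contrast_{key}.tsv", sep="\t")

    with _Stage("venn"):
        contrast_keys = list(results)
        selected_lists = [results[k].selected for k in contrast_keys]
        venn = {
            "lists": dict(zip(("A", "B", "C"), contrast_keys)),
            "regions": venn_partition(*selected_lists),
        }
        with open(out_dir / "venn.json", "w") as fh:
            json.dump(_jsonable(venn), fh, sort_keys=True, indent=2)

    with _Stage("enrichment"):
        if params["universe"] == "detected":
            universe_probes = set(filtered.probe_ids)
        else:
            universe_probes = set(matrix.probe_ids)
        tables = {}
        for key, res in results.items():
            tables[key] = enrich(
                set(res.selected), universe_probes, pmap, gsc, q_cutoff=params["q_cutoff"]
            )
            tables[key].to_csv(out_dir / f"enrichment_{key}.tsv", sep="\t", index=False)

    with _Stage("compare"):
        comparison = compare_enrichment_across_contrasts(tables, top_k=params["top_k"])
        comparison.to_csv(out_dir / "enrichment_comparison.tsv", sep="\t")
        if params["plots"]:
            from .plots import plot_enrichment_comparison

            plot_enrichment_comparison(comparison, out_dir / "enrichment_comparison.png")

    recovery = None
    if truth is not None and truth.planted_pathways:
        with _Stage("recovery"):
            recovery = sim.evaluate_recovery(tables, truth, q_cutoff=params["q_cutoff"])

    report = PipelineReport(
        counts={
            "probes_input": matrix.n_probes,
            "present_on_all": filtered.n_probes,
            "selected": {key: len(res.selected) for key, res in results.items()},
        },
        venn=venn,
        enrichment={
            key: table.head(params["top_k"]).to_dict(orient="records")
            for key, table in tables.items()
        },
        parameters={**params, "group_order": list(group_order)},
        seed=seed,
        recovery=recovery,
    )
    report.to_json(out_dir / "report.json")
    return report
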