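"""Run orchestration: schema-checked configs, staged execution, manifests.

A run config is a YAML/dict document::

    seed: 7
    out_dir: runs/demo
    stages:
      - stage: simulate_screen
        params: {n_genes: 200, guides_per_gene: 4}
      - stage: screen_score
        params: {alpha: 0.25, n_perm: 500}

Stages execute in the listed order, share an in-memory context (later stages
consume earlier outputs or read the files named in their params), and each
stage receives a child seed derived from the global seed and its position —
``SeedSequence(global_seed, spawn_key=(stage_index,))`` — so a stage is
reproducible in isolation.  Every run writes ``manifest.json`` recording
parameters, seeds, package version, and sha256 checksums of the outputs;
identical config + inputs reproduce identical outputs for the deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import meta_analysis, screen_scoring, silac_turnover, synthetic_data
from . import transcript_filters
from .synthetic_data import write_table

log = logging.getLogger("levelscan")

__all__ = ["RunConfig", "run", "read_tsv", "load_config"]


def read_tsv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a TSV with fault locations surfaced (file, line, field count)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # keep the C-parser's line/column info
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------

# stage -> {param: (type(s), validator or None)}
_positive = ("must be > 0", lambda v: v > 0)
_nonneg = ("must be >= 0", lambda v: v >= 0)
_fraction = ("must be in [0, 1]", lambda v: 0.0 <= v <= 1.0)

_SCHEMAS: dict[str, dict[str, tuple[tuple[type, ...], tuple[str, Callable] | None]]] = {
    "simulate_screen": {
        "n_genes": ((int,), _positive),
        "guides_per_gene": ((int,), _positive),
        "n_control_guides": ((int,), _nonneg),
        "frac_true_hits": ((int, float), _fraction),
        "effect_size_sd_units": ((int, float), None),
        "cells_per_guide": ((int, float), _positive),
        "sort_fraction": ((int, float), ("must be in (0, 0.5]", lambda v: 0 < v <= 0.5)),
        "reads_per_bin": ((int,), _positive),
        "recombination_rate": ((int, float), ("must be in [0, 1)", lambda v: 0 <= v < 1)),
    },
    "screen_score": {
        "calls": ((str,), None),
        "library": ((str,), None),
        "high": ((list, str), None),
        "low": ((list, str), None),
        "min_count": ((int, float), _nonneg),
        "alpha": ((int, float), ("must be in (0, 1]", lambda v: 0 < v <= 1)),
        "n_perm": ((int,), ("must be >= 100", lambda v: v >= 100)),
        "nt_pseudogene_size": ((int,), _positive),
    },
    "simulate_meta": {
        "n_screens": ((int,), _positive),
        "n_genes": ((int,), _positive),
        "shared_hit_count": ((int,), _nonneg),
        "screen_specific_hit_count": ((int,), _nonneg),
        "shared_effect": ((int, float), None),
        "noise_se": ((int, float), _positive),
    },
    "meta_run": {
        "screens": ((list,), None),
        "q_threshold": ((int, float), ("must be in (0, 1)", lambda v: 0 < v < 1)),
        "lfc_threshold": ((int, float), _nonneg),
        "effect_filtered": ((list,), None),
        "standardize": ((bool,), None),
    },
    "simulate_silac": {
        "n_proteins": ((int,), _positive),
        "label_time_days": ((int, float), _positive),
        "ratio_noise_cv": ((int, float), _nonneg),
        "contaminant_fraction": ((int, float), _fraction),
        "extreme_ratio_fraction": ((int, float), _fraction),
    },
    "silac_halflife": {
        "peptides": ((str,), None),
        "min_intensity": ((int, float), _nonneg),
    },
    "silac_contrast": {
        "turnover": ((str,), None),
        "group_a": ((str,), None),
        "group_b": ((str,), None),
        "lfc_cut": ((int, float), _nonneg),
        "p_cut": ((int, float), ("must be in (0, 1)", lambda v: 0 < v < 1)),
    },
    "simulate_counts": {
        "n_genes": ((int,), _positive),
        "de_fraction": ((int, float), _fraction),
        "n_control": ((int,), ("must be >= 2", lambda v: v >= 2)),
        "n_knockdown": ((int,), ("must be >= 2", lambda v: v >= 2)),
    },
    "rnaseq_filter": {
        "counts": ((str,), None),
        "samples": ((str,), None),
        "group_a": ((str,), None),
        "group_b": ((str,), None),
        "pedestal": ((int, float), _positive),
        "loess_iterations": ((int,), _positive),
        "lfc_cut": ((int, float), _nonneg),
        "p_cut": ((int, float), ("must be in (0, 1)", lambda v: 0 < v < 1)),
    },
    "simulate_psi": {
        "n_junctions": ((int,), _positive),
        "n_samples_per_group": ((int,), ("must be >= 2", lambda v: v >= 2)),
        "cryptic_fraction": ((int, float), _fraction),
    },
    "splice_classify": {
        "psi": ((str,), None),
        "samples": ((str,), None),
        "dpsi_cut": ((int, float), _fraction),
        "detection_floor": ((int, float), _fraction),
    },
    "polya_classify": {
        "events": ((str,), None),
        "cfc_cut": ((int, float), _nonneg),
        "fdr_cut": ((int, float), ("must be in (0, 1)", lambda v: 0 < v < 1)),
    },
}


@dataclass
class RunConfig:
    """Validated run configuration: global seed, output dir, ordered stages."""

    seed: int
    out_dir: Path
    stages: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RunConfig":
        known_top = {"seed", "out_dir", "stages"}
        unknown = set(doc) - known_top
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in doc:
            raise ValueError("config requires out_dir")
        seed = doc.get("seed", 0)
        if not isinstance(seed, int):
            raise ValueError("seed must be an integer")
        stages = doc.get("stages", [])
        if not isinstance(stages, list):
            raise ValueError("stages must be a list")
        validated = []
        for i, entry in enumerate(stages):
            if not isinstance(entry, Mapping) or "stage" not in entry:
                raise ValueError(f"stage entry {i} must be a mapping with 'stage'")
            extra = set(entry) - {"stage", "params"}
            if extra:
                raise ValueError(f"stage entry {i}: unknown key(s) {sorted(extra)}")
            name = entry["stage"]
            if name not in _SCHEMAS:
                raise ValueError(
                    f"unknown stage {name!r}; known: {sorted(_SCHEMAS)}"
                )
            params = dict(entry.get("params") or {})
            schema = _SCHEMAS[name]
            bad = set(params) - set(schema)
            if bad:
                raise ValueError(f"stage {name!r}: unknown param(s) {sorted(bad)}")
            for key, value in params.items():
                types, check = schema[key]
                if not isinstance(value, types) or isinstance(value, bool) != (
                    bool in types
                ):
                    raise ValueError(
                        f"stage {name!r} param {key!r}: expected "
                        f"{'/'.join(t.__name__ for t in types)}, got "
                        f"{type(value).__name__}"
                    )
                if check is not None and isinstance(value, (int, float)):
                    msg, fn = check
                    if not fn(value):
                        raise ValueError(f"stage {name!r} param {key!r} {msg}")
            validated.append({"stage": name, "params": params})
        return cls(seed=seed, out_dir=Path(doc["out_dir"]), stages=validated)


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(doc)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Documented child-seed derivation, stable across runs and platforms."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write a manifest.

    Returns the manifest dict.  Validation errors (schema, missing inputs)
    are raised before any computation starts.
    """
    # pre-flight: every file-typed param must exist before anything runs
    for entry in config.stages:
        for key in ("calls", "library", "counts", "samples", "peptides",
                    "turnover", "psi", "events", "screens"):
            val = entry["params"].get(key)
            paths = val if isinstance(val, list) else [val] if val else []
            for p in paths:
                candidate = Path(p)
                if not candidate.exists() and not (config.out_dir / p).exists():
                    raise FileNotFoundError(
                        f"stage {entry['stage']!r}: input {p!r} not found"
                    )

    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    ctx: dict[str, Any] = {}
    outputs: dict[str, str] = {}
    manifest_stages = []
    for i, entry in enumerate(config.stages):
        name, params = entry["stage"], entry["params"]
        seed = stage_seed(config.seed, i)
        log.info("stage=%s index=%d seed=%d", name, i, seed)
        written = _STAGE_RUNNERS[name](params, ctx, out_dir, seed)
        for label, path in written.items():
            outputs[f"{name}.{label}"] = str(path)
        manifest_stages.append({"stage": name, "params": params, "seed": seed})

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": manifest_stages,
        "outputs": {
            k: {"path": p, "sha256": _sha256(Path(p))} for k, p in outputs.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _resolve(path: str, out_dir: Path) -> Path:
    p = Path(path)
    return p if p.exists() else out_dir / path


def _run_simulate_screen(params, ctx, out_dir, seed):
    cfg = synthetic_data.ScreenSimConfig(seed=seed, **params)
    calls, counts, truth, library = synthetic_data.simulate_sorting_screen(cfg)
    ctx.update(calls=calls, counts=counts, screen_truth=truth, library=library)
    return synthetic_data.write_screen_dataset(out_dir, calls, counts, truth, library)


def _run_screen_score(params, ctx, out_dir, seed):
    params = dict(params)
    calls = (
        read_tsv(_resolve(params.pop("calls"), out_dir))
        if "calls" in params
        else ctx["calls"]
    )
    library = (
        read_tsv(_resolve(params.pop("library"), out_dir))
        if "library" in params
        else ctx["library"]
    )
    high = params.pop("high", ["high"])
    low = params.pop("low", ["low"])
    if isinstance(high, str):
        high = high.split(",")
    if isinstance(low, str):
        low = low.split(",")
    result = screen_scoring.score_screen(
        calls, library, high=high, low=low, seed=seed, **params
    )
    ctx["gene_scores"] = result["gene_scores"]
    ctx["screen_summary"] = result["summary"]
    return {
        "guide_stats": write_table(result["guide_stats"], out_dir / "guide_stats.tsv"),
        "gene_scores": write_table(result["gene_scores"], out_dir / "gene_scores.tsv"),
        "summary": write_table(result["summary"], out_dir / "screen_summary.tsv"),
        "rank_plot": write_table(
            screen_scoring.rank_plot_table(result["gene_scores"]),
            out_dir / "rank_plot.tsv",
        ),
    }


def _run_simulate_meta(params, ctx, out_dir, seed):
    cfg = synthetic_data.MetaSimConfig(seed=seed, **params)
    summaries, truth = synthetic_data.simulate_screen_summaries(cfg)
    ctx["summaries"] = summaries
    written = synthetic_data.write_summaries(out_dir, summaries)
    written["truth"] = write_table(truth, out_dir / "meta_truth.tsv")
    return written


def _run_meta_run(params, ctx, out_dir, seed):
    params = dict(params)
    if "screens" in params:
        summaries = {
            Path(p).stem: read_tsv(_resolve(p, out_dir)) for p in params.pop("screens")
        }
    else:
        summaries = ctx["summaries"]
    q = params.pop("q_threshold", 0.05)
    lfc = params.pop("lfc_threshold", 1.0)
    eff = params.pop("effect_filtered", [])
    results = meta_analysis.meta_all_combinations(summaries, **params)
    written = {}
    for subset, table in results.items():
        flagged = meta_analysis.classify_novelty(
            table, {s: summaries[s] for s in subset}, q_threshold=q,
            lfc_threshold=lfc, effect_filtered=[s for s in eff if s in subset],
        )
        label = "meta_" + "_".join(subset)
        written[label] = write_table(flagged, out_dir / f"{label}.tsv")
    ctx["meta_results"] = results
    return written


def _run_simulate_silac(params, ctx, out_dir, seed):
    cfg = synthetic_data.TurnoverSimConfig(seed=seed, **params)
    peptides, truth = synthetic_data.simulate_silac_peptides(cfg)
    ctx["peptides"] = peptides
    return {
        "peptides": write_table(peptides, out_dir / "silac_peptides.tsv"),
        "truth": write_table(truth, out_dir / "silac_truth.tsv"),
    }


def _run_silac_halflife(params, ctx, out_dir, seed):
    params = dict(params)
    peptides = (
        read_tsv(_resolve(params.pop("peptides"), out_dir))
        if "peptides" in params
        else ctx["peptides"]
    )
    kept, tally = silac_turnover.filter_peptides(peptides, **params)
    turnover = silac_turnover.protein_half_life(
        silac_turnover.peptide_table_half_lives(kept)
    )
    ctx["turnover"] = turnover
    (out_dir / "silac_rejections.json").write_text(json.dumps(tally, indent=2))
    return {
        "turnover": write_table(turnover, out_dir / "protein_turnover.tsv"),
        "rejections": out_dir / "silac_rejections.json",
    }


def _run_silac_contrast(params, ctx, out_dir, seed):
    params = dict(params)
    turnover = (
        read_tsv(_resolve(params.pop("turnover"), out_dir))
        if "turnover" in params
        else ctx["turnover"]
    )
    contrast = silac_turnover.contrast_half_life(
        turnover, params.pop("group_a"), params.pop("group_b"), **params
    )
    return {"contrast": write_table(contrast, out_dir / "halflife_contrast.tsv")}


def _run_simulate_counts(params, ctx, out_dir, seed):
    params = dict(params)
    groups = {"NT": params.pop("n_control", 4), "KD": params.pop("n_knockdown", 3)}
    counts, sample_groups, truth = synthetic_data.simulate_expression_counts(
        params.pop("n_genes", 2000), groups, params.pop("de_fraction", 0.05), seed
    )
    ctx.update(counts=counts, sample_groups=sample_groups)
    return {
        "counts": write_table(counts, out_dir / "expression_counts.tsv", index=True),
        "samples": write_table(
            sample_groups.rename_axis("sample").reset_index(),
            out_dir / "sample_sheet.tsv",
        ),
        "truth": write_table(truth, out_dir / "expression_truth.tsv"),
    }


def _run_rnaseq_filter(params, ctx, out_dir, seed):
    params = dict(params)
    if "counts" in params:
        counts = read_tsv(_resolve(params.pop("counts"), out_dir), index_col=0)
        sheet = read_tsv(_resolve(params.pop("samples"), out_dir))
        sample_groups = sheet.set_index("sample")["group"]
    else:
        counts, sample_groups = ctx["counts"], ctx["sample_groups"]
    group_a = params.pop("group_a", "NT")
    group_b = params.pop("group_b", "KD")
    pedestal = params.pop("pedestal", 2.0)
    iterations = params.pop("loess_iterations", 3)
    logged = transcript_filters.cpm_pedestal_log2(counts, pedestal=pedestal)
    normalized = transcript_filters.cyclic_loess_normalize(logged, iterations=iterations)
    kept, thresholds, report = transcript_filters.noise_filter(
        normalized, sample_groups, pedestal=pedestal
    )
    de = transcript_filters.differential_expression(
        kept, sample_groups, group_a, group_b, **params
    )
    qc = transcript_filters.outlier_report(normalized)
    (out_dir / "noise_thresholds.json").write_text(json.dumps(thresholds, indent=2))
    return {
        "kept_matrix": write_table(kept, out_dir / "kept_genes.tsv", index=True),
        "de": write_table(de, out_dir / "differential_expression.tsv"),
        "noise_report": write_table(
            report.reset_index(), out_dir / "noise_report.tsv"
        ),
        "qc": write_table(qc.reset_index(), out_dir / "outlier_report.tsv"),
        "thresholds": out_dir / "noise_thresholds.json",
    }


def _run_simulate_psi(params, ctx, out_dir, seed):
    psi, groups, truth = synthetic_data.simulate_junction_psi(
        params.get("n_junctions", 1000),
        params.get("n_samples_per_group", 4),
        params.get("cryptic_fraction", 0.05),
        seed,
    )
    ctx.update(psi=psi, psi_groups=groups)
    return {
        "psi": write_table(psi, out_dir / "junction_psi.tsv", index=True),
        "samples": write_table(
            groups.rename_axis("sample").reset_index(), out_dir / "psi_samples.tsv"
        ),
        "truth": write_table(truth, out_dir / "psi_truth.tsv"),
    }


def _run_splice_classify(params, ctx, out_dir, seed):
    params = dict(params)
    if "psi" in params:
        psi = read_tsv(_resolve(params.pop("psi"), out_dir), index_col=0)
        sheet = read_tsv(_resolve(params.pop("samples"), out_dir))
        groups = sheet.set_index("sample")["group"]
    else:
        psi, groups = ctx["psi"], ctx["psi_groups"]
    classified = transcript_filters.classify_junctions(psi, groups, **params)
    return {"junctions": write_table(classified, out_dir / "junction_classes.tsv")}


def _run_polya_classify(params, ctx, out_dir, seed):
    params = dict(params)
    events = read_tsv(_resolve(params.pop("events"), out_dir))
    classified = transcript_filters.filter_polya_events(events, **params)
    return {"polya": write_table(classified, out_dir / "polya_classes.tsv")}


_STAGE_RUNNERS: dict[str, Callable] = {
    "simulate_screen": _run_simulate_screen,
    "screen_score": _run_screen_score,
    "simulate_meta": _run_simulate_meta,
    "meta_run": _run_meta_run,
    "simulate_silac": _run_simulate_silac,
    "silac_halflife": _run_silac_halflife,
    "silac_contrast": _run_silac_contrast,
    "simulate_counts": _run_simulate_counts,
    "rnaseq_filter": _run_rnaseq_filter,
    "simulate_psi": _run_simulate_psi,
    "splice_classify": _run_splice_classify,
    "polya_classify": _run_polya_classify,
}
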