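"""Pipeline orchestration: split → cluster → explain → evaluate → visualize.

Each stage consumes only the on-disk artifacts of the stages before it, so
any stage can be rerun from a populated output directory (anchor search
dominates runtime, which makes checkpointing essential).  All randomness
derives from the single configured seed; two runs with the same
configuration and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import importlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .anchors import AnchorParams, AnchorRule, Predicate, find_anchor, read_rules, \
    write_rules
from .clustering import Clustering, read_clusterings, run_clustering, \
    sweep_clustering, write_clusterings
from .config import PipelineConfig
from .distances import pairwise_distances
from .evaluation import cofulfillment_matrix, completeness_histogram, full_metrics
from .models import BINDING, NON_BINDING, ConstantModel, PredictionSplit, \
    predict_labels, split_by_prediction
from .regions import region_rule_distribution, render_rule_motif, \
    split_frequency_matrix
from .samples import ContractViolation, SequenceSample, read_fasta, \
    read_region_map, read_sample_table, write_region_map, write_sample_table
from .synthetic import Benchmark, PlantedRuleModel, RepertoireConfig, make_benchmark

logger = logging.getLogger(__name__)

SPLITS = (NON_BINDING, BINDING)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending entity."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# config resolution


def _resolve_data(config: PipelineConfig, base: Path
                  ) -> tuple[list[SequenceSample], dict, Benchmark | None]:
    data = config.data
    if data.synthetic is not None:
        s = data.synthetic
        rep = RepertoireConfig(n_samples=s.n_samples, frame_length=s.frame_length,
                               n_seed_sequences=s.n_seed_sequences,
                               mutation_rate=s.mutation_rate, seed=config.seed)
        bench = make_benchmark(config.seed, config=rep, n_rules=s.n_rules,
                               label_noise=s.label_noise)
        return bench.samples, bench.region_map, bench
    if data.table is not None:
        samples = read_sample_table(base / data.table, data.frame_length)
    else:
        samples = read_fasta(base / data.fasta, data.frame_length)
    region_map = {}
    if data.regions is not None:
        region_map = read_region_map(base / data.regions)
        samples = [
            SequenceSample(id=s.id, frame=s.frame, regions=region_map.get(s.id))
            for s in samples
        ]
    return samples, region_map, None


def _resolve_model(config: PipelineConfig, bench: Benchmark | None):
    section = config.model
    if section.kind == "constant":
        return ConstantModel(label=section.constant_label)
    if section.kind == "import":
        module_name, _, attr = section.import_path.partition(":")
        obj = getattr(importlib.import_module(module_name), attr)
        return obj() if callable(obj) and not hasattr(obj, "predict") else obj
    # planted
    if section.rules:
        planted = tuple(
            tuple(Predicate(int(p), str(sym)) for p, sym in rule)
            for rule in section.rules
        )
        return PlantedRuleModel(planted_rules=planted,
                                label_noise=section.label_noise, seed=config.seed)
    if bench is None:
        raise ContractViolation(
            "model kind 'planted' without explicit rules requires synthetic data")
    return bench.model


def _anchor_params(config: PipelineConfig, seed: int) -> AnchorParams:
    a = config.anchors
    return AnchorParams(
        precision_threshold=a.precision_threshold, delta=a.delta, tau=a.tau,
        beam_width=a.beam_width, batch_size=a.batch_size,
        max_predicates=a.max_predicates, max_pulls=a.max_pulls, seed=seed)


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    state = np.random.SeedSequence([base_seed, *key]).generate_state(1)[0]
    return int(state % (2 ** 31))


# ---------------------------------------------------------------------------
# stages


@_stage("split")
def stage_split(config: PipelineConfig, base: Path, out: Path) -> None:
    """Load (or generate) the data, run the model, write the split table."""
    out.mkdir(parents=True, exist_ok=True)
    samples, region_map, bench = _resolve_data(config, base)
    model = _resolve_model(config, bench)
    labels = predict_labels(model, samples)
    split = split_by_prediction(samples, labels)
    write_sample_table(samples, out / "samples.tsv")
    if region_map:
        write_region_map(region_map, out / "regions.tsv")
    split.write(out / "split.tsv")


@_stage("cluster")
def stage_cluster(config: PipelineConfig, base: Path, out: Path) -> None:
    """Cluster each prediction split separately; write the clustering table."""
    samples = read_sample_table(out / "samples.tsv")
    split = PredictionSplit.read(out / "split.tsv")
    by_id = {s.id: s for s in samples}
    section = config.clustering
    clusterings = []
    for split_name in SPLITS:
        ids = split.ids_of(split_name)
        if not ids:
            logger.warning("split %s is empty; skipping clustering", split_name)
            continue
        members = [by_id[i] for i in ids]
        d = pairwise_distances(members, metric=section.metric)
        grid = section.eps_grid if section.algorithm == "optics" else section.k_grid
        if grid:
            clustering = sweep_clustering(
                d, section.algorithm, grid, criterion=section.criterion,
                split=split_name, linkage_method=section.linkage,
                seed=derive_seed(config.seed, 1))
        else:
            kwargs = ({"eps": section.eps, "min_samples": section.min_samples}
                      if section.algorithm == "optics" else {"k": section.k})
            clustering = run_clustering(
                d, section.algorithm, split=split_name,
                linkage_method=section.linkage,
                seed=derive_seed(config.seed, 1), **kwargs)
        clusterings.append(clustering)
    write_clusterings(clusterings, out / "clustering.tsv")
    log = {
        "version": __version__,
        "seed": config.seed,
        "clustering": [
            {"split": c.split, "algorithm": c.algorithm, "params": c.params,
             "criterion_scores": c.criterion_scores}
            for c in clusterings
        ],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


@_stage("explain")
def stage_explain(config: PipelineConfig, base: Path, out: Path) -> None:
    """One anchor rule per cluster medoid; write JSON-lines and text files."""
    samples = read_sample_table(out / "samples.tsv")
    split = PredictionSplit.read(out / "split.tsv")
    clusterings = read_clusterings(out / "clustering.tsv")
    _, _, bench = _resolve_data(config, base)
    model = _resolve_model(config, bench)
    by_id = {s.id: s for s in samples}
    rules: list[AnchorRule] = []
    for si, split_name in enumerate(SPLITS):
        if split_name not in clusterings:
            continue
        clustering = clusterings[split_name]
        pool = [by_id[i] for i in split.ids_of(split_name)]
        for cluster in sorted(clustering.medoids):
            medoid = by_id[clustering.medoids[cluster]]
            params = _anchor_params(
                config, derive_seed(config.seed, 2, si, cluster))
            rules.append(find_anchor(medoid, model, pool, params,
                                     source=(split_name, cluster)))
    write_rules(rules, out / "anchors.jsonl")
    with open(out / "anchors.txt", "w") as fh:
        for rule in rules:
            fh.write(f"# {rule.rule_id} (medoid {rule.source[2]})\n")
            fh.write(rule.to_text() + "\n\n")


@_stage("evaluate")
def stage_evaluate(config: PipelineConfig, base: Path, out: Path) -> None:
    """CL/CS/SP metrics, overlap matrices, completeness, region densities."""
    samples = read_sample_table(out / "samples.tsv")
    split = PredictionSplit.read(out / "split.tsv")
    clusterings = read_clusterings(out / "clustering.tsv")
    rules = read_rules(out / "anchors.jsonl")
    report = full_metrics(rules, samples, split, clusterings,
                          exclusive=config.evaluation.cl_exclusive)
    report.write(out / "metrics.tsv")
    overlap = cofulfillment_matrix(rules, samples)
    overlap.frame("predicates").to_csv(out / "overlap_predicates.tsv", sep="\t")
    overlap.frame("cofulfillment").to_csv(out / "overlap_cofulfillment.tsv", sep="\t")
    completeness_histogram(rules, samples).to_frame().to_csv(
        out / "completeness.tsv", sep="\t", index=False)
    if (out / "regions.tsv").exists():
        region_map = read_region_map(out / "regions.tsv")
        frames = []
        for split_name in SPLITS:
            density = region_rule_distribution(
                rules, region_map, split_name, mode=config.evaluation.region_mode)
            frames.append(density.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(
            out / "region_density.tsv", sep="\t", index=False, float_format="%.6f")


@_stage("visualize")
def stage_visualize(config: PipelineConfig, base: Path, out: Path) -> None:
    """Overlap heatmap, completeness histogram, region densities, motifs."""
    if not config.figures:
        return
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    figures = out / "figures"
    figures.mkdir(exist_ok=True)
    samples = read_sample_table(out / "samples.tsv")
    split = PredictionSplit.read(out / "split.tsv")
    rules = read_rules(out / "anchors.jsonl")
    by_id = {s.id: s for s in samples}

    overlap = cofulfillment_matrix(rules, samples)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    for ax, which, title in ((axes[0], "predicates", "shared predicates"),
                             (axes[1], "cofulfillment", "co-fulfilling samples")):
        mat = overlap.frame(which)
        im = ax.imshow(mat.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(figures / "overlap.png", dpi=150)
    plt.close(fig)

    hist = completeness_histogram(rules, samples)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(list(hist.counts), list(hist.counts.values()), color="#255c99")
    ax.set_xlabel("number of applicable anchors")
    ax.set_ylabel("number of samples")
    fig.tight_layout()
    fig.savefig(figures / "completeness.png", dpi=150)
    plt.close(fig)

    if (out / "region_density.tsv").exists():
        density = pd.read_csv(out / "region_density.tsv", sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(10, 3.5), sharey=True)
        for ax, split_name in zip(axes, (BINDING, NON_BINDING)):
            sub = density[density["split"] == split_name]
            ax.bar(sub["region"], sub["density"], color="#d97f11")
            ax.set_title(f"{split_name} rules")
            ax.tick_params(axis="x", rotation=45)
        axes[0].set_ylabel("predicates per position")
        fig.tight_layout()
        fig.savefig(figures / "region_density.png", dpi=150)
        plt.close(fig)

    region_map = (read_region_map(out / "regions.tsv")
                  if (out / "regions.tsv").exists() else {})
    for split_name in SPLITS:
        split_rules = [r for r in rules if r.source[0] == split_name
                       and r.predicates]
        if not split_rules:
            continue
        members = [by_id[i] for i in split.ids_of(split_name)]
        freq = split_frequency_matrix(members)
        rule = split_rules[0]
        render_rule_motif(rule, region_map, freq,
                          figures / f"motif_{split_name.replace('-', '_')}.png")


STAGES = {
    "split": stage_split,
    "cluster": stage_cluster,
    "explain": stage_explain,
    "evaluate": stage_evaluate,
    "visualize": stage_visualize,
}


def run_pipeline(config: PipelineConfig, base: Path | str = ".") -> Path:
    """Execute all stages in order; returns the output directory."""
    base = Path(base)
    out = (base / config.output_dir if not Path(config.output_dir).is_absolute()
           else Path(config.output_dir))
    for name in ("split", "cluster", "explain", "evaluate", "visualize"):
        logger.info("running stage %s", name)
        STAGES[name](config, base, out)
    return out
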