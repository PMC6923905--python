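"""Pipeline orchestration: graph -> indel repair -> substitution repair -> metrics.

Per-read correction is embarrassingly parallel, so an optional process pool
(fork-based) can spread reads over workers; results are collected in input
order and are identical to a serial run for any worker count.
"""

from __future__ import annotations

import json
import logging
import math
import multiprocessing
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import dbg, evaluate, indel, simulate, subst
from .errors import ParameterError
from .io_formats import (
    ReadRecord,
    deserialize_graph,
    read_sequences,
    serialize_graph,
    write_sequences,
)

logger = logging.getLogger("hybridec")


@dataclass
class PipelineConfig:
    """Every tunable of the correction pipeline, validated up front.

    The config is serialized into reports and metrics for provenance.
    """

    k: int = dbg.DEFAULT_K
    canonical: bool = True
    tau: int = indel.DEFAULT_TAU
    search: str = "widest"
    b: int = indel.DEFAULT_BRANCHING
    max_len_factor: float = indel.DEFAULT_MAX_LEN_FACTOR
    frag_len: int = subst.DEFAULT_FRAG_LEN
    skew_low: float = subst.DEFAULT_SKEW_LOW
    skew_high: float = subst.DEFAULT_SKEW_HIGH
    tau_low: int | None = None  # defaults to tau
    thresh_high: int | None = None  # defaults to max(tau, ceil(spectrum median/4))
    thresh_low: int | None = None  # defaults to tau
    spectrum_stat: str = "instances"  # spectrum median over instances or distinct
    workers: int = 1
    seed: int | None = None
    # file paths (None when a stage is driven in memory)
    short_reads: str | None = None
    long_reads: str | None = None
    graph_path: str | None = None
    out_path: str | None = None
    report_path: str | None = None

    def validate(self) -> "PipelineConfig":
        if self.k < 2:
            raise ParameterError(f"k must be >= 2, got {self.k}")
        if self.tau < 1:
            raise ParameterError(f"tau must be >= 1, got {self.tau}")
        if self.search not in ("widest", "shortest", "greedy"):
            raise ParameterError(f"unknown search strategy {self.search!r}")
        if self.b < 1:
            raise ParameterError(f"branching factor must be >= 1, got {self.b}")
        if self.max_len_factor <= 0:
            raise ParameterError("max_len_factor must be > 0")
        if self.frag_len < self.k:
            raise ParameterError(
                f"frag_len ({self.frag_len}) must be >= k ({self.k})"
            )
        if self.skew_low > self.skew_high:
            raise ParameterError("skew_low must be <= skew_high")
        if self.workers < 1:
            raise ParameterError("workers must be >= 1")
        if self.spectrum_stat not in ("instances", "distinct"):
            raise ParameterError(f"unknown spectrum_stat {self.spectrum_stat!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def resolve_thresholds(
    config: PipelineConfig, graph: dbg.DeBruijnGraph
) -> tuple[int, int, int, float]:
    """(tau_low, thresh_high, thresh_low, graph_median) with defaults filled.

    The voting threshold for high-coverage areas defaults to a quarter of
    the instance-weighted spectrum median: several sampling standard
    deviations below typical genomic depth (so coverage dips never veto the
    true base) yet far above the count of error k-mers, and never below tau.
    The low-coverage threshold defaults to tau itself.
    """
    graph_median = graph.spectrum_median(mode=config.spectrum_stat)
    tau_low = config.tau_low if config.tau_low is not None else config.tau
    thresh_high = (
        config.thresh_high
        if config.thresh_high is not None
        else max(config.tau, math.ceil(graph_median / 4))
    )
    thresh_low = config.thresh_low if config.thresh_low is not None else config.tau
    return tau_low, thresh_high, thresh_low, graph_median


# -- worker-pool plumbing ----------------------------------------------------

_POOL_STATE: dict = {}


def _init_pool(graph, kwargs, stage):
    _POOL_STATE["graph"] = graph
    _POOL_STATE["kwargs"] = kwargs
    _POOL_STATE["stage"] = stage


def _pool_correct(read: ReadRecord):
    graph = _POOL_STATE["graph"]
    kwargs = _POOL_STATE["kwargs"]
    if _POOL_STATE["stage"] == "indel":
        return indel.correct_read_indels(read, graph, **kwargs)
    return subst.correct_read_substitutions(read, graph, **kwargs)


def _map_reads(stage: str, reads: Sequence[ReadRecord], graph, kwargs, workers: int):
    if workers <= 1:
        fn = (
            indel.correct_read_indels
            if stage == "indel"
            else subst.correct_read_substitutions
        )
        return [fn(read, graph, **kwargs) for read in reads]
    ctx = multiprocessing.get_context("fork")
    chunk = max(1, len(reads) // (workers * 4))
    with ctx.Pool(
        workers, initializer=_init_pool, initargs=(graph, kwargs, stage)
    ) as pool:
        return list(pool.imap(_pool_correct, reads, chunksize=chunk))


def correct_indels(
    reads: Sequence[ReadRecord],
    graph: dbg.DeBruijnGraph,
    config: PipelineConfig,
) -> tuple[list[ReadRecord], list[indel.IndelCorrectionReport]]:
    """Indel-correct a batch of reads (order-preserving, optionally parallel)."""
    kwargs = dict(
        tau=config.tau,
        search=config.search,
        max_len_factor=config.max_len_factor,
        b=config.b,
    )
    results = _map_reads("indel", reads, graph, kwargs, config.workers)
    out = [
        ReadRecord(id=read.id, sequence=seq)
        for read, (seq, _) in zip(reads, results)
    ]
    return out, [rep for _, rep in results]


def correct_substitutions(
    reads: Sequence[ReadRecord],
    graph: dbg.DeBruijnGraph,
    config: PipelineConfig,
) -> tuple[list[ReadRecord], list[subst.SubstCorrectionReport]]:
    """Substitution-correct a batch of reads (order-preserving)."""
    tau_low, thresh_high, thresh_low, graph_median = resolve_thresholds(config, graph)
    kwargs = dict(
        frag_len=config.frag_len,
        skew_low=config.skew_low,
        skew_high=config.skew_high,
        tau_low=tau_low,
        thresh_high=thresh_high,
        thresh_low=thresh_low,
        graph_median=graph_median,
    )
    results = _map_reads("subst", reads, graph, kwargs, config.workers)
    out = [
        ReadRecord(id=read.id, sequence=seq)
        for read, (seq, _) in zip(reads, results)
    ]
    return out, [rep for _, rep in results]


def correct_reads(
    reads: Sequence[ReadRecord],
    graph: dbg.DeBruijnGraph,
    config: PipelineConfig,
):
    """Full two-phase correction: indel repair, then substitution repair."""
    indel_out, indel_reports = correct_indels(reads, graph, config)
    final_out, subst_reports = correct_substitutions(indel_out, graph, config)
    return final_out, indel_out, indel_reports, subst_reports


def evaluate_reads(
    original: Sequence[ReadRecord],
    corrected: Sequence[ReadRecord],
    ref: str,
    logs: dict[str, simulate.ErrorLog],
    min_identity: float = 0.7,
) -> dict:
    """Aggregate gain / identity / N50 / %aligned over a corrected read set."""
    tp = fp = fn = 0
    ident_before = []
    ident_after = []
    for orig, corr in zip(original, corrected):
        log = logs[orig.id]
        interval = ref[log.start : log.end]
        e_m = evaluate.error_set_from_truth(log)
        e_r = evaluate.error_set_from_alignment(
            corr.sequence, interval, ref_offset=log.start
        )
        g = evaluate.compute_gain(e_m, e_r)
        tp += g.TP
        fp += g.FP
        fn += g.FN
        ident_before.append(evaluate.align_identity(interval, orig.sequence))
        ident_after.append(evaluate.align_identity(interval, corr.sequence))
    gain = (tp - fp) / (tp + fn) if tp + fn > 0 else (1.0 if fp == 0 else -1.0)
    pct_reads, pct_bases = evaluate.aligned_fraction(corrected, ref, logs)
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "gain": gain,
        "mean_identity_before": sum(ident_before) / len(ident_before),
        "mean_identity_after": sum(ident_after) / len(ident_after),
        "n50_before": evaluate.n50([len(r) for r in original]),
        "n50_after": evaluate.n50([len(r) for r in corrected]),
        "pct_aligned_reads": pct_reads,
        "pct_aligned_bases": pct_bases,
    }


def write_indel_report(reports, path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"#config {json.dumps(config.to_dict())}\n")
        fh.write("#read_id\tn_weak\tn_replaced\tn_unchanged\toutcomes\n")
        for rep in reports:
            outcomes = ";".join(
                f"{o.start}-{o.end}:{o.outcome}" for o in rep.outcomes
            )
            fh.write(
                f"{rep.read_id}\t{rep.n_weak_regions}\t{rep.n_replaced}\t"
                f"{rep.n_unchanged}\t{outcomes}\n"
            )


def write_subst_report(reports, path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"#config {json.dumps(config.to_dict())}\n")
        fh.write(
            "#read_id\tn_fragments\tn_error_fragments\tn_flagged\tn_corrected\n"
        )
        for rep in reports:
            fh.write(
                f"{rep.read_id}\t{rep.n_fragments}\t{rep.n_error_fragments}\t"
                f"{rep.n_positions_flagged}\t{rep.n_positions_corrected}\n"
            )


def run_pipeline(
    config: PipelineConfig,
    *,
    ref_path: str | None = None,
    truth_path: str | None = None,
    metrics_path: str | None = None,
) -> dict:
    """File-driven end-to-end run: build/load graph, correct, optionally score.

    Returns a summary dict (also written to ``metrics_path`` when given).
    """
    config.validate()
    if config.long_reads is None or config.out_path is None:
        raise ParameterError("long_reads and out_path are required")

    if config.graph_path and Path(config.graph_path).exists() and not config.short_reads:
        logger.info("loading graph from %s", config.graph_path)
        graph = deserialize_graph(config.graph_path)
    else:
        if not config.short_reads:
            raise ParameterError("either short_reads or an existing graph_path is required")
        logger.info("building graph from %s (k=%d)", config.short_reads, config.k)
        graph = dbg.build_graph(
            read_sequences(config.short_reads), k=config.k, canonical=config.canonical
        )
        if config.graph_path:
            serialize_graph(graph, config.graph_path)
    logger.info("graph: %d vertices, %d instances", len(graph), graph.total_instances)

    reads = list(read_sequences(config.long_reads))
    final, indel_out, indel_reports, subst_reports = correct_reads(
        reads, graph, config
    )
    write_sequences(final, config.out_path, format="fasta")
    if config.report_path:
        base = Path(config.report_path)
        write_indel_report(indel_reports, base.with_suffix(".indel.tsv"), config)
        write_subst_report(subst_reports, base.with_suffix(".subst.tsv"), config)

    summary: dict = {
        "config": config.to_dict(),
        "n_reads": len(reads),
        "n_weak_regions": sum(r.n_weak_regions for r in indel_reports),
        "n_replaced": sum(r.n_replaced for r in indel_reports),
        "n_subst_corrected": sum(r.n_positions_corrected for r in subst_reports),
    }
    if ref_path and truth_path:
        ref = next(read_sequences(ref_path)).sequence
        logs = simulate.read_truth(truth_path)
        summary["metrics"] = evaluate_reads(reads, final, ref, logs)
    if metrics_path:
        with open(metrics_path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
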