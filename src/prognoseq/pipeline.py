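"""End-to-end orchestration: synthesize -> normalize -> screen -> discover ->
network -> report, with structured logging and a run manifest.

One YAML config (one seed) drives every stochastic stage; re-running with the
same config reproduces the summary JSON byte for byte.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from . import normalization as norm
from . import survival_screen as ss
from . import intergenic_discovery as igd
from . import coexpression_network as coex
from .synthetic_data import (
    CohortConfig,
    make_synthetic_genome,
    simulate_cohort,
    simulate_reads,
)

log = logging.getLogger("prognoseq")

ABUNDANCE_BIN_EDGES = (10.0, 100.0, 1000.0)
ABUNDANCE_BIN_LABELS = ("<10", "10-99", "100-999", ">=1000")


@dataclass
class RunConfig:
    """Paths, thresholds, stage toggles and the single run seed."""

    outdir: str = "prognoseq_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    fdr: float = 0.10
    storey_lambda: float = 0.5
    r_threshold: float = 0.6
    max_count_threshold: int = 5
    min_avg_count: float = 5.0
    min_length: int = 100
    min_depth: float = 0.075
    merge_candidates: tuple[int, ...] = (0, 10, 20, 30, 50)
    post_fdr_gap: int = 1000
    depth_scale: float = 8.0
    n_read_patients: int = 8
    stages: dict = field(
        default_factory=lambda: {
            "synth": True,
            "normalize": True,
            "screen": True,
            "discover": True,
            "network": True,
            "report": True,
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1 or not 0 < self.storey_lambda < 1:
            raise ValueError("fdr and storey_lambda must lie in (0, 1)")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in [-1, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "merge_candidates" in raw:
            raw["merge_candidates"] = tuple(int(c) for c in raw["merge_candidates"])
        return cls(**raw)


def abundance_bin_report(
    raw: iof.CountMatrix, qvalues: pd.Series, fdr: float = 0.10
) -> pd.DataFrame:
    """Tabulate, per median-raw-count bin, how many features were screened and
    how many were identified (q < fdr), with the percent to one decimal.

    Bins are fixed at <10, 10-99, 100-999, >=1000 on each feature's median
    raw count across patients; a Total row closes the table.
    """
    medians = raw.values.median(axis=1)
    common = medians.index.intersection(qvalues.index)
    medians = medians.loc[common]
    q = qvalues.loc[common]
    edges = (-np.inf,) + ABUNDANCE_BIN_EDGES + (np.inf,)
    rows = []
    for lo, hi, lab in zip(edges[:-1], edges[1:], ABUNDANCE_BIN_LABELS):
        mask = (medians >= lo) & (medians < hi)
        n = int(mask.sum())
        n_id = int((q[mask] < fdr).sum())
        pct = round(100.0 * n_id / n, 1) if n else 0.0
        rows.append({"bin": lab, "n_features": n, "n_identified": n_id, "percent": pct})
    n_tot = sum(r["n_features"] for r in rows)
    id_tot = sum(r["n_identified"] for r in rows)
    rows.append(
        {
            "bin": "Total",
            "n_features": n_tot,
            "n_identified": id_tot,
            "percent": round(100.0 * id_tot / n_tot, 1) if n_tot else 0.0,
        }
    )
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = _time.perf_counter()
            log.info("stage %s: start", name)
            out = fn(*args, **kwargs)
            log.info("stage %s: done in %.2fs", name, _time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage, writing all outputs under ``config.outdir``.

    Returns the JSON summary (also written to summary.json): feature counts
    at each filter stage, pi0, identifications at the FDR threshold, the
    abundance-bin table, and network component sizes. A manifest lists every
    file written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: list[str] = []
    summary: dict = {"seed": config.seed}

    def write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest.append(name)
        return path

    try:
        stages = config.stages
        cohort_cfg = CohortConfig(**{**config.cohort, "seed": config.seed})

        counts = survival = truth = None
        if stages.get("synth", True):
            counts, survival, truth = _synth(cohort_cfg, write)
            summary["n_patients"] = counts.n_samples
            summary["n_features_simulated"] = counts.n_features
            summary["n_events"] = int(sum(r.event for r in survival))

        normalized = None
        if stages.get("normalize", True) and counts is not None:
            normalized, retained, n_removed = _normalize(counts, config, write)
            summary["n_features_retained"] = int(len(retained))
            summary["n_features_removed_max_count"] = int(n_removed)

        results = None
        if stages.get("screen", True) and normalized is not None:
            results, pi0, excluded = _screen(normalized, survival, config, write)
            summary["pi0"] = round(pi0, 4)
            summary["n_screened"] = int(results.shape[0])
            summary["n_excluded_constant"] = len(excluded)
            summary["n_identified"] = int((results["q"] < config.fdr).sum())

        if stages.get("discover", True):
            summary["intergenic"] = _discover(config, write)

        if stages.get("network", True) and results is not None and normalized is not None:
            hits = results.index[results["q"] < config.fdr].tolist()
            summary["network"] = _network(normalized, hits, config, write)

        if stages.get("report", True) and counts is not None and results is not None:
            table = abundance_bin_report(counts, results["q"], fdr=config.fdr)
            write("abundance_bins.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
            summary["abundance_bins"] = table.to_dict(orient="records")

        write("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)))
        write("manifest.txt", lambda p: p.write_text("\n".join(manifest) + "\n"))
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary


@_stage("synth")
def _synth(cohort_cfg: CohortConfig, write):
    counts, survival, truth = simulate_cohort(cohort_cfg)
    log.info("cohort: %d features x %d patients", counts.n_features, counts.n_samples)
    write("counts.tsv", lambda p: iof.write_count_matrix(counts, p))
    write("survival.csv", lambda p: iof.write_survival(survival, p))
    write("truth.tsv", lambda p: truth.to_csv(p, sep="\t"))
    return counts, survival, truth


@_stage("normalize")
def _normalize(counts, config: RunConfig, write):
    retained, n_removed = norm.max_count_filter(counts, threshold=config.max_count_threshold)
    filtered = iof.CountMatrix(counts.values.loc[retained], counts.feature_class)
    logged = norm.log2_transform(filtered)
    normalized = norm.third_quartile_normalize(logged)
    log.info("normalize: retained %d features (removed %d)", len(retained), n_removed)
    write("normalized.tsv", lambda p: normalized.values.to_csv(p, sep="\t", index_label="feature_id"))
    _, rle_summary = norm.rle_diagnostic(normalized)
    write("rle_summary.tsv", lambda p: rle_summary.to_csv(p, sep="\t", index_label="sample_id"))
    return normalized, retained, n_removed


@_stage("screen")
def _screen(normalized, survival, config: RunConfig, write):
    time_arr, event_arr = iof.align_survival(survival, list(normalized.values.columns))
    results, pi0, excluded = ss.screen(
        normalized.values, time_arr, event_arr, fdr=config.fdr, lam=config.storey_lambda
    )
    log.info("screen: %d features, pi0=%.3f, %d identified at q<%.2f",
             results.shape[0], pi0, int((results["q"] < config.fdr).sum()), config.fdr)
    write("screen.tsv", lambda p: results.to_csv(p, sep="\t"))
    return results, pi0, excluded


@_stage("discover")
def _discover(config: RunConfig, write) -> dict:
    genome = make_synthetic_genome(config.seed, n_patients=config.n_read_patients)
    reads = simulate_reads(genome, config.n_read_patients, config.depth_scale, config.seed + 1)
    islands = igd.build_islands(reads)
    cutoff = igd.estimate_merge_cutoff(islands, genome.genes, config.merge_candidates)
    rois = igd.merge_islands(islands, cutoff, n_patients=config.n_read_patients)
    retained = igd.filter_rois(
        rois,
        min_avg_count=config.min_avg_count,
        min_length=config.min_length,
        min_depth=config.min_depth,
    )
    intergenic = igd.classify_intergenic(retained, genome.genes)
    log.info(
        "discover: %d reads -> %d islands -> %d ROIs (cutoff %d) -> %d retained -> %d intergenic",
        len(reads), len(islands), len(rois), cutoff, len(retained), len(intergenic),
    )
    write("refflat.txt", lambda p: iof.write_refflat(genome.genes, p))
    write("reads.bed", lambda p: iof.write_bed(reads, p))
    write(
        "intergenic_rois.bed",
        lambda p: iof.write_bed(
            [iof.GenomicInterval(r.chrom, r.start, r.end, r.pooled_count, "roi") for r in intergenic],
            p,
        ),
    )
    return {
        "n_reads": len(reads),
        "n_islands": len(islands),
        "merge_cutoff": int(cutoff),
        "n_rois": len(rois),
        "n_retained": len(retained),
        "n_intergenic": len(intergenic),
    }


@_stage("network")
def _network(normalized, hits: list[str], config: RunConfig, write) -> dict:
    graph = coex.correlation_graph(normalized.values, features=hits, threshold=config.r_threshold)
    comps, degrees = coex.graph_components(graph)
    log.info("network: %d nodes, %d edges, %d components",
             graph.number_of_nodes(), graph.number_of_edges(), len(comps))
    write("network.sif", lambda p: iof.write_graph(graph, p, fmt="sif"))
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "component_sizes": sorted((len(c) for c in comps), reverse=True),
    }
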