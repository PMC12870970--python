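"""End-to-end run: classification -> FPCA -> clustering -> merging, with a
manifest that makes deterministic stages re-runnable bit-identically."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_trajectories
from .fpca_cluster import (
    build_cluster_profiles,
    cluster_scores,
    merge_correlated_clusters,
    run_fpca,
)
from .io import AnalysisConfig, BetaMatrix, SampleTable, write_results

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _digest(frame: pd.DataFrame) -> str:
    return hashlib.sha256(pd.util.hash_pandas_object(frame, index=True).values.tobytes()).hexdigest()


def run_pipeline(
    beta: BetaMatrix,
    samples: SampleTable,
    config: AnalysisConfig | None = None,
    outdir: str | Path = "snitch_out",
    cluster_method: str = "hdbscan",
    skip_cluster: bool = False,
) -> Path:
    """Run all stages and write artifacts + a run manifest to ``outdir``.

    Artifacts: ``classification.csv``, ``nl_trajectories.csv``,
    ``fpca.json``, ``clusters.csv`` (pre-merge), ``clusters_merged.csv``,
    ``cluster_profiles.json`` and ``manifest.json``.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.__dict__, default=list)),
        "inputs": {
            "beta_sha256": _digest(beta.frame),
            "samples_sha256": _digest(samples.frame),
            "n_cpg": beta.n_cpg,
            "n_sample": beta.n_sample,
        },
    }

    t0 = time.perf_counter()
    classification = classify_trajectories(beta, samples, config)
    timings["classify"] = time.perf_counter() - t0
    write_results(classification.table, outdir / "classification.csv")

    if not skip_cluster:
        trajectories = classification.smoothed_trajectories("NL")
        n_nl = len(trajectories.cpg_ids)
        manifest["n_nl"] = n_nl
        if n_nl >= max(3, config.min_cluster_size):
            t0 = time.perf_counter()
            pd.DataFrame(
                trajectories.curves,
                index=pd.Index(trajectories.cpg_ids, name="cpg_id"),
                columns=[f"age_{g:g}" for g in trajectories.grid],
            ).to_csv(outdir / "nl_trajectories.csv")
            fpca = run_fpca(trajectories, config, standardize=True)
            write_results(fpca.to_dict(), outdir / "fpca.json")
            assignment = cluster_scores(
                fpca.scores,
                method=cluster_method,
                cpg_ids=trajectories.cpg_ids,
                seed=config.seed,
                min_cluster_size=config.min_cluster_size,
                restarts=config.kmeans_restarts,
            )
            write_results(assignment.to_frame(), outdir / "clusters.csv")
            profiles = build_cluster_profiles(assignment, trajectories, beta)
            merged = merge_correlated_clusters(
                profiles, trajectories, beta,
                rho_threshold=config.merge_rho, assignment=assignment,
            )
            write_results(merged.assignment.to_frame(), outdir / "clusters_merged.csv")
            write_results(
                {"profiles": [p.to_dict() for p in merged.profiles],
                 "merge_log": merged.log.to_dict(orient="records")},
                outdir / "cluster_profiles.json",
            )
            timings["cluster"] = time.perf_counter() - t0
        else:
            logger.warning("only %d NL CpGs; skipping FPCA/clustering", n_nl)

    manifest["stage_timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    label_counts = classification.table["label"].value_counts().to_dict()
    manifest["label_counts"] = {k: int(v) for k, v in label_counts.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
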