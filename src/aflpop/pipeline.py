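"""End-to-end analysis: filter -> ordination -> partitioning -> admixture ->
relatedness -> spatial autocorrelation, from one config, with a JSON
summary sufficient to regenerate every figure-style output.

One global seed feeds per-stage child seeds through numpy's SeedSequence
spawning, so any stage can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from . import ordination, partitioning, relatedness, spatial_autocorr
from .exceptions import ConfigError
from .marker_data import (
    MarkerMatrix,
    align_metadata,
    filter_loci,
    filter_webs,
    read_binary_matrix,
    read_metadata,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Everything one full analysis needs; serialized into every report."""

    matrix_path: str
    meta_path: str
    out_dir: str = "aflpop_run"
    seed: int = 0
    # filters
    min_web_size: int = 2
    drop_empty_individuals: bool = True
    # ordination
    nmds_dims: int = 3
    nmds_max_starts: int = 50
    nmds_conv_ratio: float = 0.999999
    # partitioning
    c_max: int | None = None  # default: number of webs
    linkage: str = "average"
    # admixture
    run_admixture: bool = True
    k_min: int = 1
    k_max: int | None = None  # default: number of webs + 2
    admixture_replicates: int = 3
    admixture_burn_in: int = 2000
    admixture_iters: int = 4000
    # relatedness
    relatedness_n_perm: int = 999
    relatedness_n_boot: int = 1000
    relatedness_min_web_size: int = 3
    # spatial autocorrelation
    autocorr_bounds: list[float] | None = None
    autocorr_n_perm: int = 999
    autocorr_n_boot: int = 1000
    strata: list[str] = field(default_factory=lambda: ["all"])
    # plotting
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def run_full_analysis(
    cfg: AnalysisConfig,
    matrix: MarkerMatrix | None = None,
    meta: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Run every stage, write per-stage outputs under ``cfg.out_dir`` and
    return (and write) the top-level summary dict.

    ``matrix``/``meta`` may be passed in-memory; otherwise they are read
    from the configured paths.  Deterministic under a fixed seed.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(cfg.seed).spawn(4 + len(cfg.strata))

    def _stage_seed(idx: int) -> int:
        return int(np.random.default_rng(children[idx]).integers(2**31))

    summary: dict[str, Any] = {"config": cfg.to_dict(), "stages": {}}

    def stage(name: str):
        logger.info("[%s] starting (t=%.1fs)", name, time.time() - t0)

    # ---- filtering -------------------------------------------------------
    stage("filter")
    if matrix is None:
        matrix = read_binary_matrix(cfg.matrix_path)
    if meta is None:
        meta = read_metadata(cfg.meta_path)
    filtered, report = filter_loci(
        matrix, drop_empty_individuals=cfg.drop_empty_individuals
    )
    filtered, meta_f = filter_webs(filtered, meta, cfg.min_web_size)
    filtered.to_csv(out / "filtered_matrix.csv")
    (out / "filter_report.json").write_text(report.to_json())
    n_webs = meta_f["web_id"].nunique()
    summary["stages"]["filter"] = {
        "n_individuals": filtered.n_individuals,
        "n_loci": filtered.n_loci,
        "n_webs": int(n_webs),
        "dropped_loci": report.n_loci_in - report.n_loci_out,
        "dropped_individuals": report.n_individuals_in - report.n_individuals_out,
    }

    # ---- ordination ------------------------------------------------------
    stage("nmds")
    diss = ordination.jaccard_dissimilarity(filtered)
    res = ordination.nmds(
        diss,
        k=cfg.nmds_dims,
        max_starts=cfg.nmds_max_starts,
        conv_ratio=cfg.nmds_conv_ratio,
        seed=_stage_seed(0),
    )
    coords = pd.DataFrame(
        res.configuration,
        columns=[f"dim{i+1}" for i in range(cfg.nmds_dims)],
    )
    coords.insert(0, "individual_id", filtered.individual_ids)
    coords.to_csv(out / "nmds_coordinates.tsv", sep="\t", index=False)
    summary["stages"]["nmds"] = {
        "stress": round(res.stress, 6),
        "n_starts_used": res.n_starts_used,
        "best_start_index": res.best_start_index,
        "converged": bool(res.converged),
    }

    # ---- partitioning ----------------------------------------------------
    stage("clusters")
    c_max = cfg.c_max if cfg.c_max is not None else max(2, int(n_webs))
    profile = partitioning.optimal_clusters(diss, c_max, cfg.linkage)
    pd.DataFrame(
        {"C": profile.candidates, "avg_silhouette": profile.scores}
    ).to_csv(out / "silhouette_profile.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"individual_id": filtered.individual_ids, "cluster": profile.labels}
    ).to_csv(out / "cluster_labels.csv", index=False)
    summary["stages"]["clusters"] = {
        "optimal_c": profile.optimal_c,
        "linkage": cfg.linkage,
        "c_max": int(c_max),
    }

    # ---- admixture -------------------------------------------------------
    if cfg.run_admixture:
        stage("admixture")
        k_max = cfg.k_max if cfg.k_max is not None else int(n_webs) + 2
        dk, runs = adm.run_k_scan(
            filtered,
            cfg.k_min,
            k_max,
            replicates=cfg.admixture_replicates,
            burn_in=cfg.admixture_burn_in,
            n_iter=cfg.admixture_iters,
            seed=_stage_seed(1),
        )
        dk.to_tsv(out / "delta_k.tsv")
        best_runs = runs[dk.optimal_k]
        q_best = adm.align_labels(best_runs)
        q_mean = np.mean(q_best, axis=0)
        qdf = pd.DataFrame(
            q_mean, columns=[f"q_{k+1}" for k in range(dk.optimal_k)]
        )
        qdf.insert(0, "individual_id", filtered.individual_ids)
        qdf.to_csv(out / "ancestry_Q.csv", index=False)
        summary["stages"]["admixture"] = {
            "optimal_k": dk.optimal_k,
            "k_range": [cfg.k_min, int(k_max)],
            "replicates": cfg.admixture_replicates,
            "burn_in": cfg.admixture_burn_in,
            "n_iter": cfg.admixture_iters,
        }

    # ---- relatedness -----------------------------------------------------
    stage("relatedness")
    rel_m, rel_meta = filter_webs(filtered, meta_f, cfg.relatedness_min_web_size)
    rel_summary: dict[str, Any] = {}
    if rel_m.n_individuals >= cfg.relatedness_min_web_size:
        rep = relatedness.group_relatedness_test(
            filtered,
            meta_f,
            n_perm=cfg.relatedness_n_perm,
            n_boot=cfg.relatedness_n_boot,
            seed=_stage_seed(2),
            min_web_size=cfg.relatedness_min_web_size,
        )
        rep.to_tsv(out / "relatedness_report.tsv")
        rel_summary = {
            row.web_id: {"mean_r": round(row.mean_r, 6), "p_ge": row.p_ge, "flag": row.flag}
            for row in rep.table.itertuples()
        }
    summary["stages"]["relatedness"] = rel_summary

    # ---- spatial autocorrelation ----------------------------------------
    stage("autocorr")
    auto_summary: dict[str, Any] = {}
    for i, stratum in enumerate(cfg.strata):
        try:
            cg = spatial_autocorr.correlogram(
                filtered,
                meta_f,
                bounds=cfg.autocorr_bounds,
                n_boot=cfg.autocorr_n_boot,
                n_perm=cfg.autocorr_n_perm,
                seed=_stage_seed(3 + i),
                stratum=stratum,
            )
        except Exception as exc:  # stratum too small etc.
            logger.warning("autocorr stratum %r failed: %s", stratum, exc)
            auto_summary[stratum] = {"error": str(exc)}
            continue
        cg.to_tsv(out / f"correlogram_{stratum}.tsv")
        auto_summary[stratum] = {
            "class_upper_m": [round(float(b), 3) for b in cg.table["class_upper_m"]],
            "r": [round(float(v), 6) for v in cg.table["r"]],
            "significant": [bool(v) for v in cg.table["significant"]],
        }
    summary["stages"]["autocorr"] = auto_summary

    if cfg.plots:
        from . import plots

        plots.plot_all(out, filtered, meta_f, res, profile)

    # timing stays out of the summary so reruns are byte-identical
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return summary
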