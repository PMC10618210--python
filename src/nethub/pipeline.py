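"""End-to-end orchestration: load -> DST -> hubs -> MDST -> candidate
pathways -> clamped transition ensemble -> pattern report.

A single base seed fans out deterministically to per-stage seeds (CRC32 of
the stage name mixed with the base), so any stage can be rerun independently
and the whole pipeline is reproducible from its manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import io as nio
from .boolean_sim import ClampSpec, run_ensemble
from .dst_search import DST, MDST, GAConfig, ga_search
from .graph_core import undirected_projection
from .hub_analysis import average_degrees, hub_connecting_paths, identify_hubs
from .transition_analysis import (
    distance_series,
    extract_patterns,
    tf_increase_counts,
    tf_on_probability_at_decrease_initiation,
    tf_pattern_frequencies,
)

__all__ = ["PipelineConfig", "run_full_pipeline", "stage_seed"]

log = logging.getLogger("nethub")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (base_seed + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    network_path: str
    rules_path: str | None = None
    states_path: str | None = None
    init_state: str | None = None
    target_state: str | None = None
    clamp_on: tuple[str, ...] = ()
    clamp_off: tuple[str, ...] = ()
    ga: GAConfig = field(default_factory=GAConfig)
    hub_rule: str = "above_mean"
    top_k: int = 2
    path_max_len: int = 2
    ensemble_size: int = 700
    max_iter: int = 1_000_000
    seed: int = 0
    out_dir: str = "nethub_out"

    def validate(self) -> None:
        if not Path(self.network_path).exists():
            raise FileNotFoundError(self.network_path)
        for p in (self.rules_path, self.states_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        simulate = self.rules_path is not None or self.states_path is not None
        if simulate and (self.rules_path is None or self.states_path is None):
            raise ValueError(
                "simulation requires both rules_path and states_path"
            )

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_hub_csv(report, hubs, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["node", "mean_degree", "sd", "hub_flag"])
        for node, mean, sd in sorted(
            zip(report.nodes, report.mean_degree, report.sd_degree),
            key=lambda t: (-t[1], t[0]),
        ):
            w.writerow([node, f"{mean:.6f}", f"{sd:.6f}", int(node in hubs)])


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Stage failures abort with the stage name in the raised error; outputs of
    completed stages are left in place.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "base_seed": cfg.seed,
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        net = nio.load_network(cfg.network_path)
        graph = undirected_projection(net)
        manifest["stages"][stage] = {
            "n_nodes": net.n_nodes,
            "n_edges": len(net.edges),
            "undirected_edges": graph.n_edges,
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        log.info("loaded %s: %d nodes, %d directed edges", net.name, net.n_nodes, len(net.edges))

        stage = "dst"
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, stage)
        ga_cfg = GAConfig(**{**cfg.ga.__dict__, "seed": seed})
        dst_archive = ga_search(graph, DST, ga_cfg)
        nio.write_archive(dst_archive, out / "dst_trees")
        dst_report = average_degrees(dst_archive)
        dst_hubs = identify_hubs(dst_report, cfg.hub_rule, k=cfg.top_k)
        _write_hub_csv(dst_report, set(dst_hubs), out / "dst_hubs.csv")
        manifest["stages"][stage] = {
            "seed": seed,
            "optimum_distance": dst_archive.optimum.distance_total,
            "archive_size": len(dst_archive),
            "hubs": dst_hubs,
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        log.info("DST: optimum %d, %d trees", dst_archive.optimum.distance_total, len(dst_archive))

        mdst_hubs = []
        if graph.weighted:
            stage = "mdst"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            ga_cfg = GAConfig(**{**cfg.ga.__dict__, "seed": seed})
            mdst_archive = ga_search(graph, MDST, ga_cfg)
            nio.write_archive(mdst_archive, out / "mdst_trees")
            mdst_report = average_degrees(mdst_archive)
            mdst_hubs = identify_hubs(mdst_report, cfg.hub_rule, k=cfg.top_k)
            _write_hub_csv(mdst_report, set(mdst_hubs), out / "mdst_hubs.csv")
            manifest["stages"][stage] = {
                "seed": seed,
                "optimum_distance": mdst_archive.optimum.distance_total,
                "optimum_cost": mdst_archive.optimum.cost_total,
                "archive_size": len(mdst_archive),
                "hubs": mdst_hubs,
                "wall_s": round(time.perf_counter() - t0, 3),
            }
            log.info("MDST: %d trees", len(mdst_archive))

        stage = "paths"
        top2 = identify_hubs(dst_report, "top_k", k=2)
        paths = hub_connecting_paths(net, top2[0], top2[1], cfg.path_max_len)
        with (out / "hub_paths.tsv").open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["path"])
            for p in paths:
                w.writerow(["-".join(p)])
        manifest["stages"][stage] = {"hub_pair": top2, "n_paths": len(paths)}

        if cfg.rules_path is not None:
            stage = "simulate"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            rules = nio.load_rules(cfg.rules_path)
            states = nio.load_states(cfg.states_path, rules.nodes)
            if cfg.init_state not in states or cfg.target_state not in states:
                raise ValueError(
                    f"init/target states {cfg.init_state!r}/{cfg.target_state!r} "
                    f"not among {sorted(states)}"
                )
            clamp = ClampSpec.of(cfg.clamp_on, cfg.clamp_off)
            trajectories, summary = run_ensemble(
                rules,
                states[cfg.init_state],
                states[cfg.target_state],
                clamp,
                n_runs=cfg.ensemble_size,
                max_iter=cfg.max_iter,
                base_seed=seed,
            )
            runs_dir = out / "runs"
            runs_dir.mkdir(exist_ok=True)
            for r, traj in enumerate(trajectories):
                nio.write_trajectory(traj, runs_dir / f"run_{r:04d}.tsv")
            manifest["stages"][stage] = {
                "seed": seed,
                "n_runs": summary.n_runs,
                "convergence_fraction": summary.convergence_fraction,
                "iteration_quantiles": summary.iteration_quantiles,
                "wall_s": round(time.perf_counter() - t0, 3),
            }
            log.info("ensemble: %.1f%% converged", 100 * summary.convergence_fraction)

            stage = "analyze"
            t0 = time.perf_counter()
            target = states[cfg.target_state]
            all_series = [distance_series(t, target) for t in trajectories]
            all_patterns = [
                p for s in all_series for p in extract_patterns(s)
            ]
            freq = tf_pattern_frequencies(all_patterns, rules.nodes)
            inc = tf_increase_counts(all_series, rules.nodes)
            try:
                on_prob = tf_on_probability_at_decrease_initiation(
                    all_patterns, rules.nodes
                )
            except ValueError:
                on_prob = {n: float("nan") for n in rules.nodes}
            with (out / "pattern_report.csv").open("w", newline="") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(
                    ["node", "decreasing_patterns", "increasing_patterns",
                     "increase_iterations", "p_on_at_decrease_initiation"]
                )
                for n in rules.nodes:
                    w.writerow(
                        [n, freq["decreasing"][n], freq["increasing"][n],
                         inc[n], f"{on_prob[n]:.6f}"]
                    )
            for r, series in enumerate(all_series):
                with (runs_dir / f"run_{r:04d}_distance.tsv").open("w", newline="") as fh:
                    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                    w.writerow(["iteration", "lcs_distance"])
                    for t, d in enumerate(series.distances):
                        w.writerow([t - 1 if t else "init", int(d)])
            manifest["stages"][stage] = {
                "n_patterns": len(all_patterns),
                "wall_s": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
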