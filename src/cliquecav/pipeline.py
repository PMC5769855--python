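"""End-to-end analysis: load/average/threshold -> cliques & stats ->
persistence -> minimal cycles -> null comparison -> per-scan matching.

Driven by a flat INI config; every output is listed in a JSON manifest
together with the parameters and seeds that produced it, so any file is
regenerable from the manifest alone.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cliques as cliques_mod
from . import graph_stats, matching, synthetic
from .cycles import minimal_cycles
from .network import (
    WeightedNetwork,
    add_tiebreak_noise,
    group_average,
    load_network,
    save_thresholded,
    threshold_by_density,
)
from .persistence import betti_curves, build_filtration, persistent_homology

__all__ = ["RunConfig", "PipelineStageError", "run_full_analysis"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input fingerprint."""


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of a full run.

    Defaults mirror the analysis conditions: threshold rho = 0.25, homology
    dimensions 1-2, tie-break noise bound 1e-4, 1000 rich-club nulls.
    """

    network_paths: list[Path]
    output_dir: Path
    metadata_path: Path | None = None
    scan_paths: list[Path] = dataclasses.field(default_factory=list)
    rho: float = 0.25
    max_dim: int = 2
    tiebreak: str = "lex"  # 'lex' | 'noise'
    noise_epsilon: float = 1e-4
    seed: int = 0
    average_order: str = "average-then-threshold"
    null_model: bool = False
    n_null: int = 1000
    matching_enabled: bool = True
    n_cycle_points: int = 8  # longest-lived classes to recover cycles for

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(path)
        base = Path(path).parent

        def paths(section: str, key: str) -> list[Path]:
            raw = cp.get(section, key, fallback="").strip()
            return [base / p for p in raw.split()] if raw else []

        cfg = cls(
            network_paths=paths("input", "network"),
            metadata_path=(paths("input", "metadata") or [None])[0],
            scan_paths=paths("input", "scans"),
            output_dir=base / cp.get("output", "dir", fallback="results"),
            rho=cp.getfloat("analysis", "rho", fallback=0.25),
            max_dim=cp.getint("analysis", "max_dim", fallback=2),
            tiebreak=cp.get("analysis", "tiebreak", fallback="lex"),
            noise_epsilon=cp.getfloat("analysis", "noise_epsilon", fallback=1e-4),
            seed=cp.getint("analysis", "seed", fallback=0),
            null_model=cp.getboolean("null", "enabled", fallback=False),
            n_null=cp.getint("richclub", "n_null", fallback=1000),
            matching_enabled=cp.getboolean("matching", "enabled", fallback=True),
            n_cycle_points=cp.getint("analysis", "n_cycle_points", fallback=8),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.network_paths:
            raise ValueError("config must list at least one input network")
        for p in [*self.network_paths, *self.scan_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.metadata_path is not None and not Path(self.metadata_path).exists():
            raise FileNotFoundError(self.metadata_path)
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.tiebreak not in ("lex", "noise"):
            raise ValueError("tiebreak must be 'lex' or 'noise'")


def _fingerprint(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Any stage error aborts with the stage name and an input fingerprint.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (str(v) if isinstance(v, Path) else [str(x) for x in v] if isinstance(v, list) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {str(p): _fingerprint(p) for p in config.network_paths},
        "outputs": {},
    }
    stage = "load"
    try:
        nets = [load_network(p, config.metadata_path) for p in config.network_paths]
        net = group_average(nets) if len(nets) > 1 else nets[0]
        if config.tiebreak == "noise":
            net = add_tiebreak_noise(net, config.noise_epsilon, seed=config.seed)

        if config.null_model:
            stage = "null_model"
            coords = net.coordinates()
            if coords is None:
                raise ValueError(
                    "null model requested but metadata has no x/y/z coordinates"
                )
            mw = synthetic.minimally_wired(coords, list(net.node_ids))
        else:
            mw = None

        stage = "threshold"
        tnet = threshold_by_density(net, config.rho)
        save_thresholded(tnet, out / "thresholded.csv")
        manifest["outputs"]["thresholded.csv"] = {"rho": config.rho}

        stage = "cliques"
        mc = cliques_mod.maximal_cliques(tnet)
        with open(out / "maximal_cliques.txt", "w") as fh:
            for c in mc:
                fh.write(" ".join(net.node_ids[v] for v in sorted(c)) + "\n")
        part = cliques_mod.node_participation(mc, net.n_nodes)
        _write_tsv(part.assign(node=net.node_ids), out / "participation.tsv")
        manifest["outputs"]["participation.tsv"] = {"n_maximal_cliques": len(mc)}
        labels = net.systems()
        if labels is not None:
            by_sys = cliques_mod.participation_by_group(part, labels)
            _write_tsv(by_sys, out / "participation_by_system.tsv", index=True)
            manifest["outputs"]["participation_by_system.tsv"] = {}
        if mw is not None:
            tmw = threshold_by_density(mw, config.rho)
            part_mw = cliques_mod.node_participation(
                cliques_mod.maximal_cliques(tmw), net.n_nodes
            )
            diff = cliques_mod.participation_difference(part, part_mw)
            _write_tsv(diff.assign(node=net.node_ids), out / "participation_diff_mw.tsv")
            manifest["outputs"]["participation_diff_mw.tsv"] = {}

        stage = "graph_stats"
        comm = graph_stats.communicability(net)
        cores = graph_stats.core_decomposition(net)
        rc = graph_stats.rich_club(net, n_null=config.n_null, seed=config.seed)
        node_table = pd.DataFrame(
            {
                "node": net.node_ids,
                "strength": net.strengths,
                "communicability": comm.node_communicability,
                "k_core": cores.k_core,
                "s_core": cores.s_core,
            }
        )
        _write_tsv(node_table, out / "stats_nodes.tsv")
        _write_tsv(rc.table.reset_index(), out / "stats_richclub.tsv")
        manifest["outputs"]["stats_nodes.tsv"] = {}
        manifest["outputs"]["stats_richclub.tsv"] = {
            "n_null": config.n_null,
            "seed": config.seed,
            "degenerate": bool(rc.degenerate),
        }

        stage = "persistence"
        filt = build_filtration(net)
        diagram = persistent_homology(filt, max_dim=config.max_dim)
        _write_tsv(diagram.to_dataframe(), out / "diagram_empirical.tsv")
        _write_tsv(betti_curves(filt, config.max_dim), out / "betti_empirical.tsv")
        manifest["outputs"]["diagram_empirical.tsv"] = {
            "n_points": len(diagram.points)
        }
        if mw is not None:
            filt_mw = build_filtration(mw)
            dgm_mw = persistent_homology(filt_mw, max_dim=config.max_dim)
            _write_tsv(dgm_mw.to_dataframe(), out / "diagram_minimally_wired.tsv")
            manifest["outputs"]["diagram_minimally_wired.tsv"] = {
                "n_points": len(dgm_mw.points)
            }

        stage = "minimal_cycles"
        points = sorted(
            diagram.positive(), key=lambda p: -(p.lifetime if np.isfinite(p.lifetime) else 1e9)
        )[: config.n_cycle_points]
        cycle_records = []
        reference_reps = []
        for p in points:
            reps = minimal_cycles(filt, p)
            reference_reps.append((p, reps))
            cycle_records.append(
                {
                    "dim": p.dimension,
                    "rho_birth": p.rho_birth,
                    "rho_death": None if p.death_step is None else p.rho_death,
                    "representatives": [
                        {
                            "class_id": r.class_id,
                            "cliques": [
                                [net.node_ids[v] for v in c] for c in sorted(r.cliques)
                            ],
                        }
                        for r in reps
                    ],
                }
            )
        with open(out / "minimal_cycles.json", "w") as fh:
            json.dump(cycle_records, fh, indent=1, sort_keys=True)
        manifest["outputs"]["minimal_cycles.json"] = {"n_points": len(points)}

        if config.matching_enabled and config.scan_paths:
            stage = "matching"
            rows = []
            for sp in config.scan_paths:
                scan = load_network(sp, config.metadata_path)
                for p, reps in reference_reps:
                    res = matching.match_scan(reps, scan, scan_id=Path(sp).name)
                    rows.append(
                        {
                            "scan": res.scan_id,
                            "dim": p.dimension,
                            "ref_rho_birth": p.rho_birth,
                            "rule1": res.rule1_any,
                            "rule2": res.rule2_found,
                            "subrule": res.subrule or "",
                            "density": res.density,
                        }
                    )
            _write_tsv(pd.DataFrame(rows), out / "match_table.tsv")
            manifest["outputs"]["match_table.tsv"] = {"n_scans": len(config.scan_paths)}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineStageError):
            raise
        fp = manifest["inputs"]
        raise PipelineStageError(f"stage '{stage}' failed (inputs {fp}): {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
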