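"""End-to-end pipeline: data → equilibrium → ensemble → consensus → diff.

Driven by a single YAML/JSON config with sections mirroring the library
modules. Each treatment group either names a synthetic preset or points
at abundance/metadata files; the pipeline aggregates to the requested
rank, converts to floored relative abundances, estimates the group
equilibrium over its week window, runs the repeated Monte-Carlo direct
search anchored to the per-subject trajectories, distills a consensus
signed network, and finally compares the named pair of networks. All
randomness derives from a single top-level seed recorded in the log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abundance import (
    AbundanceTable,
    SampleMetadata,
    aggregate_taxa,
    estimate_equilibrium,
    read_metadata,
    read_table,
    relative_abundance,
    subject_trajectories,
    write_table,
    DEFAULT_FLOOR,
)
from .inference import SearchConfig, consensus_network, infer_ensemble
from .networks import SignedNetwork, compare_networks
from .synthetic import generate_dataset, make_scenario

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_WINDOWS"]

#: Default week-of-age windows for equilibrium estimation: the full
#: series for untreated groups, post-treatment weeks (>= 9 weeks of age,
#: when dosing starts) for treated ones.
DEFAULT_WINDOWS = {"control": (3.0, 15.0), "treated": (9.0, 15.0)}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _derived_seed(base_seed: int, salt: int) -> int:
    return int(
        np.random.SeedSequence([int(base_seed), int(salt)]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class _GroupResult:
    name: str
    network: SignedNetwork
    edge_tsv: Path


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the full analysis described by a config file or dict.

    Returns a dict with the per-group networks and the comparison, and
    writes all artifacts (tables, ensemble JSON, edge-list TSV, GraphML,
    diff report, log) under the output directory. Deterministic for a
    fixed config and seed.
    """
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "config"
    try:
        if isinstance(config, (str, Path)):
            cfg = yaml.safe_load(Path(config).read_text())
        else:
            cfg = dict(config)
        if not isinstance(cfg, dict) or "groups" not in cfg:
            raise ValueError("config must be a mapping with a 'groups' section")
        base_seed = int(seed if seed is not None else cfg.get("seed", 0))
        out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "."))
        out.mkdir(parents=True, exist_ok=True)
        ab_cfg = cfg.get("abundance", {})
        level = ab_cfg.get("level", "phylum")
        floor = float(ab_cfg.get("floor", DEFAULT_FLOOR))
        inf_cfg = dict(cfg.get("inference", {}))
        cons_cfg = cfg.get("consensus", {})
        sign_support = float(cons_cfg.get("sign_support", 0.8))
        strength_floor = float(cons_cfg.get("strength_floor", 0.05))
        compare_pair = cfg.get("compare")
        weight_tol = float(cfg.get("weight_tol", 0.05))
        groups = cfg["groups"]
        if not isinstance(groups, dict) or not groups:
            raise ValueError("'groups' must be a non-empty mapping")
    except (ValueError, TypeError, KeyError, OSError, yaml.YAMLError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    log(f"glvnet {__version__} | numpy {np.__version__}")
    log(f"seed: {base_seed}")
    log(f"output directory: {out}")

    results: dict[str, _GroupResult] = {}
    for gi, (gname, gcfg) in enumerate(groups.items()):
        stage = f"data:{gname}"
        try:
            if "preset" in gcfg:
                scen_seed = _derived_seed(base_seed, 2 * gi)
                scen = make_scenario(
                    gcfg["preset"], {"seed": scen_seed, **gcfg.get("overrides", {})}
                )
                table, meta = generate_dataset(scen)
                write_table(table, out / f"{gname}_counts.tsv")
                meta.to_tsv(out / f"{gname}_metadata.tsv")
                (out / f"{gname}_scenario.json").write_text(scen.to_json())
                log(f"{gname}: synthesized preset {gcfg['preset']!r} "
                    f"(seed {scen_seed})")
            else:
                table = read_table(gcfg["table"], gcfg.get("format", "tsv"))
                meta = read_metadata(gcfg["metadata"])
                log(f"{gname}: read {gcfg['table']}")
        except (ValueError, KeyError, OSError) as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = f"aggregate:{gname}"
        try:
            table = aggregate_taxa(table, level)
            rel = relative_abundance(table, floor)
        except ValueError as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = f"equilibrium:{gname}"
        try:
            window = tuple(gcfg.get("window") or DEFAULT_WINDOWS[
                "control" if gi == 0 else "treated"])
            group_label = gcfg.get("group_label", gname)
            eq = estimate_equilibrium(rel, meta, group_label, window, floor)
            (out / f"{gname}_equilibrium.json").write_text(eq.to_json())
            log(f"{gname}: y_bar over weeks {window} = "
                f"{np.array2string(eq.y_bar, precision=4)}")
        except ValueError as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = f"infer:{gname}"
        try:
            search = SearchConfig(
                **{**inf_cfg, "seed": _derived_seed(base_seed, 2 * gi + 1)}
            )
            trajs = subject_trajectories(rel, meta, group_label)
            ensemble = infer_ensemble(
                eq.y_bar, search, trajectories=trajs, taxa=rel.taxa
            )
            ensemble.save(out / f"{gname}_ensemble.json")
            log(f"{gname}: {len(ensemble.accepted)}/{search.n_restarts} "
                f"restarts admissible")
        except (ValueError, TypeError, RuntimeError) as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = f"consensus:{gname}"
        try:
            net = consensus_network(ensemble, sign_support, strength_floor)
            edge_tsv = out / f"{gname}_edges.tsv"
            net.to_edgelist_tsv(edge_tsv)
            net.to_graphml(out / f"{gname}_network.graphml")
            with open(out / f"{gname}_self_limitation.tsv", "w") as fh:
                fh.write("taxon\tself_limitation\n")
                for taxon in net.nodes:
                    fh.write(f"{taxon}\t{net.self_limitation[taxon]:.10g}\n")
            log(f"{gname}: consensus network with {len(net.edges)} edges")
        except ValueError as exc:
            raise PipelineError(stage, str(exc)) from exc

        results[gname] = _GroupResult(gname, net, edge_tsv)

    diff = None
    if compare_pair:
        stage = "compare"
        try:
            first, second = compare_pair
            diff = compare_networks(
                results[first].network, results[second].network, weight_tol
            )
            (out / "diff.json").write_text(diff.to_json())
            log(
                f"compare {first} vs {second}: "
                f"{len(diff.edges_only_in_first)} lost, "
                f"{len(diff.edges_only_in_second)} gained, "
                f"{len(diff.sign_flips)} sign flips, "
                f"{len(diff.weight_changes)} weight changes"
            )
        except (ValueError, KeyError) as exc:
            raise PipelineError(stage, str(exc)) from exc

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return {
        "networks": {g: r.network for g, r in results.items()},
        "diff": diff,
        "out_dir": out,
    }
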