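"""End-to-end orchestration: seeds -> network -> subnetwork -> connectivity
significance -> MCODE modules -> enrichment & prioritization -> hub tables.

A :class:`RunConfig` (YAML-serializable) names every input and parameter;
``run_all`` validates the inputs up front, executes the stages, writes each
stage's table, and finishes with a manifest mapping every output file to its
SHA-256 content hash. Outputs are deterministically ordered, so rerunning
the same config with the same seed reproduces the hashes bit for bit (the
config echo, log, and manifest itself are excluded from hashing since they
may embed paths).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import graph_core, seed_selection, connectivity, mcode as mcode_mod
from . import hub_centrality, enrichment as enrichment_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all"]


@dataclass
class RunConfig:
    edge_lists: list[str] = field(default_factory=list)
    score_table: str = ""
    gmt_files: list[str] = field(default_factory=list)
    out_dir: str = "ppinet_out"
    symbol_col: str = "gene"
    score_col: str = "inference_score"
    seed_threshold: float = 40.0
    strict_threshold: bool = True
    taxid_filter: int | None = None
    alpha: float = 0.05
    n_reps: int = 1000
    null_mode: str = "uniform"
    rng_seed: int = 0
    mcode_params: dict = field(default_factory=dict)
    universe: str = "interactome"  # or a path to a newline-separated list
    hub_scope: str = "module"  # or "network"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not self.edge_lists:
            raise ValueError("config needs at least one edge list")
        for p in [*self.edge_lists, self.score_table, *self.gmt_files]:
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")
        if self.universe != "interactome" and not Path(self.universe).exists():
            raise FileNotFoundError(f"universe file missing: {self.universe}")
        if self.hub_scope not in ("module", "network"):
            raise ValueError("hub_scope must be 'module' or 'network'")
        if self.null_mode not in ("uniform", "degree_binned"):
            raise ValueError("null_mode must be 'uniform' or 'degree_binned'")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as
    ``manifest.json``). Any stage failure halts with the stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    outputs: list[Path] = []

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("seeds")
        pairs = seed_selection.read_score_table(
            config.score_table, config.symbol_col, config.score_col
        )
        seeds = seed_selection.select_seeds(
            pairs, config.seed_threshold, strict=config.strict_threshold
        )
        seed_selection.write_seed_list(seeds, out / "seeds.tsv")
        outputs.append(out / "seeds.tsv")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("seeds", e) from e

    try:
        _stage("network")
        parts = []
        for path in config.edge_lists:
            records = graph_core.read_edge_list(path, source=Path(path).stem)
            parts.append(
                graph_core.build_interactome(records, taxid_filter=config.taxid_filter)
            )
        network = graph_core.merge(parts) if len(parts) > 1 else parts[0]
        stats = {
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
            "inputs": [asdict(p.build_report) for p in parts if p.build_report],
        }
        with open(out / "network_stats.json", "w") as fh:
            json.dump(stats, fh, indent=1, sort_keys=True)
        outputs.append(out / "network_stats.json")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("network", e) from e

    try:
        _stage("subnetwork")
        selected = seeds.selected_genes
        induced = graph_core.induced_subgraph(network, selected)
        comps = graph_core.connected_components(induced)
        if not comps:
            raise ValueError("no seed gene maps to the network")
        subnetwork = graph_core.induced_subgraph(induced, comps[0])
        graph_core.write_graph(subnetwork, out / "subnetwork.tsv", format="tsv")
        outputs += [out / "subnetwork.tsv", out / "subnetwork.nodes.tsv"]
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("subnetwork", e) from e

    try:
        _stage("significance")
        lcc_sum, shd_sum = connectivity.significance(
            network,
            selected,
            n_reps=config.n_reps,
            rng_seed=config.rng_seed,
            mode=config.null_mode,
        )
        with open(out / "significance.tsv", "w") as fh:
            keys = [
                "statistic", "observed", "null_mean", "null_sd", "z_score",
                "z_defined", "empirical_p", "n_reps", "rng_seed", "tail",
                "n_undefined_null",
            ]
            fh.write("\t".join(keys) + "\n")
            for s in (lcc_sum, shd_sum):
                d = s.to_dict()
                fh.write("\t".join(_fmt(d[k]) for k in keys) + "\n")
        with open(out / "null_draws.tsv", "w") as fh:
            fh.write("rep\tlcc\tshd\n")
            for i, (a, b) in enumerate(
                zip(lcc_sum.null_values, shd_sum.null_values)
            ):
                fh.write(f"{i}\t{a:g}\t{b:.6g}\n")
        outputs += [out / "significance.tsv", out / "null_draws.tsv"]
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("significance", e) from e

    try:
        _stage("modules")
        params = mcode_mod.McodeParams(**config.mcode_params)
        modules = mcode_mod.run_mcode(subnetwork, params)
        mcode_mod.write_modules(modules, out / "modules.tsv")
        with open(out / "mcode_params.json", "w") as fh:
            json.dump(asdict(params), fh, indent=1, sort_keys=True)
        outputs += [out / "modules.tsv", out / "mcode_params.json"]
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("modules", e) from e

    try:
        _stage("enrichment")
        collections = [enrichment_mod.read_gmt(p) for p in config.gmt_files]
        if config.universe == "interactome":
            universe = network.nodes
        else:
            universe = {
                line.strip()
                for line in Path(config.universe).read_text().splitlines()
                if line.strip()
            }
        results = enrichment_mod.module_enrichment(modules, collections, universe)
        results.to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
        prioritized = enrichment_mod.prioritize_modules(results, alpha=config.alpha)
        with open(out / "prioritized.tsv", "w") as fh:
            fh.write("rank\tmodule\n")
            for i, label in enumerate(prioritized, start=1):
                fh.write(f"{i}\t{label}\n")
        outputs += [out / "enrichment.tsv", out / "prioritized.tsv"]
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("enrichment", e) from e

    try:
        _stage("hubs")
        if config.hub_scope == "module":
            tables = {
                m.label: hub_centrality.hub_table(subnetwork, m) for m in modules
            }
        else:
            tables = {"network": hub_centrality.hub_table(subnetwork)}
        hub_centrality.write_hub_table(tables, out / "hubs.tsv")
        outputs.append(out / "hubs.tsv")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("hubs", e) from e

    manifest = {
        "rng_seed": config.rng_seed,
        "n_reps": config.n_reps,
        "files": {p.name: _sha256(p) for p in outputs},
        "prioritized_modules": prioritized,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)
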