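"""File-level pipeline stages shared by the CLI and scripted use.

Each stage reads standard inputs (SBML network directory, compound-set
files), runs one analysis, and writes machine-readable outputs into an
output directory:

========== =====================================================
stage       outputs
========== =====================================================
iscope      ``indiv_scopes.json``, ``scope_summary.json``
cscope      ``comm_scopes.json``
addedvalue  ``addedvalue.json``, ``addedvalue.sbml``
mincom      ``mincom.json``, ``producibility_targets.json``
            (+ ``enumeration.json`` when enumeration is on)
analysis    ``association_graph.gml`` / ``.tsv``,
            ``key_species_taxonomy.tsv``
========== =====================================================

Output JSON files are deterministic for given inputs (no embedded
timestamps), so running the four stages in sequence produces the same
files as the all-in-one ``metacom`` runner.  Every run also appends a
``run_metadata.json`` parameter record and a human-readable log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .analysis import association_graph, read_taxonomy, taxonomy_summary, write_graph
from .expansion import (
    classify_target_producers,
    community_scope,
    cooperation_potential,
    individual_scopes,
    scope_summary,
)
from .model import CompoundSet, NetworkCollection, remove_orphan_reactions
from .sbml_io import read_collection, read_compound_set, write_compound_set
from .selection import (
    DEFAULT_ENUMERATION_CAP,
    enumerate_minimal_communities,
    key_species,
    key_species_from_enumeration,
    minimal_community,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    networks_dir: Path
    seeds_path: Path
    output_dir: Path
    targets_path: Path | None = None
    noorphan: bool = False
    enumerate: bool = False
    cap: int = DEFAULT_ENUMERATION_CAP
    taxonomy_path: Path | None = None
    include_seed_compounds: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.networks_dir = Path(self.networks_dir)
        self.seeds_path = Path(self.seeds_path)
        self.output_dir = Path(self.output_dir)
        if self.targets_path is not None:
            self.targets_path = Path(self.targets_path)
        if self.taxonomy_path is not None:
            self.taxonomy_path = Path(self.taxonomy_path)

    def record(self) -> dict:
        return {
            "version": __version__,
            "networks_dir": str(self.networks_dir),
            "seeds_path": str(self.seeds_path),
            "targets_path": str(self.targets_path) if self.targets_path else None,
            "output_dir": str(self.output_dir),
            "noorphan": self.noorphan,
            "enumerate": self.enumerate,
            "cap": self.cap,
            "taxonomy_path": str(self.taxonomy_path) if self.taxonomy_path else None,
            "include_seed_compounds": self.include_seed_compounds,
            "rng_seed": self.rng_seed,
        }


def _write_json(path: Path, payload: object) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _setup_output(config: RunConfig, stage: str) -> Path:
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    record_path = out / "run_metadata.json"
    record = {"parameters": config.record(), "stages": []}
    if record_path.exists():
        record = json.loads(record_path.read_text(encoding="utf-8"))
    if stage not in record["stages"]:
        record["stages"].append(stage)
    record["parameters"] = config.record()
    _write_json(record_path, record)
    handler = logging.FileHandler(out / "comscope.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("comscope")
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out / "comscope.log").resolve()
        for h in root.handlers
    ):
        root.addHandler(handler)
    return out


def load_inputs(
    config: RunConfig,
) -> tuple[NetworkCollection, CompoundSet, CompoundSet | None]:
    coll = read_collection(config.networks_dir)
    if config.noorphan:
        coll = NetworkCollection(remove_orphan_reactions(net) for net in coll)
    seeds = read_compound_set(config.seeds_path, "seeds")
    targets = None
    if config.targets_path is not None:
        targets = read_compound_set(config.targets_path, "targets")
    return coll, seeds, targets


def stage_iscope(config: RunConfig) -> dict[str, Path]:
    """Individual scopes per network plus union/intersection summary."""
    out = _setup_output(config, "iscope")
    coll, seeds, _ = load_inputs(config)
    scopes = individual_scopes(coll, seeds)
    payload = {
        org: sorted(res.reachable if config.include_seed_compounds else res.produced)
        for org, res in scopes.items()
    }
    summary = scope_summary(coll, seeds)
    _write_json(out / "indiv_scopes.json", payload)
    _write_json(
        out / "scope_summary.json",
        {
            "union": sorted(summary.union),
            "intersection": sorted(summary.intersection),
            "min_size": summary.min_size,
            "max_size": summary.max_size,
            "mean_size": summary.mean_size,
        },
    )
    logger.info(
        "iscope: %d networks, union %d, intersection %d",
        len(coll),
        len(summary.union),
        len(summary.intersection),
    )
    return {"indiv_scopes": out / "indiv_scopes.json",
            "scope_summary": out / "scope_summary.json"}


def stage_cscope(config: RunConfig) -> dict[str, Path]:
    """Community (collective) scope of the pooled meta-network."""
    out = _setup_output(config, "cscope")
    coll, seeds, _ = load_inputs(config)
    com = community_scope(coll, seeds)
    reported = com.reachable if config.include_seed_compounds else com.produced
    _write_json(out / "comm_scopes.json", {"com_scope": sorted(reported)})
    logger.info("cscope: %d producible metabolites", len(com.produced))
    return {"comm_scopes": out / "comm_scopes.json"}


def stage_addedvalue(config: RunConfig) -> dict[str, Path]:
    """Cooperation potential: community-only producible metabolites."""
    out = _setup_output(config, "addedvalue")
    coll, seeds, _ = load_inputs(config)
    coop = cooperation_potential(coll, seeds)
    _write_json(out / "addedvalue.json", {"addedvalue": sorted(coop.ids)})
    write_compound_set(coop, out / "addedvalue.sbml")
    logger.info("addedvalue: %d cooperation-only metabolites", len(coop))
    return {
        "addedvalue_json": out / "addedvalue.json",
        "addedvalue_sbml": out / "addedvalue.sbml",
    }


def _resolve_targets(
    config: RunConfig, coll: NetworkCollection, seeds: CompoundSet,
    targets: CompoundSet | None,
) -> CompoundSet:
    if targets is not None:
        return targets
    prior = config.output_dir / "addedvalue.sbml"
    if prior.exists():
        return read_compound_set(prior, "targets")
    coop = cooperation_potential(coll, seeds)
    if not coop.ids:
        raise ValueError(
            "no targets given and the cooperation potential is empty; "
            "provide --targets"
        )
    return CompoundSet("targets", coop.ids)


def stage_mincom(config: RunConfig, require_targets: bool = False) -> dict[str, Path]:
    """Minimal community + key species for the targets (or the
    cooperation potential when no explicit targets are given)."""
    out = _setup_output(config, "mincom")
    coll, seeds, targets = load_inputs(config)
    if require_targets and targets is None and not (
        config.output_dir / "addedvalue.sbml"
    ).exists():
        raise ValueError(
            "mincom needs targets: provide --targets or run addedvalue first"
        )
    targets = _resolve_targets(config, coll, seeds, targets)
    mincom = minimal_community(coll, seeds, targets)
    outputs: dict[str, Path] = {}
    if config.enumerate:
        enum = enumerate_minimal_communities(coll, seeds, targets, cap=config.cap)
        ks = key_species_from_enumeration(enum)
        _write_json(
            out / "enumeration.json",
            {
                "communities": [list(c) for c in enum.communities],
                "complete": enum.complete,
            },
        )
        outputs["enumeration"] = out / "enumeration.json"
    else:
        ks = key_species(coll, seeds, targets)
    payload = {**mincom.to_dict(), **ks.to_dict()}
    _write_json(out / "mincom.json", payload)
    report = classify_target_producers(coll, seeds, targets)
    _write_json(out / "producibility_targets.json", report.to_dict())
    logger.info(
        "mincom: min_size %d, %d key species (%d essential)",
        mincom.min_size,
        len(ks.key_species),
        len(ks.essential_symbionts),
    )
    outputs.update(
        {
            "mincom": out / "mincom.json",
            "producibility_targets": out / "producibility_targets.json",
        }
    )
    return outputs


def stage_analysis(config: RunConfig) -> dict[str, Path]:
    """Association graph over enumerated optima + taxonomy role table."""
    out = _setup_output(config, "analysis")
    coll, seeds, targets = load_inputs(config)
    targets = _resolve_targets(config, coll, seeds, targets)
    enum = enumerate_minimal_communities(coll, seeds, targets, cap=config.cap)
    ks = key_species_from_enumeration(enum)
    graph = association_graph(enum, ks)
    write_graph(graph, out / "association_graph.gml", out / "association_graph.tsv")
    taxonomy = (
        read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    )
    table = taxonomy_summary(ks, coll, taxonomy)
    table.to_csv(out / "key_species_taxonomy.tsv", sep="\t")
    logger.info(
        "analysis: %d communities, graph %d nodes / %d edges",
        len(enum),
        graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return {
        "gml": out / "association_graph.gml",
        "edge_list": out / "association_graph.tsv",
        "taxonomy": out / "key_species_taxonomy.tsv",
    }


def run_metacom(config: RunConfig) -> dict[str, Path]:
    """Full workflow: iscope → cscope → addedvalue → mincom.

    Without explicit targets, the cooperation potential computed at the
    addedvalue stage becomes the community-selection objective.
    """
    outputs = {}
    outputs.update(stage_iscope(config))
    outputs.update(stage_cscope(config))
    outputs.update(stage_addedvalue(config))
    outputs.update(stage_mincom(config))
    return outputs
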