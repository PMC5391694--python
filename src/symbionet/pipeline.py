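"""End-to-end per-region analysis: config in, report bundle out.

Sequences records -> traits -> diversity -> null models -> network for one
region, writing every table, graph and JSON report into an output directory
with a checksum manifest. Defaults follow the standard settings of this kind
of analysis: 8-collection minimum per plant genus, 99 burn-in swap steps and
9999 analysed null samples, 999 dispersion permutations, 100 Louvain restarts.

A single top-level seed drives every stochastic stage through spawned
sub-seeds, so a given config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import (
    dispersion_test,
    group_functional_diversity,
    group_fungal_diversity,
    pca_ordination,
)
from .errors import PipelineStageError, SymbionetError
from .network import (
    host_breadth_summary,
    louvain_partition,
    nestedness_test,
    project_unipartite,
    write_edge_list_csv,
    write_graphml,
    write_nestedness_report,
    write_partition_csv,
)
from .nullmodels import diversity_gap_test, sample_null, write_null_report
from .records import (
    apply_min_collections,
    build_matrix,
    filter_ecm_fungi,
    filter_ecm_plants,
    load_status_table,
    read_records,
    resolve_nothofagaceae,
)
from .traits import assign_exploration_types, load_exploration_lookup

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    records_path: str
    plant_status_path: str
    ecm_plants_path: str
    fungal_status_path: str
    exploration_types_path: str
    region: str
    output_dir: str
    seed: int
    min_collections: int = 8
    exclude_genus_only_fungi: bool = False
    burn_in: int = 99
    n_samples: int = 9999
    thin: int = 1
    n_perm: int = 999
    louvain_restarts: int = 100
    strict_lookups: bool = False
    include_self_loops: bool = True
    level: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SymbionetError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict[str, str]
    interaction_matrix: object
    functional_matrix: object
    fungal_diversity: object
    functional_diversity: object
    ordination: object
    dispersion: object
    gap_test: object
    nestedness: object
    graph: object
    partition: object
    host_breadth: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_region_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Run the full analysis for one region and write the report bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    # Four independent sub-seeds: functional null ensemble, nestedness
    # ensemble, dispersion permutations, Louvain restarts.
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(4)
    ]

    try:
        stage = "records"
        rs = read_records(cfg.records_path)
        logger.info("records: %d read from %s", len(rs), cfg.records_path)
        table = load_status_table(
            cfg.plant_status_path, cfg.ecm_plants_path, cfg.fungal_status_path
        )
        rs = filter_ecm_plants(rs, table)
        rs = filter_ecm_fungi(rs, table, strict=cfg.strict_lookups)
        rs = resolve_nothofagaceae(rs)
        matrix = build_matrix(
            rs, cfg.region, table, exclude_genus_only_fungi=cfg.exclude_genus_only_fungi
        )
        matrix = apply_min_collections(matrix, cfg.min_collections)
        logger.info(
            "records: %d observations of %d fungal taxa on %d plant genera",
            matrix.total(),
            len(matrix.col_labels),
            len(matrix.row_labels),
        )
        emit("interaction_matrix.csv", matrix.write_csv)

        stage = "traits"
        lookup = load_exploration_lookup(cfg.exploration_types_path)
        fm = assign_exploration_types(
            matrix, lookup, on_missing="error" if cfg.strict_lookups else "drop"
        )
        emit("functional_matrix.csv", fm.write_csv)

        stage = "diversity"
        fungal_summary, fungal_t = group_fungal_diversity(matrix)
        functional_summary, functional_t = group_functional_diversity(fm)
        rows = []
        for g in matrix.row_labels:
            rows.append(
                {
                    "plant_genus": g,
                    "status": matrix.row_status[g],
                    "H_functional": functional_summary.per_genus_H[g],
                    "H_fungal": fungal_summary.per_genus_H[g],
                }
            )
        emit(
            "diversity_summary.csv",
            lambda p: pd.DataFrame(rows).to_csv(p, index=False),
        )
        ordination = pca_ordination(fm)
        score_df = pd.DataFrame(
            ordination.scores,
            columns=[f"PC{i + 1}" for i in range(ordination.scores.shape[1])],
        )
        score_df.insert(0, "plant_genus", list(ordination.row_labels))
        emit("ordination_scores.csv", lambda p: score_df.to_csv(p, index=False))
        dispersion = dispersion_test(fm, n_perm=cfg.n_perm, seed=seeds[2])
        emit(
            "dispersion.json",
            lambda p: Path(p).write_text(
                json.dumps(
                    {
                        "F": dispersion.F,
                        "df1": dispersion.df1,
                        "df2": dispersion.df2,
                        "p_parametric": dispersion.p_parametric,
                        "p_permutation": dispersion.p_permutation,
                        "n_perm": dispersion.n_perm,
                        "seed": dispersion.seed,
                        "distances": dict(dispersion.distances),
                    },
                    indent=2,
                )
            ),
        )

        stage = "nullmodels"
        fm_ensemble = sample_null(
            fm.counts,
            burn_in=cfg.burn_in,
            n_samples=cfg.n_samples,
            thin=cfg.thin,
            seed=seeds[0],
        )
        gap = diversity_gap_test(fm, fm_ensemble)
        emit("null_report.json", lambda p: write_null_report(gap, fm_ensemble, p))

        stage = "network"
        nest_ensemble = sample_null(
            matrix.counts,
            burn_in=cfg.burn_in,
            n_samples=cfg.n_samples,
            thin=cfg.thin,
            seed=seeds[1],
        )
        nest = nestedness_test(matrix, nest_ensemble, level=cfg.level)
        emit("nestedness_report.json", lambda p: write_nestedness_report(nest, p))
        graph = project_unipartite(matrix)
        partition = louvain_partition(
            graph,
            seed=seeds[3],
            n_restarts=cfg.louvain_restarts,
            include_self_loops=cfg.include_self_loops,
        )
        logger.info(
            "network: %d modules, Q = %.3f; nestedness %.3f (%s)",
            partition.n_modules,
            partition.Q,
            nest.observed,
            nest.direction,
        )
        emit("network_edges.csv", lambda p: write_edge_list_csv(graph, p))
        emit("network.graphml", lambda p: write_graphml(graph, p))
        emit("partition.csv", lambda p: write_partition_csv(graph, partition, p))
        breadth = host_breadth_summary(matrix)
        emit(
            "host_breadth.csv",
            lambda p: pd.DataFrame(
                [{"status": s, "mean_host_breadth": b} for s, b in sorted(breadth.items())]
            ).to_csv(p, index=False),
        )

        stage = "report"
        emit("resolved_config.yaml", cfg.to_yaml)
        emit(
            "run_log.json",
            lambda p: Path(p).write_text(
                json.dumps(
                    {
                        "software": f"symbionet {__version__}",
                        "seed": cfg.seed,
                        "sub_seeds": seeds,
                        "region": cfg.region,
                        "n_records_analysed": matrix.total(),
                        "n_plant_genera": len(matrix.row_labels),
                        "n_fungal_taxa": len(matrix.col_labels),
                        "modules": partition.n_modules,
                        "modularity_Q": partition.Q,
                        "nestedness": nest.observed,
                        "nestedness_direction": nest.direction,
                    },
                    indent=2,
                )
            ),
        )
        manifest = {p.name: _sha256(p) for p in written}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc

    return ReportBundle(
        output_dir=out,
        manifest=manifest,
        interaction_matrix=matrix,
        functional_matrix=fm,
        fungal_diversity=(fungal_summary, fungal_t),
        functional_diversity=(functional_summary, functional_t),
        ordination=ordination,
        dispersion=dispersion,
        gap_test=gap,
        nestedness=nest,
        graph=graph,
        partition=partition,
        host_breadth=breadth,
    )
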