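"""Pipeline orchestration: config validation, end-to-end run, report export.

The run order per transcription factor is: load inputs, stack the Boolean
gene x study matrix, compute Hamming similarity / exclusive intersections /
k-of-n consensus, classify the consensus against the deletion and
overexpression tables, then compute phase distributions, enrichment against
the genome-wide CCR baseline, functional tallies and the network export;
finally the cross-TF shared (partially) validated target set.  All report
tables are written with stable ordering, so re-running on identical inputs
yields byte-identical files.  Every computation happens in memory before
any file is written, so a failing stage leaves no partial output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Mapping

import pandas as pd
import yaml

from . import data_io
from .consensus import (
    TargetMatrix,
    build_target_matrix,
    exclusive_intersections,
    hamming_similarity,
    intersections_to_frame,
    k_of_n_consensus,
    study_totals,
)
from .data_io import DEFAULT_GROUPING, PRECALLED, PhaseAnnotation, ThresholdRule
from .enrichment import (
    PhaseDistribution,
    export_network,
    functional_tally,
    phase_distribution,
    phase_enrichment,
    shared_targets,
)
from .errors import ComputationError, ConfigError
from .validation import (
    Category,
    ResponseClass,
    classes_to_frame,
    direction_summary,
    fully_validated,
    partially_validated,
    validation_categories,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    path: Path
    threshold_rule: ThresholdRule | str = PRECALLED


@dataclass(frozen=True)
class TFSpec:
    tf: str
    studies: tuple[StudySpec, ...]
    deletion_path: Path
    overexpression_path: Path


@dataclass(frozen=True)
class PipelineConfig:
    tfs: tuple[TFSpec, ...]
    universe_path: Path
    alias_path: Path | None = None
    phase_path: Path | None = None
    terms_path: Path | None = None
    edges_path: Path | None = None
    k: int = 4
    universe_mode: Literal["genome", "union"] = "genome"
    oe_rule: Literal["final", "any"] = "final"
    deletion_cutoff: float = 1.0
    oe_cutoff: float = 1.0
    grouping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPING))
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        for tf_spec in self.tfs:
            n = len(tf_spec.studies)
            if self.k > n:
                raise ConfigError(
                    f"k={self.k} exceeds the {n} studies configured for {tf_spec.tf}"
                )
            ids = [s.study_id for s in tf_spec.studies]
            if len(set(ids)) != len(ids):
                raise ConfigError(f"duplicate study_id for {tf_spec.tf}: {ids}")


_TOP_KEYS = {
    "k", "universe_mode", "universe", "aliases", "oe_rule", "deletion_cutoff",
    "oe_cutoff", "phases", "terms", "edges", "tfs", "grouping", "out_dir",
}
_TF_KEYS = {"studies", "deletion", "overexpression"}
_STUDY_KEYS = {"study_id", "path", "score_column", "comparator", "cutoff", "precalled"}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and schema-check a YAML pipeline config; unknown keys are
    rejected and defaults (k=4, genome universe, final-point OE rule,
    cutoffs 1.0) are filled in.  Relative paths resolve against the config
    file's directory."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    base = path.parent

    def resolve(p: str | None) -> Path | None:
        return (base / p) if p is not None else None

    tf_block = raw.get("tfs")
    if not isinstance(tf_block, dict) or not tf_block:
        raise ConfigError(f"{path}: 'tfs' must map TF labels to their inputs")
    tf_specs = []
    for tf, spec in tf_block.items():
        unknown = set(spec) - _TF_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown keys under tfs.{tf}: {sorted(unknown)}")
        studies = []
        for entry in spec.get("studies", []):
            unknown = set(entry) - _STUDY_KEYS
            if unknown:
                raise ConfigError(f"{path}: unknown study keys: {sorted(unknown)}")
            if entry.get("precalled"):
                rule: ThresholdRule | str = PRECALLED
            else:
                missing = {"score_column", "comparator", "cutoff"} - set(entry)
                if missing:
                    raise ConfigError(
                        f"{path}: study {entry.get('study_id')} missing {sorted(missing)} "
                        "(or set precalled: true)"
                    )
                rule = ThresholdRule(entry["score_column"], entry["comparator"],
                                     float(entry["cutoff"]))
            studies.append(StudySpec(entry["study_id"], base / entry["path"], rule))
        for key in ("deletion", "overexpression"):
            if key not in spec:
                raise ConfigError(f"{path}: tfs.{tf} missing '{key}'")
        tf_specs.append(TFSpec(tf, tuple(studies), base / spec["deletion"],
                               base / spec["overexpression"]))

    if "universe" not in raw:
        raise ConfigError(f"{path}: missing 'universe'")
    grouping = raw.get("grouping") or dict(DEFAULT_GROUPING)
    return PipelineConfig(
        tfs=tuple(tf_specs),
        universe_path=base / raw["universe"],
        alias_path=resolve(raw.get("aliases")),
        phase_path=resolve(raw.get("phases")),
        terms_path=resolve(raw.get("terms")),
        edges_path=resolve(raw.get("edges")),
        k=int(raw.get("k", 4)),
        universe_mode=raw.get("universe_mode", "genome"),
        oe_rule=raw.get("oe_rule", "final"),
        deletion_cutoff=float(raw.get("deletion_cutoff", 1.0)),
        oe_cutoff=float(raw.get("oe_cutoff", 1.0)),
        grouping=grouping,
        out_dir=resolve(raw.get("out_dir")),
    )


@dataclass
class TFResult:
    """All per-TF pipeline outputs."""

    tf: str
    matrix: TargetMatrix
    similarity: pd.DataFrame
    intersections: pd.DataFrame
    consensus: frozenset[str]
    classes: Mapping[str, ResponseClass]
    categories: Mapping[str, Category]
    category_counts: Mapping[Category, int]
    direction_summary: pd.DataFrame
    phase_dist_partial: PhaseDistribution
    enrichment: pd.DataFrame | None
    go_tally: pd.DataFrame
    kegg_tally: pd.DataFrame

    @property
    def fully_validated(self) -> frozenset[str]:
        return fully_validated(self.categories)

    @property
    def partially_validated(self) -> frozenset[str]:
        return partially_validated(self.categories)


@dataclass
class ConsensusReport:
    """Consolidated result of one pipeline run."""

    per_tf: dict[str, TFResult]
    shared_partial: tuple[str, ...]
    shared_full: tuple[str, ...]
    baseline_dist: PhaseDistribution
    network_nodes: pd.DataFrame
    network_edges: pd.DataFrame
    metadata: dict[str, Any]

    def check_consistency(self) -> None:
        """Every reported count must be re-derivable from the report's own
        gene lists."""
        for tf, res in self.per_tf.items():
            if sum(res.category_counts.values()) != len(res.consensus):
                raise ComputationError(f"{tf}: category counts do not sum to |consensus|")
            if res.category_counts[Category.BOTH] != len(res.fully_validated):
                raise ComputationError(f"{tf}: BOTH count mismatch")
            n_union = int(res.matrix.data.any(axis=1).sum())
            if int(res.intersections["count"].sum()) != n_union:
                raise ComputationError(f"{tf}: exclusive counts do not sum to union size")
            dist = res.phase_dist_partial
            phase_total = sum(dist.counts[p] for p in data_io.PHASES)
            if phase_total != dist.n_ccr:
                raise ComputationError(f"{tf}: phase counts do not sum to CCR total")
        tfs = list(self.per_tf)
        if len(tfs) == 2:
            a, b = (self.per_tf[t] for t in tfs)
            if set(self.shared_partial) != set(a.partially_validated & b.partially_validated):
                raise ComputationError("shared (partially) validated set inconsistent")
            if set(self.shared_full) != set(a.fully_validated & b.fully_validated):
                raise ComputationError("shared fully validated set inconsistent")


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> ConsensusReport:
    """Execute the full analysis and (when ``out_dir`` is set) write all
    report tables plus ``report.json`` metadata."""
    warnings: list[str] = []

    _stage("load universe")
    universe = data_io.load_universe(config.universe_path, config.alias_path)
    logger.info("universe: %d genes, %d aliases", len(universe), len(universe.alias_map))

    phase_ann = (
        data_io.load_phase_annotation(config.phase_path, config.grouping, universe)
        if config.phase_path
        else PhaseAnnotation({}, dict(config.grouping))
    )
    ann = data_io.load_annotation_table(config.terms_path, config.edges_path, universe)

    _stage("genome-wide CCR baseline")
    baseline = phase_distribution(universe.genes, phase_ann)
    logger.info("baseline CCR fraction: %.4f (%d/%d)",
                baseline.ccr_fraction, baseline.n_ccr, baseline.n_total)

    per_tf: dict[str, TFResult] = {}
    for tf_spec in config.tfs:
        tf = tf_spec.tf
        _stage(f"{tf}: load studies")
        studies = [
            data_io.load_study_targets(s.path, s.study_id, tf, s.threshold_rule, universe)
            for s in tf_spec.studies
        ]
        for s in studies:
            logger.info("%s %s: %d targets", tf, s.study_id, len(s.targets))

        _stage(f"{tf}: consensus")
        matrix = build_target_matrix(studies, universe, config.universe_mode)
        similarity = hamming_similarity(matrix)
        intersections = exclusive_intersections(matrix)
        consensus = k_of_n_consensus(matrix, config.k)
        logger.info("%s: %d consensus targets (k=%d of %d)",
                    tf, len(consensus), config.k, len(studies))

        _stage(f"{tf}: validation")
        tables = data_io.load_validation_tables(
            tf_spec.deletion_path, tf_spec.overexpression_path,
            config.deletion_cutoff, config.oe_cutoff, universe,
        )
        classes, categories, counts = validation_categories(consensus, tables, config.oe_rule)
        dir_summary = direction_summary(categories, classes)
        partial = partially_validated(categories)
        logger.info("%s: %d (partially) validated, %d fully validated",
                    tf, len(partial), len(fully_validated(categories)))

        _stage(f"{tf}: enrichment")
        dist = phase_distribution(partial, phase_ann)
        enrich = (
            phase_enrichment(dist, baseline)
            if dist.fractions is not None and baseline.fractions is not None
            else None
        )
        if enrich is None:
            warnings.append(f"{tf}: phase enrichment skipped (no CCR genes)")
        go_tally = functional_tally(fully_validated(categories), ann, "GO_term_1")
        kegg_tally = functional_tally(partial, ann, "KEGG")

        per_tf[tf] = TFResult(
            tf, matrix, similarity, intersections, consensus, classes, categories,
            dict(counts), dir_summary, dist, enrich, go_tally, kegg_tally,
        )

    _stage("cross-TF shared targets")
    tf_names = list(per_tf)
    if len(tf_names) == 2:
        a, b = (per_tf[t] for t in tf_names)
        shared_partial = shared_targets(a.partially_validated, b.partially_validated)
        shared_full = shared_targets(a.fully_validated, b.fully_validated)
        network_genes = set(a.fully_validated) | set(b.fully_validated)
    else:
        shared_partial = shared_full = ()
        network_genes = set().union(*(r.fully_validated for r in per_tf.values()))
    nodes, edges = export_network(network_genes, ann, phase_ann, tuple(tf_names)[:2]
                                  if len(tf_names) >= 2 else ("FKH1", "FKH2"))

    metadata = {
        "k": config.k,
        "universe_mode": config.universe_mode,
        "hamming_denominator": f"{config.universe_mode} rows",
        "oe_rule": config.oe_rule,
        "deletion_cutoff": config.deletion_cutoff,
        "oe_cutoff": config.oe_cutoff,
        "n_universe": len(universe),
        "warnings": warnings,
        "per_tf": {
            tf: {
                "n_consensus": len(res.consensus),
                "n_partially_validated": len(res.partially_validated),
                "n_fully_validated": len(res.fully_validated),
                "category_counts": {c.value: res.category_counts[c] for c in Category},
                "study_totals": {s: int(n) for s, n in study_totals(res.matrix).items()},
                "ccr_in_partial": res.phase_dist_partial.n_ccr,
                "ccr_fraction_partial": res.phase_dist_partial.ccr_fraction,
            }
            for tf, res in per_tf.items()
        },
        "n_shared_partially_validated": len(shared_partial),
        "n_shared_fully_validated": len(shared_full),
        "baseline_ccr_fraction": baseline.ccr_fraction,
    }

    report = ConsensusReport(per_tf, shared_partial, shared_full, baseline,
                             nodes, edges, metadata)
    report.check_consistency()
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: ConsensusReport, out_dir: str | Path) -> None:
    """Write every report table as TSV plus metadata JSON, with stable
    ordering throughout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tf, res in report.per_tf.items():
        low = tf.lower()
        data_io.write_tsv(res.matrix.to_frame(), out / f"target_matrix_{low}.tsv")
        sim = res.similarity.round(6).reset_index(names="study")
        data_io.write_tsv(sim, out / f"hamming_similarity_{low}.tsv")
        data_io.write_tsv(intersections_to_frame(res.intersections),
                          out / f"intersections_{low}.tsv")
        data_io.write_tsv(pd.DataFrame({"gene": sorted(res.consensus)}),
                          out / f"consensus_{low}.tsv")
        data_io.write_tsv(classes_to_frame(res.categories, res.classes),
                          out / f"validation_{low}.tsv")
        counts_df = pd.DataFrame(
            [(c.value, res.category_counts[c]) for c in Category],
            columns=["category", "count"],
        )
        data_io.write_tsv(counts_df, out / f"validation_summary_{low}.tsv")
        data_io.write_tsv(res.direction_summary, out / f"direction_summary_{low}.tsv")
        data_io.write_tsv(res.phase_dist_partial.to_frame(),
                          out / f"phase_distribution_{low}.tsv")
        if res.enrichment is not None:
            data_io.write_tsv(res.enrichment.round(6), out / f"phase_enrichment_{low}.tsv")
        data_io.write_tsv(res.go_tally.round(6), out / f"go_tally_{low}.tsv")
        data_io.write_tsv(res.kegg_tally.round(6), out / f"kegg_tally_{low}.tsv")
    data_io.write_tsv(pd.DataFrame({"gene": list(report.shared_partial)}),
                      out / "shared_partially_validated.tsv")
    data_io.write_tsv(pd.DataFrame({"gene": list(report.shared_full)}),
                      out / "shared_fully_validated.tsv")
    data_io.write_tsv(report.baseline_dist.to_frame(), out / "phase_distribution_genome.tsv")
    data_io.write_tsv(report.network_nodes, out / "network_nodes.tsv")
    data_io.write_tsv(report.network_edges, out / "network_edges.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)


def check_report_dir(out_dir: str | Path) -> list[str]:
    """Re-assert internal consistency of an existing report directory.

    Returns a list of problems (empty = consistent): category counts must
    match the per-gene validation table, consensus sizes must match the
    metadata, exclusive intersection counts must sum to the union size.
    """
    out = Path(out_dir)
    problems: list[str] = []
    meta = json.loads((out / "report.json").read_text())
    for tf, stats in meta["per_tf"].items():
        low = tf.lower()
        val = pd.read_csv(out / f"validation_{low}.tsv", sep="\t")
        counts = val["category"].value_counts().to_dict()
        for cat, n in stats["category_counts"].items():
            if counts.get(cat, 0) != n:
                problems.append(f"{tf}: {cat} count {counts.get(cat, 0)} != metadata {n}")
        consensus = pd.read_csv(out / f"consensus_{low}.tsv", sep="\t")
        if len(consensus) != stats["n_consensus"]:
            problems.append(f"{tf}: consensus list length != metadata")
        inter = pd.read_csv(out / f"intersections_{low}.tsv", sep="\t")
        matrix = pd.read_csv(out / f"target_matrix_{low}.tsv", sep="\t", index_col="gene")
        if int(inter["count"].sum()) != int((matrix.sum(axis=1) > 0).sum()):
            problems.append(f"{tf}: exclusive counts do not sum to union size")
    return problems
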