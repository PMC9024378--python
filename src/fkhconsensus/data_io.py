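"""Reading, normalizing and writing the pipeline's tables.

All inputs are plain TSV (tab-separated, UTF-8, header row required, ``#``
comment lines skipped).  Gene identifiers are canonicalized to uppercase
systematic names through an alias map; names that cannot be mapped are kept
verbatim (uppercased) and logged, never dropped — the six binding studies
report a mix of standard and systematic naming conventions and silently
discarding unmapped rows would bias every downstream count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigError, FormatError, InputError

logger = logging.getLogger(__name__)

#: Cell-cycle phases of peak expression, in canonical display order.
PHASES: tuple[str, ...] = ("G1(P)", "G1", "G1/S", "S", "G2", "G2/M", "M", "M/G1")

#: Token for genes without a phase-of-peak-expression assignment.
NO_DATA = "NO_DATA"

#: Accepted spellings of the no-data token in input files (case-insensitive).
_NO_DATA_ALIASES = {"NO_DATA", "NO DATA", "NODATA", "NA", ""}

#: Default phase → temporal-group mapping: growth, genome duplication, division.
DEFAULT_GROUPING: dict[str, str] = {
    "G1(P)": "EARLY",
    "G1": "EARLY",
    "G1/S": "EARLY",
    "S": "MID",
    "G2": "LATE",
    "G2/M": "LATE",
    "M": "LATE",
    "M/G1": "LATE",
}

EDGE_TYPES = ("regulatory", "physical")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneUniverse:
    """Ordered gene universe plus a standard-name → systematic-name alias map.

    ``alias_map`` keys are stored uppercase; lookups are case-insensitive.
    Aliases may map to genes outside the universe — such mappings are flagged
    at load time but retained.
    """

    genes: tuple[str, ...]
    alias_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise InputError(f"duplicate genes in universe: {dupes[:5]}")
        object.__setattr__(self, "_gene_set", frozenset(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_set  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ThresholdRule:
    """Score filter applied to one study's table: keep rows where
    ``score_column <comparator> cutoff`` (comparator ``>=`` or ``<=``)."""

    score_column: str
    comparator: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.comparator not in (">=", "<="):
            raise ConfigError(f"comparator must be '>=' or '<=', got {self.comparator!r}")

    def passes(self, score: float) -> bool:
        return score >= self.cutoff if self.comparator == ">=" else score <= self.cutoff


#: Sentinel threshold rule for studies whose table already lists final calls.
PRECALLED = "precalled"


@dataclass(frozen=True)
class StudyDataset:
    """One binding study's Boolean target calls for one transcription factor."""

    study_id: str
    tf: str
    targets: frozenset[str]
    threshold_rule: ThresholdRule | str = PRECALLED

    def __post_init__(self) -> None:
        if not self.targets:
            logger.warning("study %s (%s): empty target set", self.study_id, self.tf)


@dataclass(frozen=True)
class ValidationTables:
    """Per-gene responses to TF deletion and to a TF-overexpression time course.

    A gene absent from a table has *no evidence* (not a zero response); the
    classifier maps absence to direction NONE.
    """

    deletion: Mapping[str, float]
    overexpression: Mapping[str, tuple[float, ...]]
    deletion_cutoff: float
    oe_cutoff: float

    def __post_init__(self) -> None:
        if self.deletion_cutoff < 0 or self.oe_cutoff < 0:
            raise ConfigError("validation cutoffs must be >= 0")
        lengths = {len(v) for v in self.overexpression.values()}
        if len(lengths) > 1:
            raise FormatError(f"ragged overexpression time courses: lengths {sorted(lengths)}")
        if lengths and min(lengths) < 1:
            raise FormatError("overexpression time courses must have >= 1 point")


@dataclass(frozen=True)
class PhaseAnnotation:
    """Gene → cell-cycle phase of peak expression (CCR genes), with a
    phase → {EARLY, MID, LATE} grouping."""

    phase_of: Mapping[str, str]
    grouping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPING))

    def __post_init__(self) -> None:
        bad = sorted({p for p in self.phase_of.values() if p not in PHASES and p != NO_DATA})
        if bad:
            raise FormatError(f"unknown phase tokens: {bad}")
        if set(self.grouping) != set(PHASES):
            raise ConfigError("grouping must cover the 8 phases exactly once")

    def phase(self, gene: str) -> str:
        """Phase for ``gene``; genes without an annotation row are NO_DATA."""
        return self.phase_of.get(gene, NO_DATA)


@dataclass(frozen=True)
class AnnotationTable:
    """Functional labels per gene (per scheme, e.g. GO_term_1 / KEGG) and
    regulatory/physical interaction edges."""

    term_of: Mapping[str, Mapping[str, frozenset[str]]]  # scheme -> gene -> labels
    edges: tuple[tuple[str, str, str, str], ...] = ()  # (source, target, type, evidence)

    def __post_init__(self) -> None:
        for src, tgt, etype, _ in self.edges:
            if etype not in EDGE_TYPES:
                raise FormatError(f"unknown edge type {etype!r} on ({src}, {tgt})")

    def labels(self, gene: str, scheme: str) -> frozenset[str]:
        return self.term_of.get(scheme, {}).get(gene, frozenset())


# ---------------------------------------------------------------------------
# gene-ID normalization
# ---------------------------------------------------------------------------

def normalize_gene_id(name: str, universe: GeneUniverse) -> str:
    """Canonicalize a raw gene label.

    Returns ``alias_map[name]`` when the (case-insensitive) alias exists,
    otherwise the uppercased, trimmed input.  Emits a log warning when the
    result is not a member of the universe.
    """
    trimmed = name.strip() if isinstance(name, str) else ""
    if not trimmed:
        raise InputError("empty or whitespace-only gene name")
    upper = trimmed.upper()
    canonical = universe.alias_map.get(upper, upper)
    if canonical not in universe:
        logger.warning("gene %r normalized to %s, absent from universe", name, canonical)
    return canonical


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_column(df: pd.DataFrame, col: str, path: str | Path) -> None:
    if col not in df.columns:
        raise FormatError(f"{path}: missing required column {col!r} (has {list(df.columns)})")


def load_study_targets(
    path: str | Path,
    study_id: str,
    tf: str,
    threshold_rule: ThresholdRule | str,
    universe: GeneUniverse,
) -> StudyDataset:
    """Load one study's target table and apply its threshold rule.

    Membership is the OR over rows: a gene with several rows (multiple peaks
    per promoter) is a target if *any* row passes.  Rows with unparsable
    scores are skipped and logged with their line number.
    """
    df = _read_tsv(path)
    _require_column(df, "gene", path)
    if threshold_rule == PRECALLED:
        genes = df["gene"].dropna()
        targets = {normalize_gene_id(g, universe) for g in genes}
        return StudyDataset(study_id, tf, frozenset(targets), PRECALLED)

    assert isinstance(threshold_rule, ThresholdRule)
    _require_column(df, threshold_rule.score_column, path)
    scores = pd.to_numeric(df[threshold_rule.score_column], errors="coerce")
    bad = scores.isna() & df[threshold_rule.score_column].notna()
    for idx in df.index[bad]:
        # +2: header line plus 1-based numbering
        logger.warning(
            "%s line %d: unparsable score %r, row skipped",
            path, idx + 2, df.at[idx, threshold_rule.score_column],
        )
    keep = df.loc[scores.notna() & scores.map(threshold_rule.passes), "gene"]
    targets = {normalize_gene_id(g, universe) for g in keep.dropna()}
    return StudyDataset(study_id, tf, frozenset(targets), threshold_rule)


def load_validation_tables(
    del_path: str | Path,
    oe_path: str | Path,
    deletion_cutoff: float,
    oe_cutoff: float,
    universe: GeneUniverse | None = None,
) -> ValidationTables:
    """Load deletion-response and overexpression time-course tables.

    Deletion table columns: ``gene``, ``score``.  Overexpression table:
    ``gene`` followed by one column per time point; all rows must have the
    same number of points (ragged rows are a format error).
    """
    def norm(g: str) -> str:
        return normalize_gene_id(g, universe) if universe is not None else g.strip().upper()

    del_df = _read_tsv(del_path)
    deletion: dict[str, float] = {}
    if not del_df.empty:
        _require_column(del_df, "gene", del_path)
        _require_column(del_df, "score", del_path)
        scores = pd.to_numeric(del_df["score"], errors="raise")
        for g, s in zip(del_df["gene"], scores):
            deletion[norm(g)] = float(s)

    oe_df = _read_tsv(oe_path)
    overexpression: dict[str, tuple[float, ...]] = {}
    if not oe_df.empty:
        _require_column(oe_df, "gene", oe_path)
        tcols = [c for c in oe_df.columns if c != "gene"]
        if not tcols:
            raise FormatError(f"{oe_path}: no time-point columns")
        values = oe_df[tcols].apply(pd.to_numeric, errors="raise")
        if values.isna().any().any():
            raise FormatError(f"{oe_path}: ragged time courses (missing values)")
        for g, row in zip(oe_df["gene"], values.itertuples(index=False)):
            overexpression[norm(g)] = tuple(float(x) for x in row)

    return ValidationTables(deletion, overexpression, deletion_cutoff, oe_cutoff)


def load_phase_annotation(
    path: str | Path,
    grouping: Mapping[str, str] | None = None,
    universe: GeneUniverse | None = None,
) -> PhaseAnnotation:
    """Load the gene → phase-of-peak-expression table (columns ``gene``,
    ``phase``).  Unknown phase strings raise a format error listing the
    offending values."""
    df = _read_tsv(path)
    phase_of: dict[str, str] = {}
    if not df.empty:
        _require_column(df, "gene", path)
        _require_column(df, "phase", path)
        unknown = []
        for g, p in zip(df["gene"], df["phase"].fillna("")):
            token = p.strip()
            if token.upper() in _NO_DATA_ALIASES:
                phase = NO_DATA
            elif token in PHASES:
                phase = token
            else:
                unknown.append(token)
                continue
            gene = normalize_gene_id(g, universe) if universe is not None else g.strip().upper()
            phase_of[gene] = phase
        if unknown:
            raise FormatError(f"{path}: unknown phase tokens: {sorted(set(unknown))}")
    return PhaseAnnotation(phase_of, dict(grouping) if grouping else dict(DEFAULT_GROUPING))


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a standard-name → systematic-name alias table (columns
    ``standard``, ``systematic``); keys uppercased."""
    df = _read_tsv(path)
    if df.empty:
        return {}
    _require_column(df, "standard", path)
    _require_column(df, "systematic", path)
    return {
        s.strip().upper(): y.strip().upper()
        for s, y in zip(df["standard"], df["systematic"])
    }


def load_universe(genes_path: str | Path, alias_path: str | Path | None = None) -> GeneUniverse:
    """Load the declared gene universe (column ``gene``) and optional aliases.

    Aliases mapping to genes absent from the universe are flagged in the log
    but kept."""
    df = _read_tsv(genes_path)
    _require_column(df, "gene", genes_path)
    genes = tuple(dict.fromkeys(g.strip().upper() for g in df["gene"].dropna()))
    alias_map = load_alias_map(alias_path) if alias_path else {}
    universe = GeneUniverse(genes, alias_map)
    for std, sys_name in alias_map.items():
        if sys_name not in universe:
            logger.warning("alias %s -> %s maps outside the universe", std, sys_name)
    return universe


def load_annotation_table(
    terms_path: str | Path | None = None,
    edges_path: str | Path | None = None,
    universe: GeneUniverse | None = None,
) -> AnnotationTable:
    """Load functional labels (columns ``gene``, ``scheme``, ``term``) and
    interaction edges (``source``, ``target``, ``type``, ``evidence``).

    Duplicate (source, target, type) triples are collapsed to the first
    occurrence and logged."""
    def norm(g: str) -> str:
        return normalize_gene_id(g, universe) if universe is not None else g.strip().upper()

    term_of: dict[str, dict[str, set[str]]] = {}
    if terms_path is not None:
        df = _read_tsv(terms_path)
        if not df.empty:
            for col in ("gene", "scheme", "term"):
                _require_column(df, col, terms_path)
            for g, scheme, term in zip(df["gene"], df["scheme"], df["term"]):
                term_of.setdefault(scheme, {}).setdefault(norm(g), set()).add(term)

    edges: list[tuple[str, str, str, str]] = []
    if edges_path is not None:
        df = _read_tsv(edges_path)
        if not df.empty:
            for col in ("source", "target", "type", "evidence"):
                _require_column(df, col, edges_path)
            seen: set[tuple[str, str, str]] = set()
            for src, tgt, etype, ev in zip(df["source"], df["target"], df["type"], df["evidence"]):
                key = (norm(src), norm(tgt), etype)
                if key in seen:
                    logger.warning("duplicate edge %s, keeping first occurrence", key)
                    continue
                seen.add(key)
                edges.append((key[0], key[1], etype, str(ev)))

    frozen = {
        scheme: {g: frozenset(ls) for g, ls in per_gene.items()}
        for scheme, per_gene in term_of.items()
    }
    return AnnotationTable(frozen, tuple(edges))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_study_targets(dataset: StudyDataset, path: str | Path) -> None:
    """Write a study's target set as a precalled one-column TSV; re-loading
    with the precalled rule round-trips the target set exactly."""
    write_tsv(pd.DataFrame({"gene": sorted(dataset.targets)}), path)
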