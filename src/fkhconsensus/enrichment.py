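"""Cell-cycle-phase distributions, enrichment, shared targets, functional
tallies and network export.

Phase fractions are computed over the cell-cycle-regulated (CCR) genes in a
set: genes without a phase-of-peak-expression assignment count toward the
CCR fraction's denominator but are excluded from phase-fraction
denominators, so the per-phase fractions describe *when* the CCR targets
peak, not how many targets are CCR.  Enrichment compares a target set's
phase distribution with a baseline distribution (by default all CCR genes
genome-wide) as plain differences and ratios; no hypothesis test is
attached because the quantities of interest are the proportions themselves.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .data_io import NO_DATA, PHASES, AnnotationTable, PhaseAnnotation
from .errors import InputError

GROUPS = ("EARLY", "MID", "LATE")
UNANNOTATED = "UNANNOTATED"


@dataclass(frozen=True)
class PhaseDistribution:
    """Phase counts and fractions for one gene set.

    ``fractions``/``group_fractions`` are None-valued when the set contains
    no CCR gene (undefined, flagged rather than silently zero).
    """

    counts: Mapping[str, int]              # 8 phases + NO_DATA
    fractions: Mapping[str, float] | None  # over the 8 phases, CCR genes only
    group_fractions: Mapping[str, float] | None
    ccr_fraction: float
    n_total: int
    n_ccr: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for phase in (*PHASES, NO_DATA):
            frac = self.fractions.get(phase) if (self.fractions and phase != NO_DATA) else None
            rows.append((phase, self.counts.get(phase, 0), frac))
        return pd.DataFrame(rows, columns=["phase", "count", "fraction"])


def phase_distribution(genes: Iterable[str], ann: PhaseAnnotation) -> PhaseDistribution:
    """Distribution of phase of peak expression over a gene set."""
    genes = sorted(set(genes))
    counts = Counter(ann.phase(g) for g in genes)
    for phase in (*PHASES, NO_DATA):
        counts.setdefault(phase, 0)
    n_total = len(genes)
    n_ccr = n_total - counts[NO_DATA]
    if n_ccr > 0:
        fractions = {p: counts[p] / n_ccr for p in PHASES}
        group_counts = Counter()
        for p in PHASES:
            group_counts[ann.grouping[p]] += counts[p]
        group_fractions = {grp: group_counts[grp] / n_ccr for grp in GROUPS}
    else:
        fractions = None
        group_fractions = None
    ccr_fraction = n_ccr / n_total if n_total else 0.0
    return PhaseDistribution(dict(counts), fractions, group_fractions, ccr_fraction, n_total, n_ccr)


def phase_enrichment(
    target_dist: PhaseDistribution,
    baseline_dist: PhaseDistribution,
) -> pd.DataFrame:
    """Per-phase and per-group over/under-representation of the target set.

    Columns: level (phase|group), name, target_fraction, baseline_fraction,
    difference (target - baseline, exact), ratio (NaN-flagged when the
    baseline fraction is 0).  Positive difference = overrepresented.
    """
    if target_dist.fractions is None or baseline_dist.fractions is None:
        raise InputError("phase enrichment undefined: a distribution has no CCR genes")
    if set(target_dist.fractions) != set(baseline_dist.fractions):
        raise InputError("mismatched phase vocabularies")
    rows = []
    for level, names, tfr, bfr in (
        ("phase", PHASES, target_dist.fractions, baseline_dist.fractions),
        ("group", GROUPS, target_dist.group_fractions, baseline_dist.group_fractions),
    ):
        for name in names:
            t, b = tfr[name], bfr[name]
            ratio = t / b if b > 0 else float("nan")
            rows.append((level, name, t, b, t - b, ratio))
    return pd.DataFrame(
        rows,
        columns=["level", "name", "target_fraction", "baseline_fraction", "difference", "ratio"],
    )


def shared_targets(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[str, ...]:
    """Genes common to both sets, sorted lexicographically."""
    return tuple(sorted(set(set_a) & set(set_b)))


def functional_tally(
    genes: Iterable[str],
    ann: AnnotationTable,
    scheme: str = "GO_term_1",
) -> pd.DataFrame:
    """Counts per functional label over a gene set.

    A gene with multiple labels increments each once; genes with no label in
    the scheme count under UNANNOTATED.  Fractions use the gene-set size as
    the denominator, so multi-labelled genes make fractions sum above 1.
    """
    genes = sorted(set(genes))
    tally: Counter = Counter()
    for g in genes:
        labels = ann.labels(g, scheme)
        if labels:
            tally.update(labels)
        else:
            tally[UNANNOTATED] += 1
    n = len(genes)
    rows = [
        (label, count, count / n if n else 0.0)
        for label, count in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["label", "count", "fraction"])


def export_network(
    genes: Iterable[str],
    ann: AnnotationTable,
    phase_ann: PhaseAnnotation,
    tfs: tuple[str, str] = ("FKH1", "FKH2"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for the target-gene interaction network.

    Nodes are the gene set plus the two TF hubs, each with its phase of peak
    expression (NO_DATA allowed), grouped by phase (canonical phase order,
    NO_DATA last) then lexicographically.  Edges are restricted to pairs
    with both endpoints in the node set.
    """
    node_set = set(genes) | set(tfs)
    phase_order = {p: i for i, p in enumerate((*PHASES, NO_DATA))}
    nodes = sorted(node_set, key=lambda g: (phase_order[phase_ann.phase(g)], g))
    node_df = pd.DataFrame(
        [(g, phase_ann.phase(g)) for g in nodes], columns=["node", "phase"]
    )
    edge_rows = [
        (src, tgt, etype, ev)
        for src, tgt, etype, ev in ann.edges
        if src in node_set and tgt in node_set
    ]
    edge_df = pd.DataFrame(edge_rows, columns=["source", "target", "type", "evidence"])
    return node_df, edge_df
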