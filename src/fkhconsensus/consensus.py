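"""Boolean gene × study target matrix and the operations over it.

Each binding study is a Boolean vector over the gene universe: TRUE where
the study calls the gene a target.  Three summaries are computed from the
stacked matrix:

* Hamming similarity — for each study pair, the fraction of genes on which
  the two Boolean vectors agree (both TRUE or both FALSE).  The value
  depends on the denominator, i.e. on whether the matrix rows span the whole
  genome or only the union of targets; the universe mode is therefore
  recorded in every report.
* Exclusive intersections (UpSet semantics) — for each non-empty subset of
  studies, the genes that are targets in exactly those studies and no
  others.  Exclusive counts partition the union of all targets.
* k-of-n consensus — genes called by at least k of the n studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_io import GeneUniverse, StudyDataset
from .errors import ComputationError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetMatrix:
    """Boolean membership matrix; rows are genes, columns are study ids."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any() or self.data.index.duplicated().any():
            raise InputError("duplicate gene rows or study columns in target matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def studies(self) -> list[str]:
        return list(self.data.columns)

    def targets_of(self, study_id: str) -> frozenset[str]:
        col = self.data[study_id]
        return frozenset(col.index[col])

    def to_frame(self) -> pd.DataFrame:
        """0/1 integer frame for TSV serialization (first column ``gene``)."""
        out = self.data.astype(int).reset_index(names="gene")
        return out


def build_target_matrix(
    studies: Sequence[StudyDataset],
    universe: GeneUniverse,
    universe_mode: Literal["genome", "union"] = "genome",
    allow_mixed_tf: bool = False,
) -> TargetMatrix:
    """Stack study target sets into a Boolean gene × study matrix.

    ``genome`` mode keeps every universe gene as a row (study genes outside
    the universe are appended and logged); ``union`` mode keeps only genes
    targeted by at least one study.  Study column order follows the input
    order; it is preserved into every downstream table.
    """
    if not studies:
        raise InputError("need at least one study")
    tfs = {s.tf for s in studies}
    if len(tfs) > 1 and not allow_mixed_tf:
        raise InputError(f"studies span multiple TFs {sorted(tfs)}; pass allow_mixed_tf=True to override")
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate study ids: {ids}")

    union: set[str] = set().union(*(s.targets for s in studies))
    if universe_mode == "genome":
        extras = sorted(union - set(universe.genes))
        if extras:
            logger.warning("appending %d study genes absent from universe: %s%s",
                           len(extras), extras[:5], "..." if len(extras) > 5 else "")
        genes = list(universe.genes) + extras
    elif universe_mode == "union":
        genes = sorted(union)
    else:
        raise InputError(f"unknown universe_mode {universe_mode!r}")

    data = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=ids)
    for s in studies:
        data.loc[list(s.targets), s.study_id] = True
    return TargetMatrix(data)


def hamming_similarity(matrix: TargetMatrix) -> pd.DataFrame:
    """Pairwise fraction of genes on which two studies agree.

    Symmetric with unit diagonal; values in [0, 1].  The denominator is the
    number of matrix rows, so genome-mode and union-mode matrices yield
    different (both legitimate) similarity values.
    """
    X = matrix.data.to_numpy(dtype=bool)
    if X.shape[0] == 0:
        raise ComputationError("cannot compute similarity over zero gene rows")
    if X.shape[1] == 1:
        sim = np.ones((1, 1))
    else:
        sim = 1.0 - squareform(pdist(X.T, metric="hamming"))
        np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.studies, columns=matrix.studies)


def exclusive_intersections(matrix: TargetMatrix) -> pd.DataFrame:
    """UpSet-style exclusive intersection table.

    One row per non-empty study subset with at least one gene belonging to
    exactly that subset.  Columns: ``subset`` (tuple of study ids in matrix
    column order), ``count``, ``genes`` (sorted tuple).  Rows are ordered by
    count descending, then subset size, then subset lexicographically, so
    output files are deterministic.
    """
    studies = matrix.studies
    df = matrix.data
    mask = df.any(axis=1)
    rows: list[dict] = []
    if mask.any():
        patterns = df.loc[mask]
        grouped = patterns.groupby(list(studies), sort=False)
        for key, sub in grouped:
            key = (key,) if len(studies) == 1 else key
            subset = tuple(s for s, flag in zip(studies, key) if flag)
            rows.append({
                "subset": subset,
                "count": len(sub),
                "genes": tuple(sorted(sub.index)),
            })
    table = pd.DataFrame(rows, columns=["subset", "count", "genes"])
    if not table.empty:
        table = (
            table.assign(_size=table["subset"].map(len))
            .sort_values(by=["count", "_size", "subset"], ascending=[False, True, True])
            .drop(columns="_size")
            .reset_index(drop=True)
        )
    n_union = int(matrix.data.any(axis=1).sum())
    if int(table["count"].sum()) != n_union:
        raise ComputationError("exclusive counts do not sum to the union size")
    return table


def study_totals(matrix: TargetMatrix) -> pd.Series:
    """Per-study target counts (the bottom-left barplot of an UpSet figure)."""
    return matrix.data.sum(axis=0).astype(int)


def k_of_n_consensus(matrix: TargetMatrix, k: int) -> frozenset[str]:
    """Genes called a target by at least ``k`` of the matrix's studies."""
    n = len(matrix.studies)
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    counts = matrix.data.sum(axis=1)
    return frozenset(counts.index[counts >= k])


def intersections_to_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Serialize an intersection table: subsets '&'-joined, genes comma-joined."""
    return pd.DataFrame({
        "subset": ["&".join(s) for s in table["subset"]],
        "count": table["count"],
        "genes": [",".join(g) for g in table["genes"]],
    })
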