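"""Target matrix construction, Hamming similarity, exclusive intersections
and k-of-n consensus, including a brute-force per-gene oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fkhconsensus.consensus import (
    TargetMatrix,
    build_target_matrix,
    exclusive_intersections,
    hamming_similarity,
    k_of_n_consensus,
    study_totals,
)
from fkhconsensus.data_io import GeneUniverse, StudyDataset
from fkhconsensus.errors import ComputationError, InputError


def make_matrix(memberships: dict[str, set[str]], genes: list[str]) -> TargetMatrix:
    data = pd.DataFrame(
        {sid: [g in members for g in genes] for sid, members in memberships.items()},
        index=pd.Index(genes, name="gene"),
    )
    return TargetMatrix(data)


# ---------------------------------------------------------------------------
# brute-force oracle: per-gene enumeration of membership patterns
# ---------------------------------------------------------------------------

def oracle_exclusive(memberships: dict[str, set[str]], genes: list[str]):
    """Enumerate each gene's membership pattern directly."""
    table: dict[tuple[str, ...], set[str]] = {}
    for g in genes:
        subset = tuple(sid for sid in memberships if g in memberships[sid])
        if subset:
            table.setdefault(subset, set()).add(g)
    return {s: frozenset(gs) for s, gs in table.items()}


def oracle_k_of_n(memberships: dict[str, set[str]], genes: list[str], k: int):
    return frozenset(
        g for g in genes if sum(g in members for members in memberships.values()) >= k
    )


class TestBuildMatrix:
    def test_genome_mode_keeps_all_universe_rows(self, universe5):
        ds = StudyDataset("A", "FKH1", frozenset({"G1"}))
        m = build_target_matrix([ds], GeneUniverse(("G1", "G2")))
        assert m.genes == ["G1", "G2"]
        assert m.data.loc["G1", "A"] and not m.data.loc["G2", "A"]

    def test_union_mode_keeps_only_targets(self, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5, universe_mode="union")
        assert m.genes == ["G1", "G2", "G3"]

    def test_gene_outside_universe_appended(self, study_pair, universe5):
        extra = StudyDataset("C", "FKH1", frozenset({"G9"}))
        m = build_target_matrix(study_pair + [extra], universe5)
        assert "G9" in m.genes

    def test_zero_studies_rejected(self, universe5):
        with pytest.raises(InputError):
            build_target_matrix([], universe5)

    def test_mixed_tf_rejected_unless_overridden(self, universe5):
        studies = [
            StudyDataset("A", "FKH1", frozenset({"G1"})),
            StudyDataset("B", "FKH2", frozenset({"G2"})),
        ]
        with pytest.raises(InputError):
            build_target_matrix(studies, universe5)
        m = build_target_matrix(studies, universe5, allow_mixed_tf=True)
        assert m.studies == ["A", "B"]


class TestHamming:
    def test_hand_enumerated_five_gene_example(self, study_pair, universe5):
        # A={G1,G2}, B={G2,G3}: agree on G2 (both true), G4, G5 (both false)
        m = build_target_matrix(study_pair, universe5)
        sim = hamming_similarity(m)
        assert sim.loc["A", "B"] == pytest.approx(3 / 5)

    def test_identical_columns_give_one(self, universe5):
        studies = [
            StudyDataset("A", "FKH1", frozenset({"G1", "G3"})),
            StudyDataset("B", "FKH1", frozenset({"G1", "G3"})),
        ]
        sim = hamming_similarity(build_target_matrix(studies, universe5))
        assert sim.loc["A", "B"] == 1.0

    def test_complementary_columns_give_zero(self, universe5):
        studies = [
            StudyDataset("A", "FKH1", frozenset()),
            StudyDataset("B", "FKH1", frozenset({"G1", "G2", "G3", "G4", "G5"})),
        ]
        sim = hamming_similarity(build_target_matrix(studies, universe5))
        assert sim.loc["A", "B"] == 0.0

    def test_symmetric_unit_diagonal(self, small_bundle):
        _, _, _, report = small_bundle
        for res in report.per_tf.values():
            sim = res.similarity
            assert np.allclose(sim.values, sim.values.T)
            assert np.allclose(np.diag(sim.values), 1.0)
            assert (sim.values >= 0).all() and (sim.values <= 1).all()

    def test_zero_rows_rejected(self):
        m = TargetMatrix(pd.DataFrame({"A": []}, index=pd.Index([], name="gene"), dtype=bool))
        with pytest.raises(ComputationError):
            hamming_similarity(m)

    def test_permutation_invariance(self, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.data.index)
        shuffled = TargetMatrix(m.data.loc[perm, ["B", "A"]])
        sim, sim2 = hamming_similarity(m), hamming_similarity(shuffled)
        assert sim.loc["A", "B"] == sim2.loc["A", "B"]

    def test_padding_universe_moves_similarity_toward_one(self, study_pair, universe5):
        base = hamming_similarity(build_target_matrix(study_pair, universe5)).loc["A", "B"]
        padded_universe = GeneUniverse(tuple(universe5.genes) + ("G6", "G7", "G8"))
        padded = hamming_similarity(
            build_target_matrix(study_pair, padded_universe)
        ).loc["A", "B"]
        assert padded > base


class TestExclusiveIntersections:
    def test_three_gene_enumeration(self, study_pair, universe5):
        table = exclusive_intersections(build_target_matrix(study_pair, universe5))
        rows = {row.subset: (row.count, row.genes) for row in table.itertuples()}
        assert rows[("A",)] == (1, ("G1",))
        assert rows[("B",)] == (1, ("G3",))
        assert rows[("A", "B")] == (1, ("G2",))

    def test_single_study_degenerate(self, universe5):
        ds = StudyDataset("A", "FKH1", frozenset({"G1", "G2", "G3"}))
        table = exclusive_intersections(build_target_matrix([ds], universe5))
        assert len(table) == 1
        assert table.loc[0, "count"] == 3

    def test_conservation_identity(self, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5)
        table = exclusive_intersections(m)
        assert int(table["count"].sum()) == 3  # |A ∪ B|

    def test_empty_intersections_omitted(self, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5)
        table = exclusive_intersections(m)
        assert all(c >= 1 for c in table["count"])

    def test_deterministic_ordering(self, small_bundle):
        _, _, _, report = small_bundle
        for res in report.per_tf.values():
            t = res.intersections
            keys = list(zip(-t["count"], t["subset"].map(len), t["subset"]))
            assert keys == sorted(keys)

    def test_study_totals(self, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5)
        assert study_totals(m).to_dict() == {"A": 2, "B": 2}


class TestKofN:
    def test_three_study_row_sum_example(self, universe5):
        studies = [
            StudyDataset("A", "FKH1", frozenset({"G1", "G2"})),
            StudyDataset("B", "FKH1", frozenset({"G2", "G3"})),
            StudyDataset("C", "FKH1", frozenset({"G1", "G2"})),
        ]
        m = build_target_matrix(studies, universe5)
        assert k_of_n_consensus(m, 2) == {"G1", "G2"}

    def test_boundaries_union_and_intersection(self, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5)
        assert k_of_n_consensus(m, 1) == {"G1", "G2", "G3"}
        assert k_of_n_consensus(m, 2) == {"G2"}

    @pytest.mark.parametrize("k", [0, 3])
    def test_k_out_of_range(self, k, study_pair, universe5):
        m = build_target_matrix(study_pair, universe5)
        with pytest.raises(InputError):
            k_of_n_consensus(m, k)


# ---------------------------------------------------------------------------
# randomized oracle equivalence and monotonicity
# ---------------------------------------------------------------------------

@st.composite
def random_memberships(draw):
    n_studies = draw(st.integers(1, 4))
    n_genes = draw(st.integers(1, 10))
    genes = [f"G{i}" for i in range(n_genes)]
    memberships = {
        f"S{j}": {g for g in genes if draw(st.booleans())}
        for j in range(n_studies)
    }
    return memberships, genes


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_memberships())
def test_oracle_equivalence(case):
    """Vectorized results match exhaustive per-gene enumeration exactly."""
    memberships, genes = case
    studies = [StudyDataset(s, "FKH1", frozenset(m)) for s, m in memberships.items()]
    matrix = build_target_matrix(studies, GeneUniverse(tuple(genes)))

    table = exclusive_intersections(matrix)
    got = {row.subset: frozenset(row.genes) for row in table.itertuples()}
    assert got == oracle_exclusive(memberships, genes)

    for k in range(1, len(studies) + 1):
        assert k_of_n_consensus(matrix, k) == oracle_k_of_n(memberships, genes, k)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(random_memberships())
def test_k_monotonicity(case):
    memberships, genes = case
    studies = [StudyDataset(s, "FKH1", frozenset(m)) for s, m in memberships.items()]
    matrix = build_target_matrix(studies, GeneUniverse(tuple(genes)))
    n = len(studies)
    sets = [k_of_n_consensus(matrix, k) for k in range(1, n + 1)]
    for smaller_k, larger_k in itertools.pairwise(sets):
        assert larger_k <= smaller_k
    assert sets[0] == frozenset().union(*memberships.values())
    assert sets[-1] == frozenset(genes) & frozenset.intersection(
        *(frozenset(m) for m in memberships.values())
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(random_memberships(), st.integers(1, 5))
def test_universe_padding_leaves_intersections_and_consensus_unchanged(case, n_pad):
    memberships, genes = case
    studies = [StudyDataset(s, "FKH1", frozenset(m)) for s, m in memberships.items()]
    small = build_target_matrix(studies, GeneUniverse(tuple(genes)))
    padded = build_target_matrix(
        studies, GeneUniverse(tuple(genes) + tuple(f"PAD{i}" for i in range(n_pad)))
    )
    t1, t2 = exclusive_intersections(small), exclusive_intersections(padded)
    assert list(t1["subset"]) == list(t2["subset"])
    assert list(t1["count"]) == list(t2["count"])
    for k in range(1, len(studies) + 1):
        assert k_of_n_consensus(small, k) == k_of_n_consensus(padded, k)
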