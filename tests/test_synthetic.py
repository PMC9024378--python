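"""Statistical and determinism contracts of the synthetic-data generator."""

import filecmp
import math

import numpy as np
import pytest

from fkhconsensus.consensus import build_target_matrix, k_of_n_consensus
from fkhconsensus.errors import ConfigError
from fkhconsensus.synthetic import (
    GeneratorConfig,
    generate_bundle,
    generate_study,
    generate_truth,
    generate_validation,
)
from fkhconsensus.validation import Category, validation_categories


class TestGeneratorConfig:
    def test_probability_bounds_checked(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(sens=1.2)

    def test_infeasible_shared_frac(self):
        # TF2 needs 100 genes outside TF1's 150-truth but only 50 exist
        with pytest.raises(ConfigError):
            GeneratorConfig(n_genes=200, n_true=150, n_true_tf2=150, shared_frac=0.0)

    def test_phase_probs_must_sum_to_one(self):
        probs = GeneratorConfig().phase_probs_target
        probs["S"] += 0.1
        with pytest.raises(ConfigError):
            GeneratorConfig(phase_probs_target=probs)


class TestTruth:
    def test_disjoint_at_zero_shared(self):
        cfg = GeneratorConfig(n_genes=100, n_true=10, n_true_tf2=None, shared_frac=0.0, seed=3)
        _, truths = generate_truth(cfg)
        assert not truths["FKH1"] & truths["FKH2"]

    def test_identical_at_full_shared(self):
        cfg = GeneratorConfig(n_genes=100, n_true=10, n_true_tf2=None, shared_frac=1.0, seed=3)
        _, truths = generate_truth(cfg)
        assert truths["FKH1"] == truths["FKH2"]

    def test_shared_count_is_ceiling(self):
        cfg = GeneratorConfig(n_genes=500, n_true=30, n_true_tf2=11, shared_frac=0.5, seed=3)
        _, truths = generate_truth(cfg)
        assert len(truths["FKH1"] & truths["FKH2"]) == math.ceil(0.5 * 11)
        assert len(truths["FKH2"]) == 11

    def test_same_seed_reproduces(self):
        cfg = GeneratorConfig(n_genes=100, n_true=10, n_true_tf2=5, seed=5)
        u1, t1 = generate_truth(cfg)
        u2, t2 = generate_truth(cfg)
        assert u1.genes == u2.genes and t1 == t2


class TestStudy:
    def test_perfect_study_recovers_truth(self):
        cfg = GeneratorConfig(n_genes=200, n_true=20, seed=2)
        universe, truths = generate_truth(cfg)
        rng = np.random.default_rng(0)
        ds = generate_study(truths["FKH1"], universe, 1.0, 0.0, rng)
        assert ds.targets == truths["FKH1"]

    def test_dead_study_is_empty(self):
        cfg = GeneratorConfig(n_genes=200, n_true=20, seed=2)
        universe, truths = generate_truth(cfg)
        ds = generate_study(truths["FKH1"], universe, 0.0, 0.0, np.random.default_rng(0))
        assert ds.targets == frozenset()

    def test_target_count_within_three_sigma(self):
        """E|targets| = m*sens + (N-m)*fpr; check the binomial bound across seeds."""
        cfg = GeneratorConfig(n_genes=1000, n_true=100, n_true_tf2=None, seed=11)
        universe, truths = generate_truth(cfg)
        m, extra = 100, len(universe) - 100
        sens, fpr = 0.9, 0.01
        expected = m * sens + extra * fpr
        sigma = math.sqrt(m * sens * (1 - sens) + extra * fpr * (1 - fpr))
        sizes = [
            len(generate_study(truths["FKH1"], universe, sens, fpr,
                               np.random.default_rng(seed)).targets)
            for seed in range(10)
        ]
        assert abs(np.mean(sizes) - expected) < 3 * sigma


class TestValidationGeneration:
    def cfg(self, **kw):
        base = dict(n_genes=300, n_true=30, n_true_tf2=None, oe_points=4, seed=9)
        base.update(kw)
        return GeneratorConfig(**base)

    def test_deterministic_responders_all_both(self):
        cfg = self.cfg(p_del=1.0, p_oe=1.0, q_del_up=1.0, q_oe_down=1.0,
                       bg_del=0.0, bg_oe=0.0, p_oe_spike=0.0)
        universe, truths = generate_truth(cfg)
        tables = generate_validation(truths["FKH1"], universe, cfg, np.random.default_rng(1))
        _, categories, _ = validation_categories(truths["FKH1"], tables)
        assert set(categories.values()) == {Category.BOTH}

    def test_zero_background_means_non_targets_neither(self):
        cfg = self.cfg(bg_del=0.0, bg_oe=0.0)
        universe, truths = generate_truth(cfg)
        tables = generate_validation(truths["FKH1"], universe, cfg, np.random.default_rng(1))
        non_targets = set(universe.genes) - truths["FKH1"]
        _, categories, _ = validation_categories(non_targets, tables)
        assert set(categories.values()) == {Category.NEITHER}

    def test_deletion_only_boundary(self):
        cfg = self.cfg(p_del=1.0, p_oe=0.0, bg_del=0.0, bg_oe=0.0)
        universe, truths = generate_truth(cfg)
        tables = generate_validation(truths["FKH1"], universe, cfg, np.random.default_rng(1))
        _, categories, _ = validation_categories(truths["FKH1"], tables)
        assert set(categories.values()) == {Category.DELETION_ONLY}

    def test_both_fraction_converges_to_p_del_times_p_oe(self):
        """Law-of-large-numbers check on the fully validated fraction."""
        cfg = GeneratorConfig(n_genes=10_000, n_true=10_000, n_true_tf2=None,
                              shared_frac=1.0, oe_points=3, bg_del=0.0, bg_oe=0.0,
                              p_del=0.6, p_oe=0.5, seed=13)
        universe, truths = generate_truth(cfg)
        tables = generate_validation(truths["FKH1"], universe, cfg, np.random.default_rng(2))
        _, categories, counts = validation_categories(truths["FKH1"], tables)
        frac = counts[Category.BOTH] / len(truths["FKH1"])
        assert abs(frac - 0.6 * 0.5) < 0.02


class TestBundle:
    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_genes=150, n_true=15, n_true_tf2=8, oe_points=3, seed=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_bundle(cfg, d1)
        m2 = generate_bundle(cfg, d2)
        assert m1 == m2
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert not mismatch and not errors

    def test_bundle_smoke_end_to_end(self, small_bundle):
        """The default-shaped bundle runs through the whole pipeline."""
        cfg, outdir, manifest, report = small_bundle
        assert set(report.per_tf) == {"FKH1", "FKH2"}
        for res in report.per_tf.values():
            assert len(res.matrix.studies) == cfg.n_studies
        assert (outdir / "manifest.json").exists()
        assert (outdir / "config.yaml").exists()

    def test_high_fidelity_studies_recover_truth_by_consensus(self):
        """sens=0.9 / fpr=0.01 over six studies: 4-of-6 consensus tracks the
        latent truth closely (Jaccard at a fixed seed)."""
        cfg = GeneratorConfig(n_genes=1000, n_true=100, n_true_tf2=None,
                              sens=0.9, fpr=0.01, seed=1)
        universe, truths = generate_truth(cfg)
        rng = np.random.default_rng(1)
        studies = [
            generate_study(truths["FKH1"], universe, 0.9, 0.01, rng, f"s{i}")
            for i in range(6)
        ]
        consensus = k_of_n_consensus(build_target_matrix(studies, universe), 4)
        truth = truths["FKH1"]
        jaccard = len(consensus & truth) / len(consensus | truth)
        assert jaccard >= 0.9
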