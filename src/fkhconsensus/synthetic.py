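"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study design end to end: a latent true-target
set per transcription factor inside a declared gene universe; six
independent binding studies that detect true targets with per-study
sensitivity and call non-targets at a false-positive rate; genome-wide
deletion scores and overexpression time courses whose threshold crossings
are conditioned on true-target status; multinomial cell-cycle-phase
assignments (target sets CCR-enriched relative to the genome); and small
functional-annotation and interaction-edge tables.

All draws flow from one ``numpy.random.default_rng(seed)`` in a documented
order — truth sets, then binding studies (TF1's studies before TF2's), then
validation tables, then phases, then annotation — so a bundle is
byte-identical across regenerations with the same seed.

The defaults describe one fixed set of study conditions: a yeast-scale
universe of 6000 genes, a large and a small true-target set (350 and 100)
overlapping in slightly more than half of the smaller set, moderately
sensitive studies with rare false positives, and perturbation response
rates under which roughly a quarter of true targets respond to both
perturbations.  Score magnitudes are drawn from the normal mixtures
recorded in the manifest; downstream logic depends only on threshold
crossings, not on those shapes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_io import NO_DATA, PHASES, GeneUniverse, StudyDataset, ValidationTables
from .errors import ConfigError

GO_CATEGORIES = ("Cell cycle", "Cell division", "Metabolism", "Signal transduction", "Other")
KEGG_PATHWAYS = ("Cell cycle - yeast", "Glycolysis", "TCA cycle", "MAPK signaling", "Autophagy")


def _default_phase_probs_target() -> dict[str, float]:
    # CCR-rich (~60%), peaking mostly in S and the late mitotic phases
    return {
        "G1(P)": 0.04, "G1": 0.06, "G1/S": 0.05, "S": 0.15,
        "G2": 0.07, "G2/M": 0.09, "M": 0.09, "M/G1": 0.05, NO_DATA: 0.40,
    }


def _default_phase_probs_genome() -> dict[str, float]:
    # non-target CCR rate 10%; with CCR-enriched targets the genome-wide
    # CCR fraction stays below the ~15% ceiling typical of whole genomes
    return {
        "G1(P)": 0.012, "G1": 0.022, "G1/S": 0.012, "S": 0.015,
        "G2": 0.008, "G2/M": 0.015, "M": 0.008, "M/G1": 0.008, NO_DATA: 0.90,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study design.

    ``n_true`` sizes TF1's latent true-target set; ``n_true_tf2`` (default:
    same) sizes TF2's.  ``shared_frac`` is the fraction of the *smaller*
    (TF2) truth set shared with TF1.  ``sens``/``fpr`` are per-study
    detection and false-call probabilities; ``p_del``/``p_oe`` the response
    probabilities of true targets to deletion/overexpression, with
    directional biases ``q_del_up`` (up upon deletion) and ``q_oe_down``
    (down at the end of overexpression); non-targets respond at the
    background rates ``bg_del``/``bg_oe``.  ``p_oe_spike`` is the chance
    that a down-responder first overshoots +cutoff, producing an
    up-then-down trajectory.
    """

    n_genes: int = 6000
    n_true: int = 350
    n_true_tf2: int | None = 100
    n_studies: int = 6
    sens: float = 0.75
    fpr: float = 0.01
    p_del: float = 0.55
    p_oe: float = 0.45
    q_del_up: float = 0.80
    q_oe_down: float = 0.90
    bg_del: float = 0.02
    bg_oe: float = 0.02
    p_oe_spike: float = 0.05
    oe_points: int = 8
    deletion_cutoff: float = 1.0
    oe_cutoff: float = 1.0
    study_score_cutoff: float = 1.0
    phase_probs_target: dict[str, float] = field(default_factory=_default_phase_probs_target)
    phase_probs_genome: dict[str, float] = field(default_factory=_default_phase_probs_genome)
    shared_frac: float = 0.55
    alias_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = dict(
            sens=self.sens, fpr=self.fpr, p_del=self.p_del, p_oe=self.p_oe,
            q_del_up=self.q_del_up, q_oe_down=self.q_oe_down,
            bg_del=self.bg_del, bg_oe=self.bg_oe, p_oe_spike=self.p_oe_spike,
            shared_frac=self.shared_frac, alias_frac=self.alias_frac,
        )
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_true > self.n_genes or self.n_true_2 > self.n_genes:
            raise ConfigError("n_true exceeds n_genes")
        if self.oe_points < 2:
            raise ConfigError("oe_points must be >= 2")
        for label, dist in (("phase_probs_target", self.phase_probs_target),
                            ("phase_probs_genome", self.phase_probs_genome)):
            if set(dist) != {*PHASES, NO_DATA}:
                raise ConfigError(f"{label} must cover the 8 phases plus {NO_DATA}")
            if abs(sum(dist.values()) - 1.0) > 1e-12:
                raise ConfigError(f"{label} probabilities must sum to 1")
        n_shared = self.n_shared
        if self.n_true_2 - n_shared > self.n_genes - self.n_true:
            raise ConfigError(
                "infeasible shared_frac: TF2 needs more genes outside the TF1 truth set "
                "than the universe provides"
            )

    @property
    def n_true_2(self) -> int:
        return self.n_true if self.n_true_tf2 is None else self.n_true_tf2

    @property
    def n_shared(self) -> int:
        return math.ceil(self.shared_frac * min(self.n_true, self.n_true_2))


def _gene_names(n: int) -> tuple[str, ...]:
    return tuple(f"G{i:06d}" for i in range(1, n + 1))


def generate_truth(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[GeneUniverse, dict[str, frozenset[str]]]:
    """Draw the universe and the two latent true-target sets.

    TF2's truth shares ``ceil(shared_frac * min(n_true, n_true_tf2))`` genes
    with TF1's; the remainder is drawn outside TF1's truth, so shared_frac=0
    gives disjoint sets and shared_frac=1 nests the smaller inside the
    larger.  A fraction of genes receives a standard-name alias, exercising
    the name-normalization path.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    truth1 = set(map(str, rng.choice(genes, size=cfg.n_true, replace=False)))
    # the TF-encoding genes are genome members too (never latent targets here)
    all_genes = genes + ("FKH1", "FKH2")
    shared = set(map(str, rng.choice(sorted(truth1), size=min(cfg.n_shared, cfg.n_true), replace=False)))
    outside = sorted(set(genes) - truth1)
    extra = set(map(str, rng.choice(outside, size=cfg.n_true_2 - len(shared), replace=False)))
    truth2 = shared | extra

    n_alias = int(round(cfg.alias_frac * cfg.n_genes))
    aliased = map(str, rng.choice(genes, size=n_alias, replace=False))
    alias_map = {f"STD{i + 1:05d}": g for i, g in enumerate(sorted(aliased))}

    universe = GeneUniverse(all_genes, alias_map)
    return universe, {"FKH1": frozenset(truth1), "FKH2": frozenset(truth2)}


def generate_study(
    truth: frozenset[str],
    universe: GeneUniverse,
    sens: float,
    fpr: float,
    rng: np.random.Generator,
    study_id: str = "study",
    tf: str = "FKH1",
) -> StudyDataset:
    """Simulate one binding study: each true target is called with
    probability ``sens``, each other gene with probability ``fpr``,
    independently across genes (draws in universe order)."""
    u = rng.random(len(universe.genes))
    targets = {
        g for g, x in zip(universe.genes, u)
        if x < (sens if g in truth else fpr)
    }
    return StudyDataset(study_id, tf, frozenset(targets))


def _study_scores(
    targets: frozenset[str],
    universe: GeneUniverse,
    cutoff: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Genome-wide score table whose threshold crossings (score >= cutoff)
    reproduce ``targets`` exactly: called genes get cutoff + |N(1, 0.5^2)|,
    uncalled genes Uniform(0, cutoff)."""
    called = np.array([g in targets for g in universe.genes])
    scores = rng.uniform(0.0, cutoff, size=len(universe.genes))
    scores[called] = cutoff + np.abs(rng.normal(1.0, 0.5, size=int(called.sum())))
    return pd.DataFrame({"gene": universe.genes, "score": np.round(scores, 4)})


def generate_validation(
    truth: frozenset[str],
    universe: GeneUniverse,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> ValidationTables:
    """Simulate genome-wide deletion scores and overexpression time courses.

    Responder magnitudes are cutoff + |N(1, 0.5^2)| with the drawn sign;
    non-responder scores are N(0, (cutoff/4)^2) (sub-threshold at 4 sigma).
    A down-responding time course crosses -cutoff at its final point and,
    with probability ``p_oe_spike``, overshoots +cutoff at an interior
    point, yielding an up-then-down trajectory.
    """
    def responder_magnitude(cutoff: float) -> float:
        return cutoff + abs(rng.normal(1.0, 0.5))

    deletion: dict[str, float] = {}
    overexpression: dict[str, tuple[float, ...]] = {}
    del_noise_sd = cfg.deletion_cutoff / 4.0
    oe_noise_sd = cfg.oe_cutoff / 4.0

    for g in universe.genes:
        is_true = g in truth
        # deletion
        p = cfg.p_del if is_true else cfg.bg_del
        if rng.random() < p:
            sign = 1.0 if rng.random() < cfg.q_del_up else -1.0
            deletion[g] = round(sign * responder_magnitude(cfg.deletion_cutoff), 4)
        else:
            deletion[g] = round(float(rng.normal(0.0, del_noise_sd)), 4)
        # overexpression
        p = cfg.p_oe if is_true else cfg.bg_oe
        course = rng.normal(0.0, oe_noise_sd, size=cfg.oe_points)
        if rng.random() < p:
            sign = -1.0 if rng.random() < cfg.q_oe_down else 1.0
            course[-1] = sign * responder_magnitude(cfg.oe_cutoff)
            if sign < 0 and cfg.oe_points >= 2 and rng.random() < cfg.p_oe_spike:
                spike_at = int(rng.integers(0, cfg.oe_points - 1))
                course[spike_at] = responder_magnitude(cfg.oe_cutoff)
        overexpression[g] = tuple(round(float(x), 4) for x in course)

    return ValidationTables(deletion, overexpression, cfg.deletion_cutoff, cfg.oe_cutoff)


def generate_phases(
    truths: Mapping[str, frozenset[str]],
    universe: GeneUniverse,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Multinomial phase per gene: true targets (either TF) draw from the
    CCR-enriched target distribution, other genes from the genome-wide one."""
    target_union = frozenset().union(*truths.values())
    cats = (*PHASES, NO_DATA)
    p_target = np.array([cfg.phase_probs_target[c] for c in cats])
    p_genome = np.array([cfg.phase_probs_genome[c] for c in cats])
    phases: dict[str, str] = {}
    for g in universe.genes:
        p = p_target if g in target_union else p_genome
        phases[g] = cats[rng.choice(len(cats), p=p)]
    return phases


def _annotation_rows(
    truths: Mapping[str, frozenset[str]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str, str]]]:
    """Functional labels for true targets and regulatory/physical edges."""
    terms: list[tuple[str, str, str]] = []
    target_union = sorted(frozenset().union(*truths.values()))
    go_p = np.array([0.25, 0.15, 0.20, 0.15, 0.25])
    kegg_p = np.array([0.30, 0.15, 0.15, 0.20, 0.20])
    for g in target_union:
        if rng.random() < 0.8:
            terms.append((g, "GO_term_1", GO_CATEGORIES[rng.choice(5, p=go_p)]))
            if rng.random() < 0.3:  # some genes carry two GO labels
                terms.append((g, "GO_term_1", GO_CATEGORIES[rng.choice(5, p=go_p)]))
        if rng.random() < 0.5:
            terms.append((g, "KEGG", KEGG_PATHWAYS[rng.choice(5, p=kegg_p)]))

    edges: list[tuple[str, str, str, str]] = []
    for tf, truth in truths.items():
        for g in sorted(truth):
            if rng.random() < 0.6:
                edges.append((tf, g, "regulatory", "synthetic-binding"))
            if rng.random() < 0.1:
                edges.append((tf, g, "physical", "synthetic-ppi"))
    return terms, edges


def generate_bundle(cfg: GeneratorConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic input bundle plus a ready pipeline config.

    Files: per-study score tables for both TFs, deletion/overexpression
    tables per TF, phase annotation (CCR genes only), universe and alias
    tables, functional terms, interaction edges, ``config.yaml`` and a
    ``manifest.json`` echoing the generator configuration and seed.
    Regeneration with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    universe, truths = generate_truth(cfg, rng)

    def tsv(df: pd.DataFrame, name: str) -> str:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        return name

    files: dict[str, object] = {}
    files["universe"] = tsv(pd.DataFrame({"gene": universe.genes}), "universe.tsv")
    alias_df = pd.DataFrame(
        sorted(universe.alias_map.items()), columns=["standard", "systematic"]
    )
    files["aliases"] = tsv(alias_df, "aliases.tsv")

    study_files: dict[str, dict[str, str]] = {}
    for tf in ("FKH1", "FKH2"):
        study_files[tf] = {}
        for i in range(1, cfg.n_studies + 1):
            sid = f"study{i}"
            ds = generate_study(truths[tf], universe, cfg.sens, cfg.fpr, rng, sid, tf)
            scores = _study_scores(ds.targets, universe, cfg.study_score_cutoff, rng)
            study_files[tf][sid] = tsv(scores, f"targets_{tf.lower()}_{sid}.tsv")
    files["studies"] = study_files

    val_files: dict[str, dict[str, str]] = {}
    for tf in ("FKH1", "FKH2"):
        tables = generate_validation(truths[tf], universe, cfg, rng)
        del_df = pd.DataFrame(
            {"gene": list(tables.deletion), "score": list(tables.deletion.values())}
        )
        oe_cols = {f"t{j + 1}": [] for j in range(cfg.oe_points)}
        for course in tables.overexpression.values():
            for j, x in enumerate(course):
                oe_cols[f"t{j + 1}"].append(x)
        oe_df = pd.DataFrame({"gene": list(tables.overexpression), **oe_cols})
        val_files[tf] = {
            "deletion": tsv(del_df, f"deletion_{tf.lower()}.tsv"),
            "overexpression": tsv(oe_df, f"overexpression_{tf.lower()}.tsv"),
        }
    files["validation"] = val_files

    phases = generate_phases(truths, universe, cfg, rng)
    ccr_rows = [(g, p) for g, p in phases.items() if p != NO_DATA]
    files["phases"] = tsv(pd.DataFrame(ccr_rows, columns=["gene", "phase"]), "phases.tsv")

    terms, edges = _annotation_rows(truths, cfg, rng)
    files["terms"] = tsv(pd.DataFrame(terms, columns=["gene", "scheme", "term"]), "terms.tsv")
    files["edges"] = tsv(
        pd.DataFrame(edges, columns=["source", "target", "type", "evidence"]), "edges.tsv"
    )

    for tf in ("FKH1", "FKH2"):
        pd.DataFrame({"gene": sorted(truths[tf])}).to_csv(
            outdir / f"truth_{tf.lower()}.tsv", sep="\t", index=False
        )

    pipeline_cfg = {
        "k": 4,
        "universe_mode": "genome",
        "universe": "universe.tsv",
        "aliases": "aliases.tsv",
        "oe_rule": "final",
        "deletion_cutoff": cfg.deletion_cutoff,
        "oe_cutoff": cfg.oe_cutoff,
        "phases": "phases.tsv",
        "terms": "terms.tsv",
        "edges": "edges.tsv",
        "tfs": {
            tf: {
                "studies": [
                    {
                        "study_id": sid,
                        "path": fname,
                        "score_column": "score",
                        "comparator": ">=",
                        "cutoff": cfg.study_score_cutoff,
                    }
                    for sid, fname in study_files[tf].items()
                ],
                "deletion": val_files[tf]["deletion"],
                "overexpression": val_files[tf]["overexpression"],
            }
            for tf in ("FKH1", "FKH2")
        },
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)

    manifest = {
        "generator": asdict(cfg),
        "seed": cfg.seed,
        "score_model": {
            "responder": "cutoff + |N(1, 0.5^2)| (signed)",
            "non_responder": "N(0, (cutoff/4)^2)",
            "study_called": "cutoff + |N(1, 0.5^2)|",
            "study_uncalled": "Uniform(0, cutoff)",
        },
        "draw_order": [
            "truth (TF1, shared, TF2 extra, aliases)",
            "studies (FKH1 study1..n then FKH2, calls then scores)",
            "validation (FKH1 then FKH2, per gene: deletion then overexpression)",
            "phases", "annotation terms", "annotation edges",
        ],
        "files": files,
        "truth_files": {tf: f"truth_{tf.lower()}.tsv" for tf in ("FKH1", "FKH2")},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
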