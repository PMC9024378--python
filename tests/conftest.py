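import pytest

from fkhconsensus.data_io import GeneUniverse, StudyDataset
from fkhconsensus.pipeline import run_pipeline, validate_config
from fkhconsensus.synthetic import GeneratorConfig, generate_bundle


@pytest.fixture
def universe5():
    return GeneUniverse(("G1", "G2", "G3", "G4", "G5"))


@pytest.fixture
def study_pair():
    """The hand-enumerated two-study example over five genes:
    A = {G1, G2}, B = {G2, G3}."""
    return [
        StudyDataset("A", "FKH1", frozenset({"G1", "G2"})),
        StudyDataset("B", "FKH1", frozenset({"G2", "G3"})),
    ]


SMALL_CFG = dict(
    n_genes=400,
    n_true=40,
    n_true_tf2=20,
    oe_points=4,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic bundle plus its pipeline report, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = GeneratorConfig(**SMALL_CFG)
    manifest = generate_bundle(cfg, outdir)
    report = run_pipeline(validate_config(outdir / "config.yaml"))
    return cfg, outdir, manifest, report
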