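import pytest
from hypothesis import HealthCheck, settings

from stuckenia import RunConfig, read_alignment, run_pipeline
from stuckenia.synthdata import build_haplotype_panel, simulate_study, write_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    """Seed-1 synthetic haplotype panel used across the suite."""
    return build_haplotype_panel(1)


@pytest.fixture(scope="session")
def key(panel):
    return panel.key


@pytest.fixture(scope="session")
def study(tmp_path_factory, panel):
    """The 28-sample study-mirror fixture plus one completed pipeline run."""
    root = tmp_path_factory.mktemp("study")
    samples, truth = simulate_study(panel, seed=1)
    fixture = write_fixture(panel, samples, truth, root / "fixture")
    config = RunConfig(
        fasta=fixture / "samples.fasta",
        metadata=fixture / "metadata.tsv",
        key=fixture / "key.yaml",
        outdir=root / "run1",
        bootstrap_replicates=100,
        seed=3,
    )
    run_pipeline(config)
    return {
        "root": root,
        "fixture": fixture,
        "run": root / "run1",
        "config": config,
        "samples": samples,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_alignment(study):
    return read_alignment(study["run"] / "alignment.fasta")
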