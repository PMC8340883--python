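import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from fibromir.simulate import SimulationParams, simulate_counts, write_fixture  # noqa: E402


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests."""
    return simulate_counts(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete on-disk fixture directory at the default study conditions."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(outdir, SimulationParams(seed=42))
    return paths


@pytest.fixture(scope="session")
def pipeline_report(fixture_dir, tmp_path_factory):
    """A full end-to-end run on the default fixture (report + output dir)."""
    from fibromir.pipeline import PipelineConfig, run_all

    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        mirna_counts=str(fixture_dir["mirna_counts"]),
        gene_counts=str(fixture_dir["gene_counts"]),
        design=str(fixture_dir["design"]),
        targets=str(fixture_dir["targets"]),
        gene_sets=str(fixture_dir["gene_sets"]),
        ppi=str(fixture_dir["ppi"]),
        gene_lengths=str(fixture_dir["gene_lengths"]),
        outdir=str(outdir),
        seed=42,
    )
    report = run_all(cfg)
    return report, outdir


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir):
    from fibromir.io import read_json
    from fibromir.simulate import SyntheticTruth

    return SyntheticTruth.from_json_dict(read_json(fixture_dir["truth"]))
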