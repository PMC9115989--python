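import pytest

from tentacle import synthio


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic dataset shared across the suite."""
    return synthio.simulate(synthio.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The same bundle written to disk once."""
    outdir = tmp_path_factory.mktemp("bundle")
    synthio.write_bundle(bundle, outdir)
    return outdir


@pytest.fixture(scope="session")
def is_fixture():
    sites, design, lengths, hits = synthio.paper_pattern_fixture()
    return {"sites": sites, "design": design,
            "scaffold_lengths": lengths, "consensus_hits": hits}
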