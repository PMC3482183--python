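import pytest

from strainsnp import TranscriptContig
from strainsnp.simulate import SimulationConfig, run_simulation


@pytest.fixture
def toy_contig():
    """17-base contig with a forward ORF at [4,15]: ATG TAC AAA TAA."""
    return TranscriptContig("c1", "GGGATGTACAAATAAGG", 4, 15, "+")


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete simulated dataset (4 strains, with errors)."""
    cfg = SimulationConfig(
        n_contigs=6,
        contig_length_range=(120, 240),
        orf_fraction=0.8,
        n_strains=4,
        poly_rate=0.01,
        fixed_diff_rate=0.005,
        mean_depth=40.0,
        base_error_rate=0.005,
        seed=42,
    )
    outdir = tmp_path_factory.mktemp("small_sim")
    result = run_simulation(cfg, outdir)
    result["config"] = cfg
    return result
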