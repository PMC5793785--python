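import numpy as np
import pytest

from uorfseqr.genome_io import GenomeSequence, TranscriptModel
from uorfseqr.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 30-gene single-species experiment with planted uORFs."""
    cfg = SimulationConfig(seed=11, n_genes=30, n_species=1)
    species, truth, gene_data = simulate_experiment(cfg)
    return cfg, species, truth, gene_data


@pytest.fixture()
def plus_model():
    """Simple + strand gene: leader 30 nt, mORF 30 nt."""
    return TranscriptModel(
        gene_id="gplus", chrom="chr1", strand="+",
        morf_start=130, morf_stop=159,
        tl_isoforms=[(100, 0.75), (110, 0.25)],
        pa_sites=[(200, 1.0)],
    )


@pytest.fixture()
def minus_model():
    """Mirror gene on the - strand with the same transcript geometry."""
    return TranscriptModel(
        gene_id="gminus", chrom="chr1", strand="-",
        morf_start=169, morf_stop=140,
        tl_isoforms=[(199, 0.75), (189, 0.25)],
        pa_sites=[(100, 1.0)],
    )


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    return {"chr1": GenomeSequence("chr1", seq)}
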