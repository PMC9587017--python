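import numpy as np
import pytest

from mirdist import SimConfig, distance_matrix, make_dataset


@pytest.fixture
def write_fasta(tmp_path):
    """Factory writing a FASTA file from (id, sequence) pairs."""

    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{i}\n{s}\n" for i, s in entries))
        return path

    return _write


@pytest.fixture(scope="session")
def sim_records():
    """A small simulated study: three seed families plus unrelated background."""
    cfgs = [
        SimConfig(n_sequences=12, length=22, divergence=0.12, seed_motif="GAGGUAG", rng_seed=11),
        SimConfig(n_sequences=3, length=22, divergence=0.15, seed_motif="GGAAUGU", rng_seed=12),
        SimConfig(n_sequences=3, length=22, divergence=0.0, seed_motif="GGAAGAC", rng_seed=13),
        SimConfig(n_sequences=40, length=22, rng_seed=14),
    ]
    return make_dataset(cfgs)


@pytest.fixture(scope="session")
def sim_jc_matrix(sim_records):
    return distance_matrix(sim_records, model="JC")


@pytest.fixture(scope="session")
def sim_k2p_matrix(sim_records):
    return distance_matrix(sim_records, model="K2P")


@pytest.fixture(scope="session")
def gamma_sample():
    """A right-skewed distance-like sample from a known gamma law."""
    return np.random.default_rng(7).gamma(shape=8.5, scale=0.21, size=4000)
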