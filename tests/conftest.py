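import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_pair():
    """A 120-kb simulated wild-type/mutant pair with planted hyper-DMRs."""
    from methdmr import SimulationConfig, simulate_pair

    config = SimulationConfig(chrom_lengths={"chr1": 120_000}, seed=11,
                              planted_per_mb=40.0)
    genome, classmap, planted, wt, mut = simulate_pair(config)
    return {"config": config, "genome": genome, "classmap": classmap,
            "planted": planted, "wt": wt, "mut": mut}


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="ref.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_name, seq in records:
                fh.write(f">{rec_name}\n{seq}\n")
        return path
    return _write
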