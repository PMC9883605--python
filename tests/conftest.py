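import numpy as np
import pytest

from squigclass.experiment import ExperimentConfig, run_species_experiment
from squigclass.signal_io import RawRead
from squigclass.simulate import SimConfig, make_genome, make_pore_model, simulate_species_reads


def random_reads(n: int, n_samples: int = 50, seed: int = 0) -> list[RawRead]:
    """Small random-but-valid reads for I/O tests."""
    rng = np.random.default_rng(seed)
    return [
        RawRead(
            read_id=f"r{i:03d}",
            raw_signal=rng.integers(-32768, 32768, size=n_samples),
            digitisation=8192.0,
            offset=float(rng.integers(-20, 20)),
            range_pA=1400.0,
            sampling_rate=4000.0,
            label=int(rng.integers(0, 2)),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def simulated_pair():
    """Two species' worth of simulated, qualified reads (small)."""
    pm_a = make_pore_model(6, 11)
    pm_b = make_pore_model(6, 22)
    genome_a = make_genome(30_000, 33)
    genome_b = make_genome(30_000, 44)
    sim = SimConfig(n_reads=10, read_length_bases=400)
    reads = simulate_species_reads(genome_a, pm_a, sim, 1, "a", 1)
    reads += simulate_species_reads(genome_b, pm_b, sim, 0, "b", 2)
    return reads


@pytest.fixture(scope="session")
def species_experiment():
    """The scaled two-species control experiment (separable species):
    1000 train + 500 test reads per class, 1000-sample segments,
    2-stage network, 5-fold CV. Shared across acceptance checks."""
    return run_species_experiment(ExperimentConfig(), seed=1)


@pytest.fixture(scope="session")
def null_experiment():
    """Same experiment with one shared genome and pore model."""
    return run_species_experiment(ExperimentConfig(null_control=True), seed=1)
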