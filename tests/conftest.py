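import numpy as np
import pytest

from sweepscan.simdata import SimulationConfig, SweepSpec, simulate, write_vcf


@pytest.fixture(scope="session")
def small_neutral_truth():
    """Small neutral two-population panel reused across tests."""
    return simulate(
        SimulationConfig(seed=101, L=300_000, mu=2e-6, rec=2e-6, split_gen=50)
    )


@pytest.fixture(scope="session")
def small_sweep_truth():
    """Small panel with a strong planted sweep at 150 kb in population 1."""
    return simulate(
        SimulationConfig(
            seed=202,
            L=300_000,
            mu=2e-6,
            rec=2e-6,
            split_gen=50,
            sweep=SweepSpec(0, 150_000, 3.0, 12, reinject_budget=50),
        )
    )


@pytest.fixture(scope="session")
def neutral_vcf(tmp_path_factory, small_neutral_truth):
    d = tmp_path_factory.mktemp("neutral")
    vcf = d / "panel.vcf"
    popmap = d / "panel.popmap.tsv"
    write_vcf(
        small_neutral_truth, vcf, popmap, groups={"pop1": "A", "pop2": "B"}
    )
    return vcf, popmap


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
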