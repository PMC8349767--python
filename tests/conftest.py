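import pytest

from nucperiod import (
    PeriodicIntensityModel,
    generate_dyad_map,
    generate_periodic_mutations,
    generate_toy_genome,
)


@pytest.fixture(scope="session")
def rot_genome_dyads():
    """A ~100 kb genome with 501 regularly spaced dyads for rotational fixtures."""
    genome = generate_toy_genome(1, 500 * 200 + 300, gc_fraction=0.4, seed=11)
    dyads = generate_dyad_map(genome, spacing_bp=200, margin_bp=80, seed=11)
    return genome, dyads


@pytest.fixture(scope="session")
def rot_mutations(rot_genome_dyads):
    """100k mutations with a strong injected 10.2 bp rotational signal."""
    genome, dyads = rot_genome_dyads
    model = PeriodicIntensityModel(period=10.2, amplitude=0.8, window_radius=73)
    return generate_periodic_mutations(genome, dyads, model, 100_000, seed=12)


@pytest.fixture(scope="session")
def small_genome_dyads():
    """A small genome/dyad map for fast per-replicate pipelines."""
    genome = generate_toy_genome(1, 50 * 160 + 200, gc_fraction=0.4, seed=21)
    dyads = generate_dyad_map(genome, spacing_bp=160, margin_bp=80, seed=21)
    return genome, dyads
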