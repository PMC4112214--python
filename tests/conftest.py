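import pytest

from kinodup.simulate import SyntheticConfig, generate_genome


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast 1-2 chromosome config for unit tests."""
    base = dict(
        n_chromosomes=2,
        n_ancestral_genes=120,
        family_size_spec={"famA": 10, "famB": 10},
        event_counts={"wgd_segmental": 2, "tandem": 3, "proximal": 3,
                      "transposed": 3, "dispersed": 3},
        block_length=3,
        expression_samples=50,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def small_genome():
    cfg = small_config(seed=11)
    genome, truth = generate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture
def study_genome():
    """The full study-condition genome: 3000 genes, 50 events per mode."""
    cfg = SyntheticConfig(seed=7)
    genome, truth = generate_genome(cfg)
    return cfg, genome, truth
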