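import numpy as np
import pytest

import generosion as g


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def hs_like_lengths():
    """A strain-HS-like ORF length inventory: 4,002 genes, gamma(shape 2)
    lengths with mean 950, rounded to codons."""
    r = np.random.default_rng(42)
    return 3 * np.maximum(3, np.rint(r.gamma(2.0, 475.0, 4002) / 3)).astype(float)


def small_erosion_config(seed, **overrides):
    """A fast, noise-free erosion setup for functional tests."""
    kwargs = dict(
        seed=seed,
        n_genes=300,
        n_neutral=150,
        mutation_budget=200,
        deletion_fraction=0.1,
        point_sub_rate_gc4=0.0,
        point_sub_rate_gc2=0.0,
    )
    kwargs.update(overrides)
    if "n_genes" in overrides and "n_neutral" not in overrides:
        kwargs["n_neutral"] = max(1, kwargs["n_genes"] // 2)
    if "mutation_budget" not in overrides:
        kwargs["mutation_budget"] = max(1, kwargs["n_neutral"])
    return g.ErosionConfig(**kwargs)


@pytest.fixture(scope="session")
def closed_loop_run():
    """One full-scale noise-free erosion + comparison: a 4,000-gene ancestor,
    1,500 neutral genes, a 3,000-event budget, 10% whole-gene deletion,
    background substitution rates zero.  Shared across closed-loop tests."""
    cfg = g.ErosionConfig(
        seed=20260,
        n_genes=4000,
        n_neutral=1500,
        mutation_budget=3000,
        deletion_fraction=0.10,
        point_sub_rate_gc4=0.0,
        point_sub_rate_gc2=0.0,
    )
    ancestral = g.generate_ancestral(cfg)
    derived, truth = g.erode(ancestral, cfg)
    catalog = [g.make_is_element(np.random.default_rng([cfg.seed, 2]))]
    result = g.compare_genomes(ancestral, derived, is_catalog=catalog)
    return cfg, ancestral, derived, truth, result
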