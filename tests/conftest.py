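import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import zwdosage as z

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_genome():
    """One default-size simulated genome: layout, depth, genotypes."""
    cfg = z.SimulationConfig(seed=1)
    layout = z.simulate_genome_layout(cfg)
    profile = z.simulate_depth_windows(layout, cfg)
    summary = z.scaffold_read_counts(profile, layout)
    genotypes = z.simulate_genotypes(layout, cfg)
    return cfg, layout, profile, summary, genotypes


@pytest.fixture(scope="session")
def genome_het(default_genome):
    cfg, layout, profile, summary, genotypes = default_genome
    filtered = z.apply_variant_filters(genotypes)
    het = z.het_rate(filtered.table, layout.scaffold_lengths().to_dict())
    return het


def expression_config(seed, regime, n_z_transcripts=250, n_a_transcripts=250,
                      **kwargs):
    """1 autosome + 1 Z scaffold (no PAR) with the given transcript counts."""
    assert n_z_transcripts == n_a_transcripts, "layout uses a shared per-scaffold count"
    return z.SimulationConfig(seed=seed, n_autosomes=1, n_z_scaffolds=1,
                              par_length=0, transcripts_per_scaffold=n_z_transcripts,
                              regime=regime, **kwargs)


@pytest.fixture(scope="session")
def nocomp_expression():
    cfg = expression_config(seed=2, regime="no_compensation")
    layout = z.simulate_genome_layout(cfg)
    expr, anc, truth = z.simulate_expression(layout, cfg)
    return cfg, expr, anc, truth


def make_expression(fpkm: pd.DataFrame, linkage: dict, sexes: dict,
                    ortholog=None) -> z.ExpressionMatrix:
    """Hand-built ExpressionMatrix for small unit tests."""
    tmeta = pd.DataFrame({
        "scaffold": "S1",
        "linkage": pd.Series(linkage),
        "ortholog": pd.Series(ortholog) if ortholog else "og_" + fpkm.index,
    }).loc[fpkm.index]
    samples = pd.DataFrame({"sex": pd.Series(sexes)}).loc[fpkm.columns]
    samples.index.name = "sample"
    return z.ExpressionMatrix(fpkm=fpkm, transcripts=tmeta, samples=samples)
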