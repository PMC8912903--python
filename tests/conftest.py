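import logging

import pytest

from retroscout import references, synthio
from retroscout.pipeline import PipelineConfig, run_pipeline

logging.disable(logging.INFO)


def small_config(**overrides) -> synthio.SynthConfig:
    """A scaled-down dataset for fast unit tests: same structure as the
    default study conditions, smaller genome and read depth."""
    kw = dict(
        seed=7,
        contig_lengths=(220_000, 160_000),
        n_families=3,
        full_per_family=2,
        partial_per_family=1,
        solo_per_family=1,
        n_clusters=2,
        sirna_reads_per_element=400,
        degradation_reads_per_element=400,
        n_gene_annotations=8,
    )
    kw.update(overrides)
    return synthio.SynthConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config()
    genome, truth = synthio.build_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def domain_models():
    return references.build_domain_models()


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run under the default study conditions (2 Mb genome,
    5 families, seed 1); shared by the acceptance-level checks."""
    return run_pipeline(PipelineConfig())
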