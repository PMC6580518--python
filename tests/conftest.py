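"""Shared fixtures: seeded synthetic datasets at two scales.

The small dataset exercises every structure cheaply; the full-scale dataset
reproduces the survey's study conditions (78 family genes as 17 triads /
7 pairs / 13 singletons, 3 + 14 duplicate pairs) and backs the
recovery-suite assertions.
"""

from __future__ import annotations

import pytest

from hsfkit.pipeline import PipelineConfig, run_pipeline
from hsfkit.simulate import GeneratorConfig, generate_proteome


def small_generator_config(seed: int = 7) -> GeneratorConfig:
    return GeneratorConfig(
        class_counts={"A": 6, "B": 3, "C": 3},
        n_triads=3, n_pairs=1, n_singletons=1,
        n_duplicate_pairs_same_chrom=0, n_duplicate_pairs_segmental=1,
        n_decoys_no_dbd=3, n_decoys_no_coil=3,
        n_orthologs=3, network_edges_total=84,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    return generate_proteome(small_generator_config())


@pytest.fixture(scope="session")
def full_dataset():
    """Study-condition dataset: 78 planted family genes plus decoys."""
    return generate_proteome(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def full_summary(full_dataset):
    """Pipeline run on the study-condition dataset (bootstrap scaled to 200
    replicates; supports are not asserted on)."""
    cfg = PipelineConfig(seed=101, bootstrap_reps=200)
    return run_pipeline(full_dataset, cfg)
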