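"""Shared fixtures.

``default_genome`` / ``run_*`` fixtures materialize the full default study
(30 age-stratified loci plus one exact-duplicate annotation) and the four
technology runs the deeper tests share; they are session-scoped because the
alignment stage dominates suite runtime.
"""

from __future__ import annotations

import pytest

from retrobench import family_synth as fs
from retrobench import pipeline as pl
from retrobench.pipeline import ExperimentConfig

#: master seed for all default-study fixtures (fixed once for the suite).
MASTER_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig(master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return fs.build_family_genome(
        seed=pl.derive_seed(default_config.master_seed, "genome")
    )


def _run(genome, config, profile):
    return pl.execute_profile(genome, profile, config)


@pytest.fixture(scope="session")
def run_illumina76se(default_genome, default_config):
    return _run(default_genome, default_config, "illumina76se")[0]


@pytest.fixture(scope="session")
def run_illumina150se(default_genome, default_config):
    return _run(default_genome, default_config, "illumina150se")[0]


@pytest.fixture(scope="session")
def run_pacbio_hifi(default_genome, default_config):
    return _run(default_genome, default_config, "pacbio_hifi")[0]


@pytest.fixture(scope="session")
def runs_pacbio_standard(default_genome, default_config):
    """Both stringency modes: [strict, lenient]."""
    return _run(default_genome, default_config, "pacbio_standard")


@pytest.fixture(scope="session")
def toy_family():
    """A small, quick 5-locus family for aligner oracle tests."""
    return fs.build_family_genome(
        n_young=2,
        n_intermediate=2,
        n_old=1,
        class_assignment=["solo_ltr", "provirus", "solo_ltr", "provirus", "solo_ltr"],
        duplicate=False,
        background_length=12_000,
        seed=7,
        solo_length=400,
        provirus_length=1200,
        min_flank=100,
    )
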