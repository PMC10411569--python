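"""Shared fixtures: the default synthetic experiment is simulated once per
session and its full pipeline run shared by every test that inspects it."""

from __future__ import annotations

import numpy as np
import pytest

from denovotx.pipeline import run_all
from denovotx.screen import HomologySearcher, ScreenDatabases
from denovotx.simulate import OutgroupSpec, SimPlan, simulate_dataset

DEFAULT_SEED = 0


def small_plan(seed: int = 5, **overrides) -> SimPlan:
    """A scaled-down plan for tests that exercise mechanics, not recovery."""
    kwargs = dict(
        genome_length_per_chrom=220_000,
        n_genes=20,
        class_counts={
            "true_denovo": 3,
            "annotated_copy": 2,
            "te_copy": 2,
            "intronic": 2,
            "near_exon": 2,
            "short": 2,
            "low_expression": 2,
            "outgroup_shared": 2,
            "unplaced": 2,
        },
        n_intron_hosts=2,
        n_libraries=4,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimPlan(**kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimPlan(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_databases(default_dataset):
    ds = default_dataset
    return ScreenDatabases.build(
        ds.annotation_dbs, ds.outgroup_tx_dbs, ds.focal_genome, k=11
    )


@pytest.fixture(scope="session")
def shared_searcher():
    return HomologySearcher()


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, default_databases, shared_searcher):
    """One full default-plan pipeline run, with outputs on disk."""
    outdir = tmp_path_factory.mktemp("run_default")
    return run_all(
        {"seed": DEFAULT_SEED},
        output_dir=outdir,
        searcher=shared_searcher,
        databases=default_databases,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def identity_outgroup_dataset():
    """Default-size world with a single zero-divergence outgroup and no
    synteny breaks: every candidate region is bytewise present."""
    plan = SimPlan(
        seed=DEFAULT_SEED,
        outgroups=(OutgroupSpec("identical", 0.0, 0.0),),
        synteny_break_fraction=0.0,
    )
    return simulate_dataset(plan)
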