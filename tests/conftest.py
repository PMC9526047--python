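"""Shared fixtures: simulated datasets at the study conditions.

The heavy end-to-end fixtures are session-scoped so the recovery,
redundancy-grid and missingness checks share one simulation per seed.
"""

from __future__ import annotations

import pytest

from haploqc import kmers, pipeline, simdata, specmodel

STUDY_K = 21
STUDY_SEEDS = (1, 2, 3)
REDUNDANCY_GRID = (0.0, 0.25, 0.5, 1.0)


@pytest.fixture(scope="session")
def study_runs():
    """End-to-end runs at the study conditions (500 kb diploid, r = 0.011,
    25x per-haplotype coverage, 1% substitution error, k = 21), one per seed."""
    runs = []
    for seed in STUDY_SEEDS:
        config = simdata.SimConfig(seed=seed)
        bundle = pipeline.simulate_bundle(config)
        read_table = kmers.count_kmers([r.seq for r in bundle.reads], STUDY_K)
        hist = kmers.histogram(read_table)
        fit = specmodel.fit_spectrum(hist)
        runs.append({"config": config, "bundle": bundle, "read_table": read_table,
                     "hist": hist, "fit": fit})
    return runs


@pytest.fixture(scope="session")
def redundancy_reports(study_runs):
    """Assessment reports across the redundancy grid, sharing the seed-1 reads
    and model fit (the genome and read set do not depend on f)."""
    run = study_runs[0]
    bundle = run["bundle"]
    reports = {}
    for f in REDUNDANCY_GRID:
        contigs, truth = simdata.make_assembly(
            bundle.diploid.hap1, bundle.diploid.hap2, f,
            run["config"].n_primary_contigs, seed=run["config"].seed + 1000)
        asm_table = kmers.count_kmers([c.seq for c in contigs], STUDY_K)
        report = pipeline.assess_counts(run["read_table"], asm_table, fit=run["fit"])
        reports[f] = (report, truth)
    return reports


@pytest.fixture(scope="session")
def small_bundle():
    """A light diploid dataset for unit-level pipeline and format tests."""
    config = simdata.SimConfig(genome_length=60_000, per_hap_coverage=20.0,
                               n_primary_contigs=3, seed=7)
    return pipeline.simulate_bundle(config)
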