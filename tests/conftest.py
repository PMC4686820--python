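"""Shared fixtures: synthetic cohorts at two scales.

``cohort`` is the full-scale default study (30 samples, ~3,000 mutations
each, 800 Mb genome) run once per session through simulation, annotation,
NMD partitioning, the multi-restart ARD-NMF fit and per-mutation
assignment.  ``tiny_cohort`` is a fast small-genome cohort for unit tests
that only need realistic tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from aidsig import (annotate_context, assignment_table, build_matrix,
                    classify_clonality, compute_nmd, empirical_spectra,
                    fit_restarts, match_signatures, partition, read_genes,
                    read_mutations)
from aidsig.simulate import SimulationConfig, simulate_cohort


@dataclass
class Cohort:
    config: SimulationConfig
    paths: object
    mutations: pd.DataFrame      # annotated + nmd + stratum
    matrix: object               # StratifiedCountMatrix
    samples: list[str]
    truth: pd.DataFrame
    genes: pd.DataFrame
    metadata: pd.DataFrame
    exposures: pd.DataFrame
    model: object = None
    restarts: pd.DataFrame | None = None
    assignments: pd.DataFrame | None = None


def _build_cohort(config: SimulationConfig, out_dir: Path,
                  fit: bool, n_restarts: int = 20,
                  fit_seed: int = 11) -> Cohort:
    paths = simulate_cohort(config, out_dir)
    truth = pd.read_csv(paths.truth, sep="\t",
                        dtype={"sample": str, "chrom": str})
    muts = read_mutations(paths.mutations)
    muts = annotate_context(muts, paths.fasta)
    muts = partition(compute_nmd(muts))
    samples = sorted(muts["sample"].unique())
    matrix = build_matrix(muts, samples)
    cohort = Cohort(
        config=config, paths=paths, mutations=muts, matrix=matrix,
        samples=samples, truth=truth,
        genes=read_genes(paths.genes_bed),
        metadata=pd.read_csv(paths.metadata, sep="\t"),
        exposures=pd.read_csv(paths.exposures, sep="\t"))
    if fit:
        model, restarts = fit_restarts(
            matrix.counts, K0=20, n_restarts=n_restarts, seed0=fit_seed,
            column_labels=matrix.column_labels)
        names, _ = match_signatures(model.W, empirical_spectra(truth))
        model.rename(names)
        table = assignment_table(muts, model, matrix)
        table["clonality"] = classify_clonality(
            table["ccf"].to_numpy(), table["pr_ccf_ge_095"].to_numpy())
        cohort.model = model
        cohort.restarts = restarts
        cohort.assignments = table
    return cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory) -> Cohort:
    """Full default study conditions; fitted with 20 restarts at K0=20."""
    out = tmp_path_factory.mktemp("cohort_default")
    return _build_cohort(SimulationConfig(seed=101), out, fit=True)


TINY = dict(n_contigs=2, contig_length=3_000_000, n_genes=150,
            gene_length_min=4_000, gene_length_max=12_000,
            n_target_genes=5, n_samples=6,
            mean_mutations_younger=1200, mean_mutations_older=1500,
            n_older=3, n_ighv_mutated=4)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory) -> Cohort:
    """Small-genome cohort (fast); fitted with 6 restarts at K0=12."""
    out = tmp_path_factory.mktemp("cohort_tiny")
    config = SimulationConfig(seed=7, **TINY)
    paths = simulate_cohort(config, out)
    truth = pd.read_csv(paths.truth, sep="\t",
                        dtype={"sample": str, "chrom": str})
    muts = read_mutations(paths.mutations)
    muts = annotate_context(muts, paths.fasta)
    muts = partition(compute_nmd(muts))
    samples = sorted(muts["sample"].unique())
    matrix = build_matrix(muts, samples)
    model, restarts = fit_restarts(matrix.counts, K0=12, n_restarts=6,
                                   seed0=3, column_labels=matrix.column_labels)
    names, _ = match_signatures(model.W, empirical_spectra(truth))
    model.rename(names)
    table = assignment_table(muts, model, matrix)
    table["clonality"] = classify_clonality(
        table["ccf"].to_numpy(), table["pr_ccf_ge_095"].to_numpy())
    return Cohort(config=config, paths=paths, mutations=muts, matrix=matrix,
                  samples=samples, truth=truth,
                  genes=read_genes(paths.genes_bed),
                  metadata=pd.read_csv(paths.metadata, sep="\t"),
                  exposures=pd.read_csv(paths.exposures, sep="\t"),
                  model=model, restarts=restarts, assignments=table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
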