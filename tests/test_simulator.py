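"""Synthetic cohort generator: determinism, motif fidelity, ground truth."""

import re

import numpy as np
import pandas as pd
import pytest

from aidsig import CHANNEL_LABELS, empirical_spectra, truth_evaluate
from aidsig.simulate import (SimulationConfig, simulate_cohort,
                             simulate_genome, simulate_mutations)

SMALL = dict(n_contigs=2, contig_length=2_000_000, n_genes=100,
             gene_length_min=4_000, gene_length_max=10_000,
             n_target_genes=4, n_samples=4, mean_mutations_younger=600,
             mean_mutations_older=700, n_older=2, n_ighv_mutated=3)


def test_deterministic_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=5, **SMALL)
    p1 = simulate_cohort(cfg, tmp_path / "a")
    p2 = simulate_cohort(cfg, tmp_path / "b")
    assert p1.fasta.read_bytes() == p2.fasta.read_bytes()
    assert p1.mutations.read_bytes() == p2.mutations.read_bytes()
    assert p1.truth.read_bytes() == p2.truth.read_bytes()


def test_gene_count_and_gc_content(tmp_path):
    cfg = SimulationConfig(seed=2, n_contigs=1, contig_length=10_000_000,
                           n_genes=200, gene_length_min=4_000,
                           gene_length_max=10_000, n_target_genes=5)
    gen = simulate_genome(cfg, out_dir=tmp_path)
    bed = pd.read_csv(gen.bed_path, sep="\t", header=None)
    assert len(bed) == 200
    # non-overlapping footprints
    assert (bed[1].iloc[1:].to_numpy() >= bed[2].iloc[:-1].to_numpy()).all()
    codes = gen.codes["chr1"]
    gc = ((codes == 1) | (codes == 2)).mean()
    assert abs(gc - cfg.gc_fraction) < 0.01
    # target genes come from the top expression quartile
    q3 = gen.genes["expression"].quantile(0.75)
    assert (gen.genes.loc[gen.genes["is_target"], "expression"] >= q3).all()
    assert gen.genes["is_target"].sum() == 5


def test_zero_genes_valid_empty_bed(tmp_path):
    cfg = SimulationConfig(seed=2, n_contigs=1, contig_length=1_000_000,
                           n_genes=0, n_target_genes=0)
    gen = simulate_genome(cfg, out_dir=tmp_path)
    assert gen.bed_path.read_text() == ""
    assert len(gen.genes) == 0


@pytest.fixture(scope="module")
def small_sim(tmp_path_factory):
    cfg = SimulationConfig(seed=9, **SMALL)
    gen = simulate_genome(cfg)
    muts, truth, meta, expo = simulate_mutations(cfg, gen)
    return cfg, gen, muts, truth, meta, expo


def _base(gen, chrom, pos1):
    return "ACGT"[gen.codes[chrom][pos1 - 1]]


def test_process_motif_fidelity(small_sim):
    cfg, gen, muts, truth, _, _ = small_sim
    joined = muts.assign(process=truth["process"])
    for row in joined.itertuples():
        c = gen.codes[row.chrom]
        p = row.pos - 1
        tri = "".join("ACGT"[b] for b in c[p - 2:p + 3])
        if row.process == "ageing":
            # CpG-context C on either strand
            assert (row.ref == "C" and tri[3] == "G") or \
                   (row.ref == "G" and tri[1] == "C")
        elif row.process == "nc-AID":
            assert (row.ref == "A" and tri[1] in "AT") or \
                   (row.ref == "T" and tri[3] in "AT")
        else:  # c-AID: WRCY on either strand
            assert (row.ref == "C" and tri[0] in "AT" and tri[1] in "AG"
                    and tri[3] in "CT") or \
                   (row.ref == "G" and tri[4] in "AT" and tri[3] in "CT"
                    and tri[1] in "AG")


def test_caid_mutations_inside_target_tss_windows(small_sim):
    cfg, gen, muts, truth, _, _ = small_sim
    caid = muts[truth["process"] == "c-AID"]
    tss = gen.genes.set_index("gene_id")["tss"]
    chrom_of = gen.genes.set_index("gene_id")["chrom"]
    assert (caid["gene"] != "").all()
    for row in caid.itertuples():
        assert row.chrom == chrom_of[row.gene]
        assert abs(row.pos - tss[row.gene]) <= cfg.tss_window


def test_no_position_reused_within_sample(small_sim):
    _, _, muts, _, _, _ = small_sim
    assert not muts.duplicated(["sample", "chrom", "pos"]).any()


def test_generating_spectra_mass_on_intended_channels(small_sim):
    _, _, _, truth, _, _ = small_sim
    spectra = empirical_spectra(truth)
    ageing_channels = [i for i, lab in enumerate(CHANNEL_LABELS)
                       if re.fullmatch(r".\[C>T\]G", lab)]
    assert spectra["ageing"].iloc[ageing_channels].sum() >= 0.95
    ncaid_channels = [i for i, lab in enumerate(CHANNEL_LABELS)
                      if re.fullmatch(r".\[T>G\][AT]", lab)]
    assert spectra["nc-AID"].iloc[ncaid_channels].sum() >= 0.95
    caid_channels = [i for i, lab in enumerate(CHANNEL_LABELS)
                     if re.fullmatch(r"[AG]\[C>[TG]\][CT]", lab)]
    assert spectra["c-AID"].iloc[caid_channels].sum() >= 0.95


def test_exposures_sum_to_sample_totals(small_sim):
    _, _, muts, truth, _, expo = small_sim
    per_sample = truth.groupby(["sample", "process"]).size().unstack(
        fill_value=0)
    for row in expo.itertuples():
        assert per_sample.loc[row.sample, "ageing"] == row.n_ageing
        assert per_sample.loc[row.sample, "c-AID"] == row.n_caid
        assert per_sample.loc[row.sample, "nc-AID"] == row.n_ncaid


def test_ccf_draws_respect_clonality_intent(small_sim):
    _, _, muts, truth, _, _ = small_sim
    joined = muts.assign(intent=truth["clonality_true"])
    clonal = joined[joined["intent"] == "clonal"]
    sub = joined[joined["intent"] == "subclonal"]
    assert (clonal["ccf"] >= 0.9).all() and (clonal["pr_ccf_ge_095"] >= 0.5).all()
    assert (sub["ccf"] <= 0.7).all() and (sub["pr_ccf_ge_095"] < 0.5).all()


def test_truth_evaluate_identity_confusion(small_sim):
    _, _, muts, truth, _, _ = small_sim
    table = muts.merge(truth[["sample", "chrom", "pos", "process"]],
                       on=["sample", "chrom", "pos"])
    table["assigned_0.75"] = table["process"]
    table = table.drop(columns="process")
    rep = truth_evaluate(table, truth)
    assert rep["accuracy"] == 1.0
    conf = rep["confusion"]
    assert (conf.to_numpy().sum() == np.trace(
        conf.reindex(index=conf.columns, columns=conf.columns,
                     fill_value=0).to_numpy()))


def test_dispersed_only_cohort_has_no_excess_clustering(cohort):
    """At the default density, mutations from the dispersed processes fall
    within 1 kb of a neighbour less than 1% of the time."""
    truth = cohort.truth
    strata = cohort.mutations["stratum"].to_numpy()
    dispersed = truth["process"].isin(["ageing", "nc-AID"]).to_numpy()
    frac = (strata[dispersed] == "clustered").mean()
    assert frac < 0.01
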