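"""File-level orchestration of the analysis stages.

Each stage reads the previous stage's TSV artifacts from a working
directory and writes its own, so every stage is runnable in isolation;
``run_all`` chains them.  A manifest (config echo, seeds, row counts) is
written per stage.  The thin command-line layer in :mod:`aidsig.cli`
dispatches here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from . import io as aio
from . import ardnmf, assignment, clonality, enrichment, nmd
from .nmd import StratifiedCountMatrix, CLUSTERED, NON_CLUSTERED
from .simulate import SimulationConfig, simulate_cohort, empirical_spectra

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "aidsig_out"
    mutations: str | None = None
    mutation_format: str = "maf_tsv"
    genome: str | None = None
    genes: str | None = None
    expression: str | None = None
    metadata: str | None = None
    reference_spectra: str | None = None
    contigs: list[str] | None = None
    nmd_threshold: int = 1000
    k0: int = 20
    a: float = 10.0
    b: float | None = None
    tol: float = 1e-7
    max_iter: int = 10_000
    prune_frac: float = 1e-3
    n_restarts: int = 50
    seed: int = 0
    pms_thresholds: tuple = (0.5, 0.75)
    q_cutoff: float = 0.1
    tss_window: int = 2000
    min_mut: int = 5
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hyper(self) -> ardnmf.ARDHyper:
        return ardnmf.ARDHyper(a=self.a, b=self.b, tol=self.tol,
                               max_iter=self.max_iter,
                               prune_frac=self.prune_frac)

    def workdir(self) -> Path:
        p = Path(self.out_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def _manifest(cfg: PipelineConfig, stage: str, **info) -> None:
    path = cfg.workdir() / "manifest.json"
    data = json.loads(path.read_text()) if path.exists() else {}
    entry = {"config": {k: v for k, v in asdict(cfg).items()
                        if not isinstance(v, dict)}}
    entry.update(info)
    data[stage] = entry
    path.write_text(json.dumps(data, indent=2, default=str))


def _require(path, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise FileNotFoundError(f"missing input for this stage: {what} "
                                f"({path})")
    return Path(path)


def run_simulate(cfg: PipelineConfig) -> Path:
    sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.sim)
    out = cfg.workdir()
    paths = simulate_cohort(sim_cfg, out)
    truth = pd.read_csv(paths.truth, sep="\t")
    empirical_spectra(truth).to_csv(out / "spectra_truth.tsv", sep="\t",
                                    index_label="channel")
    cfg.mutations = str(paths.mutations)
    cfg.genome = str(paths.fasta)
    cfg.genes = str(paths.genes_bed)
    cfg.metadata = str(paths.metadata)
    if cfg.reference_spectra is None:
        cfg.reference_spectra = str(out / "spectra_truth.tsv")
    _manifest(cfg, "simulate", n_mutations=int(len(truth)),
              seed=sim_cfg.seed)
    return out


def run_annotate(cfg: PipelineConfig) -> Path:
    out = cfg.workdir()
    muts_path = _require(cfg.mutations, "mutation table")
    genome = _require(cfg.genome, "reference genome FASTA")
    muts = aio.read_mutations(muts_path, fmt=cfg.mutation_format,
                              contigs=cfg.contigs)
    muts = aio.annotate_context(muts, genome)
    aio.write_table(muts, out / "annotated.tsv")
    _manifest(cfg, "annotate", n_mutations=int(len(muts)),
              excluded=muts.attrs.get("excluded", {}))
    return out / "annotated.tsv"


def run_partition(cfg: PipelineConfig) -> Path:
    out = cfg.workdir()
    path = _require(out / "annotated.tsv", "annotated mutation table")
    muts = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    muts = nmd.compute_nmd(muts)
    muts = nmd.partition(muts, threshold_nt=cfg.nmd_threshold)
    aio.write_table(muts, out / "partitioned.tsv")
    samples = sorted(muts["sample"].unique())
    matrix = nmd.build_matrix(muts, samples)
    matrix.to_frame().to_csv(out / "count_matrix.tsv", sep="\t",
                             index_label="channel")
    nmd.spectrum_compare(matrix).to_csv(out / "spectrum_compare.tsv",
                                        sep="\t", index_label="channel")
    frac = float((muts["stratum"] == CLUSTERED).mean()) if len(muts) else 0.0
    _manifest(cfg, "partition", clustered_fraction=frac,
              n_columns=matrix.counts.shape[1])
    return out / "count_matrix.tsv"


def _load_matrix(path) -> StratifiedCountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta = []
    for col in frame.columns:
        sample, stratum = col.rsplit("__", 1)
        meta.append((sample, CLUSTERED if stratum == "clustered"
                     else NON_CLUSTERED))
    return StratifiedCountMatrix(counts=frame.to_numpy(dtype=np.int64),
                                 column_meta=meta,
                                 channel_labels=list(frame.index))


def run_decompose(cfg: PipelineConfig):
    out = cfg.workdir()
    path = _require(out / "count_matrix.tsv", "stratified count matrix")
    matrix = _load_matrix(path)
    model, restarts = ardnmf.fit_restarts(
        matrix.counts, K0=cfg.k0, hyper=cfg.hyper(),
        n_restarts=cfg.n_restarts, seed0=cfg.seed,
        column_labels=matrix.column_labels)
    if cfg.reference_spectra and Path(cfg.reference_spectra).exists():
        ref = pd.read_csv(cfg.reference_spectra, sep="\t", index_col=0)
        names, cosines = ardnmf.match_signatures(model.W, ref)
        # disambiguate duplicate "other" labels
        seen: dict[str, int] = {}
        uniq = []
        for nm in names:
            seen[nm] = seen.get(nm, 0) + 1
            uniq.append(nm if seen[nm] == 1 else f"{nm}{seen[nm]}")
        model.rename(uniq)
    aio.write_matrix(model.W, matrix.channel_labels, model.signature_names,
                     out / "W.tsv")
    aio.write_matrix(model.H, model.signature_names, matrix.column_labels,
                     out / "H.tsv")
    restarts.to_csv(out / "restarts.tsv", sep="\t", index=False)
    _manifest(cfg, "decompose", K=model.K,
              modal_k_count=int((restarts["K"] == model.K).sum()),
              log_posterior=model.log_posterior, seed0=cfg.seed)
    return model, restarts


def _load_model(out: Path) -> tuple[ardnmf.SignatureModel, StratifiedCountMatrix]:
    W = pd.read_csv(_require(out / "W.tsv", "signature matrix W"),
                    sep="\t", index_col=0)
    H = pd.read_csv(_require(out / "H.tsv", "activity matrix H"),
                    sep="\t", index_col=0)
    matrix = _load_matrix(_require(out / "count_matrix.tsv", "count matrix"))
    K = W.shape[1]
    model = ardnmf.SignatureModel(
        W_raw=W.to_numpy(), H_raw=H.to_numpy(),
        relevance=np.ones(K), active=np.ones(K, dtype=bool), K=K,
        W=W.to_numpy(), H=H.to_numpy(), log_posterior=float("nan"),
        seed=-1, n_iter=0, converged=True,
        column_labels=list(H.columns),
        signature_names=list(W.columns))
    return model, matrix


def run_assign(cfg: PipelineConfig) -> Path:
    out = cfg.workdir()
    model, matrix = _load_model(out)
    muts = pd.read_csv(_require(out / "partitioned.tsv",
                                "partitioned mutation table"),
                       sep="\t", dtype={"sample": str, "chrom": str})
    table = assignment.assignment_table(muts, model, matrix,
                                        thresholds=cfg.pms_thresholds)
    if table["ccf"].notna().any():
        table["clonality"] = clonality.classify_clonality(
            table["ccf"].to_numpy(), table["pr_ccf_ge_095"].to_numpy())
    aio.write_table(table, out / "assignments.tsv")
    label = f"assigned_{max(cfg.pms_thresholds):g}"
    _manifest(cfg, "assign",
              n_assigned=int((table[label] != "unassigned").sum()))
    return out / "assignments.tsv"


def _signature_names(table: pd.DataFrame) -> list[str]:
    return [c[2:] for c in table.columns if c.startswith("p_")]


def run_enrich(cfg: PipelineConfig) -> Path:
    out = cfg.workdir()
    table = pd.read_csv(_require(out / "assignments.tsv", "assignment table"),
                        sep="\t", dtype={"sample": str, "chrom": str})
    genes = aio.read_genes(_require(cfg.genes, "gene annotation BED"))
    if cfg.expression:
        expr = aio.read_expression(cfg.expression)
        genes = genes.drop(columns=["expression"]).merge(expr, on="gene_id",
                                                         how="left")
    genome = pyfaidx.Fasta(str(_require(cfg.genome, "reference genome")),
                           as_raw=True, sequence_always_upper=True)
    label = f"assigned_{max(cfg.pms_thresholds):g}"
    sigs = _signature_names(table)
    aid_sigs = [s for s in sigs if s in ("c-AID", "nc-AID")] or sigs
    W = pd.read_csv(out / "W.tsv", sep="\t", index_col=0)
    motifs = enrichment.hotspot_motifs(table, label, aid_sigs,
                                       W=W.to_numpy(),
                                       signature_names=list(W.columns))
    motif_rows = [(s, c, enrichment.CHANNEL_LABELS[c], m.quintile_cut)
                  for s, m in motifs.items() for c in sorted(m.channels)]
    pd.DataFrame(motif_rows, columns=["signature", "channel", "label",
                                      "quintile_cut"]).to_csv(
        out / "hotspot_motifs.tsv", sep="\t", index=False)
    info = {}
    for sig in aid_sigs:
        if not motifs[sig].channels:
            continue
        res = enrichment.gene_enrichment(sig, motifs[sig], table, label,
                                         genes, genome, q_cutoff=cfg.q_cutoff)
        safe = sig.replace("-", "").lower()
        aio.write_table(res, out / f"gene_enrichment_{safe}.tsv")
        bg = res.attrs["background"]
        info[sig] = {"r_per_mb": bg.per_mb, "n_universe": len(bg.universe),
                     "n_significant": int(res["significant"].sum())}
    contig_lengths = {name: len(genome[name]) for name in genome.keys()}
    genome_size = int(sum(contig_lengths.values()))
    tss = enrichment.tss_enrichment(table, label, genes, genome_size, sigs,
                                    window=cfg.tss_window,
                                    contig_lengths=contig_lengths)
    tss.to_frame().to_csv(out / "tss_enrichment.tsv", sep="\t",
                          index_label="signature")
    if genes["expression"].notna().any():
        quart = enrichment.expression_quartile_density(table, label, genes,
                                                       sigs)
        quart.to_csv(out / "expression_quartiles.tsv", sep="\t",
                     index_label="signature")
    _manifest(cfg, "enrich", **info)
    return out / "hotspot_motifs.tsv"


def run_clonality(cfg: PipelineConfig) -> Path:
    out = cfg.workdir()
    table = pd.read_csv(_require(out / "assignments.tsv", "assignment table"),
                        sep="\t", dtype={"sample": str, "chrom": str})
    if "clonality" not in table.columns:
        raise ValueError("assignment table lacks clonality (no CCF input)")
    sigs = _signature_names(table)
    label = f"assigned_{max(cfg.pms_thresholds):g}"
    tab, chi2, p, fisher = clonality.signature_clonality_association(
        table, label, signatures=sigs)
    tab.to_csv(out / "clonality_contingency.tsv", sep="\t")
    fisher.to_csv(out / "clonality_fisher.tsv", sep="\t", index=False)
    clonality.ccf_distribution(table, label, signatures=sigs).to_csv(
        out / "ccf_bins.tsv", sep="\t", index=False)
    info = {"chi2": chi2, "chi2_p": p}
    if cfg.metadata:
        meta = aio.read_metadata(cfg.metadata)
        ratio_rows = []
        for thr in cfg.pms_thresholds:
            lab = f"assigned_{thr:g}"
            for sig in sigs:
                per_sample, pval = clonality.subclonal_clonal_ratio_by_group(
                    table, lab, meta, sig, min_mut=cfg.min_mut)
                per_sample["signature"] = sig
                per_sample["threshold"] = thr
                ratio_rows.append(per_sample)
                info[f"ratio_p_{sig}_{thr:g}"] = pval
        pd.concat(ratio_rows, ignore_index=True).to_csv(
            out / "subclonal_clonal_ratios.tsv", sep="\t", index=False,
            float_format="%.6g")
        if "age_group" in meta.columns:
            counts = clonality.count_vs_group(table, label, meta,
                                              "age_group", sigs)
            counts.to_csv(out / "counts_vs_age.tsv", sep="\t", index=False)
        if "ighv" in meta.columns:
            counts = clonality.count_vs_group(table, label, meta,
                                              "ighv", sigs)
            counts.to_csv(out / "counts_vs_ighv.tsv", sep="\t", index=False)
    _manifest(cfg, "clonality", **info)
    return out / "clonality_contingency.tsv"


STAGES = {
    "simulate": run_simulate,
    "annotate": run_annotate,
    "partition": run_partition,
    "decompose": run_decompose,
    "assign": run_assign,
    "enrich": run_enrich,
    "clonality": run_clonality,
}


def run_all(cfg: PipelineConfig, simulate: bool = False):
    """Run every stage in order; with ``simulate`` the cohort is generated
    first, otherwise the configured input files are used."""
    order = (["simulate"] if simulate else []) + [
        "annotate", "partition", "decompose", "assign", "enrich", "clonality"]
    results = {}
    for name in order:
        log.info("stage %s", name)
        try:
            results[name] = STAGES[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
    return results
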