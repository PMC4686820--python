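"""Synthetic CLL-like cohort simulator with full ground truth.

Generates a random reference genome, a non-overlapping gene annotation
with expression levels, and per-sample somatic SNVs from three generative
processes that mirror the biology the pipeline is built to recover:

* ageing    — C>T at CpG sites (spontaneous 5-methylcytosine deamination),
              dispersed genome-wide;
* c-AID     — C>T/G (2:1) at WRCY motifs (W=A/T, R=purine, Y=pyrimidine),
              in clusters placed inside TSS +/- 2 kb windows of highly
              expressed genes, with a subset of flagged target genes
              receiving a configurable share of the clusters;
* nc-AID    — A>C at WA motifs (error-prone polymerase eta repair),
              dispersed genome-wide.

Each mutation gets a process-specific clonality draw (clonal fractions
default to the cohort values 0.36/0.40/0.54 for ageing/c-AID/nc-AID) with
a parametric CCF: clonal CCF ~ Beta(40, 2) truncated to [0.9, 1] with
Pr(CCF>=0.95) >= 0.5, subclonal CCF ~ Uniform(0.1, 0.7) with Pr < 0.5.
Samples carry IGHV status (mutated cases have higher AID exposures) and an
age-group label (older cases have more mutations).  All outputs are
deterministic in (config, seed) and are written in exactly the formats the
reader module consumes (FASTA, BED, MAF-like TSV) plus ground-truth TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CODES_TO_BASE, encode_channels_codes

AGEING, CAID, NCAID = "ageing", "c-AID", "nc-AID"
PROCESSES = (AGEING, CAID, NCAID)

# integer base codes
A, C, G, T = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    """Cohort-level study conditions; defaults are the emulated cohort."""

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 200_000_000
    gc_fraction: float = 0.41
    n_genes: int = 2000
    gene_length_min: int = 10_000
    gene_length_max: int = 60_000
    n_target_genes: int = 30
    target_fraction: float = 0.6      # share of c-AID clusters in targets
    n_samples: int = 30
    mean_mutations_younger: float = 2500.0
    mean_mutations_older: float = 3500.0
    n_older: int = 17
    n_ighv_mutated: int = 18
    # mean exposure fractions (ageing, c-AID, nc-AID) per IGHV group
    exposures_ighv_mutated: tuple = (0.73, 0.12, 0.15)
    exposures_ighv_unmutated: tuple = (0.95, 0.03, 0.02)
    exposure_concentration: float = 60.0
    clonal_fractions: dict = field(default_factory=lambda: {
        AGEING: 0.36, CAID: 0.40, NCAID: 0.54})
    cluster_size_mean: float = 3.0    # 1 + Poisson(mean - 1)
    cluster_spacing_mean: float = 200.0
    tss_window: int = 2000
    caid_ct_prob: float = 2 / 3       # C>T vs C>G

    @property
    def genome_length(self) -> int:
        return self.n_contigs * self.contig_length

    def contig_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    codes: dict[str, np.ndarray]      # per-contig int8 base codes
    genes: pd.DataFrame               # incl. expression, is_target
    fasta_path: Path | None = None
    bed_path: Path | None = None
    expression_path: Path | None = None

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: arr.size for c, arr in self.codes.items()}


def _write_fasta(path: Path, contigs: dict[str, np.ndarray],
                 width: int = 80) -> None:
    nl = np.uint8(ord("\n"))
    with open(path, "wb") as fh:
        for name, codes in contigs.items():
            fh.write(f">{name}\n".encode())
            ascii_arr = CODES_TO_BASE[codes]
            chunk_lines = 2_000_000
            step = chunk_lines * width
            for off in range(0, ascii_arr.size, step):
                part = ascii_arr[off:off + step]
                full = part.size // width
                if full:
                    block = np.empty((full, width + 1), dtype=np.uint8)
                    block[:, :width] = part[:full * width].reshape(full, width)
                    block[:, width] = nl
                    fh.write(block.tobytes())
                rem = part[full * width:]
                if rem.size:
                    fh.write(rem.tobytes() + b"\n")


def simulate_genome(config: SimulationConfig,
                    out_dir: str | Path | None = None) -> SimulatedGenome:
    """Random genome at the configured GC plus a non-overlapping gene set.

    Genes get a strand, a TSS at the strand-appropriate footprint end and
    a log-normal expression level; target genes are drawn from the top
    expression quartile.  When ``out_dir`` is given, genome.fa, genes.bed
    (0-based half-open, extra columns gene_id/score/strand/tss/expression)
    and expression.tsv are written there.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # 16-bit lookup table: base composition matches probs to within 2/65536
    quota = np.floor(probs * 65536).astype(np.int64)
    quota[np.argsort(probs * 65536 - quota)[::-1][:65536 - quota.sum()]] += 1
    table = np.repeat(np.arange(4, dtype=np.int8), quota)
    codes: dict[str, np.ndarray] = {}
    for name in config.contig_names():
        parts = []
        remaining = config.contig_length
        while remaining > 0:
            m = min(remaining, 100_000_000)
            raw = np.frombuffer(rng.bytes(2 * m), dtype=np.uint16)
            parts.append(table[raw])
            remaining -= m
        codes[name] = np.concatenate(parts) if len(parts) > 1 else parts[0]

    genes = _place_genes(config, rng)
    gen = SimulatedGenome(config=config, codes=codes, genes=genes)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gen.fasta_path = out_dir / "genome.fa"
        _write_fasta(gen.fasta_path, codes)
        gen.bed_path = out_dir / "genes.bed"
        bed = pd.DataFrame({
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "gene_id": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
            "tss": genes["tss"],
            "expression": genes["expression"],
        })
        bed.to_csv(gen.bed_path, sep="\t", header=False, index=False,
                   float_format="%.6g")
        gen.expression_path = out_dir / "expression.tsv"
        genes[["gene_id", "expression"]].to_csv(
            gen.expression_path, sep="\t", index=False, float_format="%.6g")
        genes[["gene_id", "is_target"]].to_csv(
            out_dir / "truth_genes.tsv", sep="\t", index=False)
    return gen


def _place_genes(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_genes
    contigs = config.contig_names()
    if n == 0:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                     "strand", "tss", "expression",
                                     "is_target"])
    per_contig = np.full(config.n_contigs, n // config.n_contigs)
    per_contig[: n % config.n_contigs] += 1
    rows = []
    gid = 0
    margin = 2 * config.tss_window + 10
    for ci, name in enumerate(contigs):
        k = int(per_contig[ci])
        if k == 0:
            continue
        lengths = rng.integers(config.gene_length_min,
                               config.gene_length_max + 1, size=k)
        free = config.contig_length - int(lengths.sum()) - 2 * margin
        if free <= k:
            raise ValueError("contig too short for requested genes")
        cuts = np.sort(rng.integers(0, free, size=k))
        starts = margin + cuts + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for s, L in zip(starts, lengths):
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            start1 = int(s) + 1
            end1 = int(s + L)
            tss = start1 if strand == "+" else end1
            rows.append((f"G{gid:05d}", name, start1, end1, strand, tss))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss"])
    genes["expression"] = rng.lognormal(mean=1.0, sigma=1.0, size=len(genes))
    q3 = genes["expression"].quantile(0.75)
    top = genes.index[genes["expression"] >= q3].to_numpy()
    n_target = min(config.n_target_genes, top.size)
    chosen = rng.choice(top, size=n_target, replace=False)
    genes["is_target"] = False
    genes.loc[chosen, "is_target"] = True
    return genes


def _sample_dispersed_sites(rng, codes_list, lengths, n, kind):
    """Rejection-sample n genome positions matching a dispersed motif.

    kind "ageing": CpG-context C on either strand -> C>T (G>A on plus for
    minus-strand sites).  kind "nc-AID": WA-context A on either strand ->
    A>C (T>G).  Returns (contig index, 0-based pos, ref code, alt code).
    """
    lengths = np.asarray(lengths, dtype=float)
    pc = lengths / lengths.sum()
    out_ci, out_pos, out_ref, out_alt = [], [], [], []
    got = 0
    while got < n:
        m = max(4 * (n - got), 2000)
        ci = rng.choice(len(codes_list), size=m, p=pc)
        pos = np.empty(m, dtype=np.int64)
        for c in range(len(codes_list)):
            sel = ci == c
            pos[sel] = rng.integers(2, lengths[c] - 2, size=int(sel.sum()))
        ref = np.empty(m, dtype=np.int8)
        alt = np.empty(m, dtype=np.int8)
        keep = np.zeros(m, dtype=bool)
        for c in range(len(codes_list)):
            sel = np.flatnonzero(ci == c)
            cod = codes_list[c]
            p = pos[sel]
            b0, bl, br = cod[p], cod[p - 1], cod[p + 1]
            if kind == "ageing":
                plus = (b0 == C) & (br == G)
                minus = (b0 == G) & (bl == C)
                ref[sel] = np.where(plus, C, G)
                alt[sel] = np.where(plus, T, A)
            elif kind == "nc-AID":
                plus = (b0 == A) & ((bl == A) | (bl == T))
                minus = (b0 == T) & ((br == A) | (br == T))
                ref[sel] = np.where(plus, A, T)
                alt[sel] = np.where(plus, C, G)
            else:
                raise ValueError(kind)
            keep[sel] = plus | minus
        ok = np.flatnonzero(keep)
        out_ci.append(ci[ok])
        out_pos.append(pos[ok])
        out_ref.append(ref[ok])
        out_alt.append(alt[ok])
        got += ok.size
    ci = np.concatenate(out_ci)[:n]
    pos = np.concatenate(out_pos)[:n]
    ref = np.concatenate(out_ref)[:n]
    alt = np.concatenate(out_alt)[:n]
    return ci, pos, ref, alt


def _wrcy_sites(codes: np.ndarray, lo: int, hi: int):
    """0-based positions in [lo, hi) whose strand-collapsed 4-mer is WRCY.

    Plus strand: base C with 5' R, 5'-5' W, 3' Y.  Minus strand: base G
    with 3' Y', 3'-3' W', 5' R' on the reverse complement, i.e. plus
    pattern R G Y W read at offsets -1..+2.  Returns (positions, is_minus).
    """
    lo = max(lo, 2)
    hi = min(hi, codes.size - 2)
    if hi <= lo:
        return np.empty(0, np.int64), np.empty(0, bool)
    w = codes[lo:hi]
    l1, l2 = codes[lo - 1:hi - 1], codes[lo - 2:hi - 2]
    r1, r2 = codes[lo + 1:hi + 1], codes[lo + 2:hi + 2]
    is_w = lambda b: (b == A) | (b == T)          # noqa: E731
    is_r = lambda b: (b == A) | (b == G)          # noqa: E731
    is_y = lambda b: (b == C) | (b == T)          # noqa: E731
    plus = (w == C) & is_r(l1) & is_w(l2) & is_y(r1)
    minus = (w == G) & is_y(r1) & is_w(r2) & is_r(l1)
    pos = np.flatnonzero(plus | minus) + lo
    return pos.astype(np.int64), minus[pos - lo]


def simulate_mutations(config: SimulationConfig, genome: SimulatedGenome):
    """Per-sample mutations plus ground truth.

    Returns (mutations, truth, metadata, exposures): ``mutations`` is the
    MAF-like table the reader ingests (sample, chrom, pos, ref, alt, gene,
    ccf, pr_ccf_ge_095); ``truth`` is row-aligned with process, cluster id,
    intended clonality and the generating channel; ``metadata`` holds IGHV
    status and age group per sample; ``exposures`` the true per-sample
    process counts.
    """
    rng = np.random.default_rng(config.seed + 1)
    contigs = config.contig_names()
    codes_list = [genome.codes[c] for c in contigs]
    lengths = [arr.size for arr in codes_list]
    genes = genome.genes

    # per-gene WRCY site cache inside TSS windows, for c-AID cluster genes
    q3 = genes["expression"].quantile(0.75)
    topq = genes[genes["expression"] >= q3]
    targets = topq[topq["is_target"]]
    off_targets = topq[~topq["is_target"]]
    if config.n_target_genes > 0 and targets.empty:
        raise ValueError("no target genes available for c-AID clusters")
    site_cache: dict[str, tuple] = {}

    def gene_sites(row):
        gid = row.gene_id
        if gid not in site_cache:
            cod = genome.codes[row.chrom]
            lo = int(row.tss) - 1 - config.tss_window
            hi = int(row.tss) + config.tss_window
            pos, minus = _wrcy_sites(cod, lo, hi)
            site_cache[gid] = (pos, minus)
        return site_cache[gid]

    # sample metadata
    n = config.n_samples
    samples = [f"S{i + 1:02d}" for i in range(n)]
    age = np.array(["younger"] * n, dtype=object)
    age[rng.choice(n, size=min(config.n_older, n), replace=False)] = "older"
    ighv = np.array(["unmutated"] * n, dtype=object)
    ighv[rng.choice(n, size=min(config.n_ighv_mutated, n),
                    replace=False)] = "mutated"

    clonal_frac = config.clonal_fractions
    mut_rows = []
    truth_rows = []
    expo_rows = []
    cluster_counter = 0

    for si, sample in enumerate(samples):
        mean = (config.mean_mutations_older if age[si] == "older"
                else config.mean_mutations_younger)
        n_total = int(rng.poisson(mean))
        base = (config.exposures_ighv_mutated if ighv[si] == "mutated"
                else config.exposures_ighv_unmutated)
        theta = rng.dirichlet(np.asarray(base) * config.exposure_concentration)
        counts = rng.multinomial(n_total, theta)
        expo_rows.append((sample, *counts, *theta))
        used: set[tuple[int, int]] = set()

        def emit(proc, ci, pos0, ref, alt, gene_id=None, cluster=None):
            key = (int(ci), int(pos0))
            if key in used:
                return False
            used.add(key)
            clonal = rng.random() < clonal_frac[proc]
            if clonal:
                ccf = min(max(rng.beta(40, 2), 0.9), 1.0)
                pr = rng.uniform(0.5, 1.0)
                intended = "clonal"
            else:
                ccf = rng.uniform(0.1, 0.7)
                pr = rng.uniform(0.0, 0.5)
                intended = "subclonal"
            chrom = contigs[ci]
            cod = codes_list[ci]
            chan = int(encode_channels_codes(
                np.array([ref]), np.array([alt]),
                cod[pos0 - 1:pos0], cod[pos0 + 1:pos0 + 2])[0])
            mut_rows.append((sample, chrom, int(pos0) + 1,
                             chr(CODES_TO_BASE[ref]), chr(CODES_TO_BASE[alt]),
                             gene_id if gene_id else "", ccf, pr))
            truth_rows.append((sample, chrom, int(pos0) + 1, proc,
                               cluster if cluster is not None else -1,
                               intended, chan))
            return True

        # dispersed processes: ageing and nc-AID
        for proc, kind, want in ((AGEING, "ageing", counts[0]),
                                 (NCAID, "nc-AID", counts[2])):
            need = int(want)
            while need > 0:
                ci_a, p_a, r_a, a_a = _sample_dispersed_sites(
                    rng, codes_list, lengths, need, kind)
                for ci, p0, rf, al in zip(ci_a, p_a, r_a, a_a):
                    if emit(proc, ci, p0, rf, al):
                        need -= 1

        # clustered c-AID
        remaining = int(counts[1])
        guard = 0
        while remaining > 0:
            guard += 1
            if guard > 50 * max(counts[1], 1):
                raise ValueError("insufficient WRCY-motif positions for "
                                 "requested c-AID mutations")
            pick_target = (rng.random() < config.target_fraction
                           and len(targets) > 0) or len(off_targets) == 0
            pool = targets if pick_target else off_targets
            row = pool.iloc[int(rng.integers(len(pool)))]
            pos, minus = gene_sites(row)
            if pos.size == 0:
                continue
            size = min(1 + int(rng.poisson(config.cluster_size_mean - 1)),
                       remaining)
            ci = contigs.index(row.chrom)
            idx = int(rng.integers(pos.size))
            cluster_counter += 1
            placed = 0
            cur_idx = idx
            for j in range(size):
                if j > 0:
                    step = int(rng.geometric(1.0 / config.cluster_spacing_mean))
                    nxt = np.searchsorted(pos, pos[cur_idx] + step)
                    if nxt >= pos.size:
                        break
                    cur_idx = int(nxt)
                p0 = int(pos[cur_idx])
                if minus[cur_idx]:
                    rf, al = G, (A if rng.random() < config.caid_ct_prob else C)
                else:
                    rf, al = C, (T if rng.random() < config.caid_ct_prob else G)
                if emit(CAID, ci, p0, rf, al, gene_id=row.gene_id,
                        cluster=cluster_counter):
                    placed += 1
                cur_idx += 1
                if cur_idx >= pos.size:
                    break
            remaining -= placed

    mutations = pd.DataFrame(mut_rows, columns=[
        "sample", "chrom", "pos", "ref", "alt", "gene", "ccf",
        "pr_ccf_ge_095"])
    truth = pd.DataFrame(truth_rows, columns=[
        "sample", "chrom", "pos", "process", "cluster_id",
        "clonality_true", "channel_true"])
    metadata = pd.DataFrame({"sample": samples, "ighv": ighv,
                             "age_group": age})
    exposures = pd.DataFrame(expo_rows, columns=[
        "sample", "n_ageing", "n_caid", "n_ncaid",
        "theta_ageing", "theta_caid", "theta_ncaid"])
    return mutations, truth, metadata, exposures


def empirical_spectra(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-process channel distribution (96 x processes) from ground truth."""
    out = {}
    for proc, g in truth.groupby("process"):
        counts = np.bincount(g["channel_true"].to_numpy(), minlength=96)
        out[proc] = counts / counts.sum()
    return pd.DataFrame(out)


@dataclass
class CohortPaths:
    out_dir: Path
    fasta: Path
    genes_bed: Path
    expression: Path
    mutations: Path
    truth: Path
    truth_genes: Path
    metadata: Path
    exposures: Path


def simulate_cohort(config: SimulationConfig,
                    out_dir: str | Path) -> CohortPaths:
    """Run the full simulator and write every artifact to ``out_dir``."""
    out_dir = Path(out_dir)
    genome = simulate_genome(config, out_dir=out_dir)
    mutations, truth, metadata, exposures = simulate_mutations(config, genome)
    genome.codes.clear()  # free memory; downstream reads the FASTA
    mutations.to_csv(out_dir / "mutations.tsv", sep="\t", index=False,
                     float_format="%.6g")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    exposures.to_csv(out_dir / "exposures.tsv", sep="\t", index=False,
                     float_format="%.6g")
    import json
    (out_dir / "sim_config.json").write_text(
        json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(config).items()}, indent=2))
    return CohortPaths(
        out_dir=out_dir, fasta=out_dir / "genome.fa",
        genes_bed=out_dir / "genes.bed",
        expression=out_dir / "expression.tsv",
        mutations=out_dir / "mutations.tsv", truth=out_dir / "truth.tsv",
        truth_genes=out_dir / "truth_genes.tsv",
        metadata=out_dir / "metadata.tsv",
        exposures=out_dir / "exposures.tsv")


def truth_evaluate(assignments: pd.DataFrame, truth: pd.DataFrame,
                   label_col: str = "assigned_0.75") -> dict:
    """Recovery report: confusion matrix of hard assignments against the
    generating process, accuracy over assigned mutations, and recovered
    per-process clonal fractions (from the clonality column when present).
    """
    key = ["sample", "chrom", "pos"]
    merged = assignments.merge(truth[key + ["process", "clonality_true"]],
                               on=key, how="inner")
    conf = pd.crosstab(merged["process"], merged[label_col])
    assigned = merged[merged[label_col] != "unassigned"]
    acc = float((assigned[label_col] == assigned["process"]).mean()) \
        if len(assigned) else float("nan")
    report = {"confusion": conf, "accuracy": acc,
              "n_assigned": int(len(assigned)), "n_total": int(len(merged))}
    if "clonality" in merged.columns:
        cl = merged[merged["clonality"].isin(["clonal", "subclonal"])]
        report["clonal_fraction"] = (
            cl.groupby("process")["clonality"]
            .apply(lambda s: float((s == "clonal").mean())))
    return report
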