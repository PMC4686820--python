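"""Input/output for mutation tables, gene annotations and the reference genome.

The in-memory container for mutations is a pandas DataFrame with columns

    sample, chrom, pos, ref, alt            (required; pos is 1-based)
    gene, ccf, pr_ccf_ge_095                (optional, NaN/"." when absent)
    tri_context, channel                    (set by annotate_context; channel
                                             -1 flags excluded records)
    nmd, stratum, clonality                 (set downstream)

Gene annotations are a DataFrame with columns gene_id, chrom, start, end
(1-based inclusive footprint including UTRs and introns), strand, tss
(1-based) and optional expression.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from .channels import encode_channels_codes, seq_to_codes, CODES_TO_BASE, BASES

log = logging.getLogger(__name__)

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]
OPTIONAL_COLUMNS = ["gene", "ccf", "pr_ccf_ge_095"]

_VALID_BASES = set(BASES)


def read_mutations(path, fmt: str = "maf_tsv", sample_id: str | None = None,
                   contigs: list[str] | None = None) -> pd.DataFrame:
    """Read somatic SNVs from a MAF-like TSV or a VCF.

    Parameters
    ----------
    path : file path
    fmt : "maf_tsv" or "vcf"
    sample_id : sample name for VCF input (defaults to the file stem)
    contigs : optional allow-list of contig names; records on other
        contigs are dropped with a logged count.

    Returns a mutation DataFrame.  Records with non-ACGT alleles (and, for
    VCF, non-biallelic or non-SNV records) are skipped; skip counts are
    logged and stored in ``df.attrs["skipped"]``.  A malformed TSV row
    (unparseable position) raises ``ValueError`` naming the line number.
    """
    if fmt == "maf_tsv":
        df = _read_maf_tsv(path)
    elif fmt == "vcf":
        df = _read_vcf(path, sample_id=sample_id)
    else:
        raise ValueError(f"unknown mutation format {fmt!r}")

    skipped = df.attrs.get("skipped", {})
    if contigs is not None:
        keep = df["chrom"].isin(contigs)
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.warning("dropped %d mutations on disallowed contigs", n_dropped)
            skipped["disallowed_contig"] = n_dropped
        df = df[keep].reset_index(drop=True)
    if df.empty:
        log.warning("no mutations read from %s", path)
    df.attrs["skipped"] = skipped
    return df


def _read_maf_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str,
                                            "ref": str, "alt": str},
                     comment="#")
    if df.empty and df.columns.size == 0:
        df = pd.DataFrame(columns=MUTATION_COLUMNS)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos != pos.round()) | (pos < 1)
    if bad.any():
        # +2: header line plus 1-based line numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: malformed position at line {line}")
    df["pos"] = pos.astype(np.int64)

    ref = df["ref"].astype(str).str.upper()
    alt = df["alt"].astype(str).str.upper()
    ok = (ref.isin(_VALID_BASES) & alt.isin(_VALID_BASES) & (ref != alt))
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("rejected %d records with invalid alleles", n_bad)
    df = df.assign(ref=ref, alt=alt)[ok].reset_index(drop=True)

    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("ccf", "pr_ccf_ge_095"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df[MUTATION_COLUMNS + OPTIONAL_COLUMNS]
    df.attrs["skipped"] = {"invalid_allele": n_bad}
    return df


def _read_vcf(path, sample_id: str | None = None) -> pd.DataFrame:
    import pysam

    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    rows = []
    n_multi = n_nonsnv = 0
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or \
                    ref not in _VALID_BASES or alt not in _VALID_BASES:
                n_nonsnv += 1
                continue
            rows.append((sample_id, rec.chrom, rec.pos, ref, alt))
    if n_multi or n_nonsnv:
        log.warning("skipped %d multiallelic and %d non-SNV VCF records",
                    n_multi, n_nonsnv)
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    for col in OPTIONAL_COLUMNS:
        df[col] = np.nan
    df.attrs["skipped"] = {"multiallelic": n_multi, "non_snv": n_nonsnv}
    return df


def read_genes(path) -> pd.DataFrame:
    """Read a gene annotation BED (0-based half-open) into 1-based inclusive
    coordinates.

    Expected columns: chrom, start, end, gene_id, score, strand and
    optionally tss (1-based) and expression.  When tss is absent it is the
    strand-appropriate footprint end.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str, 3: str})
    names = ["chrom", "start", "end", "gene_id", "score", "strand",
             "tss", "expression"]
    df.columns = names[: df.shape[1]]
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64) + 1,  # to 1-based inclusive
        "end": df["end"].astype(np.int64),
        "strand": df.get("strand", pd.Series(["+"] * len(df))),
    })
    if "tss" in df.columns:
        out["tss"] = df["tss"].astype(np.int64)
    else:
        out["tss"] = np.where(out["strand"] == "+", out["start"], out["end"])
    if "expression" in df.columns:
        out["expression"] = pd.to_numeric(df["expression"], errors="coerce")
    else:
        out["expression"] = np.nan
    bad = out["start"] > out["end"]
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} records with start > end")
    return out


def read_expression(path) -> pd.DataFrame:
    """Per-gene expression TSV with columns gene_id, expression."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "expression"} <= set(df.columns):
        raise ValueError(f"{path}: need columns gene_id, expression")
    return df[["gene_id", "expression"]]


def read_metadata(path) -> pd.DataFrame:
    """Per-sample metadata TSV with columns sample, ighv, age_group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValueError(f"{path}: need a 'sample' column")
    return df


def annotate_context(muts: pd.DataFrame, genome) -> pd.DataFrame:
    """Set tri_context and the 96-channel index from the reference genome.

    ``genome`` is a FASTA path or an open ``pyfaidx.Fasta``.  Records at
    contig edges or with non-ACGT flanks get channel -1 (excluded from all
    counting) and a logged tally.  A reference-allele mismatch with the
    genome raises ``ValueError`` listing the offending records.
    """
    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(os.fspath(genome), as_raw=True,
                               sequence_always_upper=True)
    muts = muts.reset_index(drop=True).copy()
    n = len(muts)
    channel = np.full(n, -1, dtype=np.int16)
    context = np.array(["..."] * n, dtype=object)
    mismatches: list[str] = []
    n_edge = n_ambig = 0

    ref_codes = seq_to_codes("".join(muts["ref"])) if n else np.array([], np.int8)
    alt_codes = seq_to_codes("".join(muts["alt"])) if n else np.array([], np.int8)

    for chrom, idx in muts.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        if chrom not in genome:
            raise ValueError(f"contig {chrom!r} absent from reference genome")
        seq = genome[chrom][:]
        codes = seq_to_codes(seq)
        L = codes.size
        pos = muts["pos"].to_numpy()[idx]
        if np.any((pos < 1) | (pos > L)):
            raise ValueError(f"positions outside contig {chrom} bounds")
        edge = (pos == 1) | (pos == L)
        n_edge += int(edge.sum())
        inner = idx[~edge]
        p0 = pos[~edge] - 1  # 0-based center
        center = codes[p0]
        f5 = codes[p0 - 1]
        f3 = codes[p0 + 1]
        mism = center != ref_codes[inner]
        if np.any(mism):
            for i in np.flatnonzero(mism)[:10]:
                row = muts.iloc[inner[i]]
                got = chr(CODES_TO_BASE[center[i]]) if center[i] >= 0 else "N"
                mismatches.append(
                    f"{row['sample']} {chrom}:{row['pos']} ref {row['ref']} "
                    f"vs genome {got}")
            continue  # error raised after the loop
        ambig = (f5 < 0) | (f3 < 0) | (center < 0)
        n_ambig += int(ambig.sum())
        ok = inner[~ambig]
        if ok.size:
            channel[ok] = encode_channels_codes(
                center[~ambig], alt_codes[ok], f5[~ambig], f3[~ambig])
            tri = np.stack([f5[~ambig], center[~ambig], f3[~ambig]], axis=1)
            tri_bytes = CODES_TO_BASE[tri]
            context[ok] = [b.tobytes().decode("ascii") for b in tri_bytes]
    if mismatches:
        raise ValueError("reference allele mismatches: " + "; ".join(mismatches))
    if n_edge or n_ambig:
        log.warning("excluded %d contig-edge and %d ambiguous-flank records "
                    "from channel encoding", n_edge, n_ambig)
    muts["tri_context"] = context
    muts["channel"] = channel
    muts.attrs["excluded"] = {"contig_edge": n_edge, "ambiguous_flank": n_ambig}
    return muts


def write_table(df: pd.DataFrame, path, float_fmt: str = "%.6g") -> None:
    """Write a TSV with header, fixed float precision, deterministic columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def write_matrix(values: np.ndarray, row_labels, col_labels, path,
                 float_fmt: str = "%.10g") -> None:
    """Write a labelled matrix as TSV (rows = row_labels)."""
    frame = pd.DataFrame(values, index=list(row_labels), columns=list(col_labels))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=float_fmt, index_label="row")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
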