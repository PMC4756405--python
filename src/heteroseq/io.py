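"""Table formats: count matrices, pileups, phenotype/hormone tables,
annotation maps, and VCF export of parental SNPs.

All tables are plain TSV/CSV with a header row; comment lines starting
with '#' may precede the header and carry metadata (library sizes for
count matrices, generating thresholds for derived tables).  Coordinates
are 0-based half-open everywhere except the VCF export, which is
1-based as the format requires.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .util import ParseError, logger

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_pileup",
    "write_pileup",
    "read_phenotypes",
    "write_phenotypes",
    "read_hormones",
    "write_hormones",
    "read_annotation",
    "write_annotation",
    "write_snps_vcf",
]

_VALID_BASES = frozenset("ACGT")


def _read_comments(path: Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            out.append(line.rstrip("\n"))
    return out


def _write_table(
    df: pd.DataFrame, path: Path, sep: str, comments: Iterable[str] = ()
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_count_matrix(cm: CountMatrix, path: Path,
                       comments: Iterable[str] = ()) -> None:
    """TSV with columns gene_id, length_bp, one column per sample;
    library sizes in '# library_size <sample> <value>' comment lines."""
    meta = [
        f"library_size\t{s}\t{int(cm.lib_sizes[s])}" for s in cm.samples
    ]
    df = pd.DataFrame({"gene_id": cm.gene_ids, "length_bp": cm.lengths.values})
    for s in cm.samples:
        df[s] = cm.counts[s].values
    _write_table(df, path, "\t", list(comments) + meta)


def read_count_matrix(path: Path) -> CountMatrix:
    """Parse and validate a count-matrix TSV written by
    :func:`write_count_matrix`.

    Library sizes default to column sums (with a warning) when no
    metadata comments are present.  Duplicate gene ids, missing
    columns, and negative or non-integer counts are rejected.
    """
    path = Path(path)
    libs: dict[str, int] = {}
    for line in _read_comments(path):
        parts = line.lstrip("# ").split("\t")
        if parts[0] == "library_size" and len(parts) == 3:
            libs[parts[1]] = int(parts[2])
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    samples = [c for c in df.columns if c not in ("gene_id", "length_bp")]
    if not samples:
        raise ParseError(f"{path}: no sample columns")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    for s in samples:
        col = df[s]
        try:
            as_int = col.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-integer count in column {s!r}") from exc
        if (as_int != col).any() or (as_int < 0).any():
            row = int(np.argmax((as_int != col) | (as_int < 0)))
            raise ParseError(
                f"{path}: invalid count at row {row} column {s!r}"
            )
        df[s] = as_int
    counts = df.set_index("gene_id")[samples]
    lengths = df.set_index("gene_id")["length_bp"]
    if not libs:
        warnings.warn(
            f"{path}: no library-size metadata; using column sums"
        )
        libs = {s: int(counts[s].sum()) for s in samples}
    return CountMatrix(counts, lengths, pd.Series(libs))


def write_pileup(pileup: pd.DataFrame, path: Path,
                 comments: Iterable[str] = ()) -> None:
    """TSV with columns chrom, pos0, gene_id, base, count_<sample>...

    Positions are written 0-based, sorted by (chrom, pos0)."""
    df = pileup.rename(columns={"pos": "pos0"}).sort_values(
        ["chrom", "pos0", "base"], kind="stable"
    )
    _write_table(df, path, "\t", comments)


def read_pileup(path: Path) -> dict[str, pd.DataFrame]:
    """Parse a multi-sample pileup TSV into one per-sample table.

    Returns {sample: DataFrame(chrom, pos, gene_id, base, count)},
    sorted by position regardless of input order.  Bases outside
    A/C/G/T are a parse error; an empty file yields empty tables with
    a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos0", "gene_id", "base"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: pileup needs columns {sorted(required)}")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    if not count_cols:
        raise ParseError(f"{path}: no count_<sample> columns")
    if len(df) == 0:
        warnings.warn(f"{path}: empty pileup")
    else:
        bad = ~df["base"].isin(_VALID_BASES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: invalid base {df['base'].iloc[row]!r} at row {row}"
            )
    df = df.sort_values(["chrom", "pos0", "base"], kind="stable")
    out = {}
    for col in count_cols:
        sample = col[len("count_"):]
        out[sample] = (
            df[["chrom", "pos0", "gene_id", "base", col]]
            .rename(columns={"pos0": "pos", col: "count"})
            .reset_index(drop=True)
        )
    return out


def write_phenotypes(df: pd.DataFrame, path: Path) -> None:
    _write_table(df, path, ",")


def read_phenotypes(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"individual_id", "line", "stage", "trait", "value"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: phenotype CSV needs {sorted(required)}")
    return df


def write_hormones(df: pd.DataFrame, path: Path) -> None:
    _write_table(df, path, ",")


def read_hormones(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"analyte", "stage", "line", "replicate", "concentration",
                "detected"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: hormone CSV needs {sorted(required)}")
    df["detected"] = df["detected"].astype(bool)
    return df


def write_annotation(df: pd.DataFrame, path: Path) -> None:
    _write_table(df[["term_id", "gene_id"]], path, "\t")


def read_annotation(path: Path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) into a term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise ParseError(f"{path}: annotation TSV needs term_id, gene_id")
    return {
        term: set(grp["gene_id"]) for term, grp in df.groupby("term_id")
    }


def write_snps_vcf(snps: pd.DataFrame, path: Path,
                   sample_p1: str = "P1", sample_p2: str = "P2") -> None:
    """Export fixed parental differences as a minimal VCF 4.2.

    The two parents appear as homozygous samples (0/0 and 1/1) with
    per-sample depth in DP; internal 0-based positions become 1-based.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heteroseq\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_p1}\t{sample_p2}\n"
        )
        for snp in snps.sort_values(["chrom", "pos"], kind="stable").itertuples():
            dp1 = getattr(snp, "cov_p1", ".")
            dp2 = getattr(snp, "cov_p2", ".")
            fh.write(
                f"{snp.chrom}\t{snp.pos + 1}\t{snp.gene_id}\t"
                f"{snp.allele_p1}\t{snp.allele_p2}\t.\tPASS\t.\t"
                f"GT:DP\t0/0:{dp1}\t1/1:{dp2}\n"
            )
    logger.info("wrote %d SNPs to %s", len(snps), path)
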