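"""Allele-specific expression from RNA-seq SNPs in a two-parent/F1 design.

Fixed differences between the two homozygous inbred parents are
discovered from per-site base pileups (minimum coverage eight reads per
site in each parent, major allele comprising at least 95% of reads, and
differing major alleles).  F1 reads matching either parental allele are
tallied per gene across its diagnostic sites; reads matching neither
allele are discarded into a QC tally.

Two questions are then asked per gene.  First, does the allelic ratio in
the F1 (AEL) differ from the ratio of the parents' own expression at the
same sites (REL)?  This is a 2x2 independence test: chi-squared without
continuity correction, replaced by Fisher's exact test when any expected
cell is below five; discordance is called at p < 0.01.  Second, is the
gene allele-specifically expressed?  A gene is called biased toward one
parent when the allelic read counts differ at least five-fold and the
exact binomial test against a 0.5 null is significant at p < 0.05; when
only one parental allele is observed at all, the single-allele rule
applies instead (one-sided p = 0.5^n < 0.001).  No multiple-testing
correction is applied to these calls (BH q-values are reported
alongside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .util import DataError, logger, percent

__all__ = [
    "call_parental_snps",
    "gene_allelic_counts",
    "ael_vs_rel_test",
    "classify_allele_specific",
    "ase_table",
    "summarize_ase",
    "CATEGORIES",
]

CATEGORIES = ("P1_only", "P1_biased", "P2_only", "P2_biased", "biallelic")


def _site_major(grp: pd.DataFrame) -> tuple[str, int, int]:
    """(major base, major count, total coverage) of one pileup site."""
    by_base = grp.groupby("base")["count"].sum().sort_values(
        ascending=False, kind="stable"
    )
    return str(by_base.index[0]), int(by_base.iloc[0]), int(by_base.sum())


def call_parental_snps(
    pileup_p1: pd.DataFrame,
    pileup_p2: pd.DataFrame,
    min_coverage: int = 8,
    purity: float = 0.95,
    gene_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fixed parental differences from two parental pileups.

    Pileups have columns chrom, pos, gene_id, base, count (0-based
    positions).  A site is emitted when each parent has at least
    ``min_coverage`` reads, each parent's major allele comprises at
    least ``purity`` of its reads (homozygosity filter for inbred
    lines), and the two major alleles differ.  ``gene_map`` (chrom,
    start, end, gene_id; half-open intervals) overrides the pileups'
    own gene annotation when given.
    """
    sites1 = {
        key: _site_major(grp)
        for key, grp in pileup_p1.groupby(["chrom", "pos"])
    }
    rows = []
    for key, grp2 in pileup_p2.groupby(["chrom", "pos"]):
        if key not in sites1:
            continue
        a1, n1, cov1 = sites1[key]
        a2, n2, cov2 = _site_major(grp2)
        if cov1 < min_coverage or cov2 < min_coverage:
            continue
        if n1 < purity * cov1 or n2 < purity * cov2:
            continue
        if a1 == a2:
            continue
        chrom, pos = key
        gene = grp2["gene_id"].iloc[0]
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "gene_id": gene,
                "allele_p1": a1,
                "allele_p2": a2,
                "cov_p1": cov1,
                "cov_p2": cov2,
            }
        )
    snps = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "gene_id", "allele_p1", "allele_p2",
            "cov_p1", "cov_p2",
        ],
    )
    if gene_map is not None and len(snps):
        snps["gene_id"] = [
            _annotate(gene_map, c, p) for c, p in zip(snps["chrom"], snps["pos"])
        ]
        snps = snps.dropna(subset=["gene_id"]).reset_index(drop=True)
    return snps.sort_values(["chrom", "pos"], kind="stable").reset_index(
        drop=True
    )


def _annotate(gene_map: pd.DataFrame, chrom: str, pos: int):
    hit = gene_map[
        (gene_map["chrom"] == chrom)
        & (gene_map["start"] <= pos)
        & (pos < gene_map["end"])
    ]
    return hit["gene_id"].iloc[0] if len(hit) else None


def gene_allelic_counts(
    f1_pileup: pd.DataFrame, snps: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene F1 read tallies over the two parental alleles.

    Returns gene_id, n_sites, reads_p1_allele, reads_p2_allele and the
    QC tally other_reads (F1 reads matching neither parental allele).
    SNP sites absent from the F1 pileup are skipped with a warning;
    genes without any usable site are absent from the output.
    """
    f1 = {
        key: grp.groupby("base")["count"].sum()
        for key, grp in f1_pileup.groupby(["chrom", "pos"])
    }
    rows: dict[str, dict[str, int]] = {}
    skipped = 0
    for snp in snps.itertuples():
        key = (snp.chrom, snp.pos)
        if key not in f1:
            skipped += 1
            continue
        base_counts = f1[key]
        a = int(base_counts.get(snp.allele_p1, 0))
        b = int(base_counts.get(snp.allele_p2, 0))
        other = int(base_counts.sum()) - a - b
        rec = rows.setdefault(
            snp.gene_id,
            {"n_sites": 0, "reads_p1_allele": 0, "reads_p2_allele": 0,
             "other_reads": 0},
        )
        rec["n_sites"] += 1
        rec["reads_p1_allele"] += a
        rec["reads_p2_allele"] += b
        rec["other_reads"] += other
    if skipped:
        logger.warning("%d SNP sites absent from the F1 pileup; skipped", skipped)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out.reset_index()


def ael_vs_rel_test(
    reads_p1_allele: int,
    reads_p2_allele: int,
    parent_reads_p1: int,
    parent_reads_p2: int,
) -> float:
    """AEL-vs-REL concordance p-value for one gene.

    2x2 independence test on [[F1 P1-allele, F1 P2-allele],
    [P1 own reads, P2 own reads]] at the same SNP sites: chi-squared
    without continuity correction, or Fisher's exact test when any
    expected cell is below five.  A zero margin leaves the test
    undefined (the gene is excluded upstream).
    """
    table = np.array(
        [[reads_p1_allele, reads_p2_allele],
         [parent_reads_p1, parent_reads_p2]],
        dtype=float,
    )
    if (table < 0).any():
        raise DataError("negative cell in 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("zero margin: AEL/REL test undefined")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        return float(stats.fisher_exact(table.astype(int)).pvalue)
    return float(stats.chi2_contingency(table, correction=False).pvalue)


def classify_allele_specific(
    reads_p1_allele: int,
    reads_p2_allele: int,
    fold: float = 5.0,
    alpha_bias: float = 0.05,
    alpha_mono: float = 0.001,
) -> tuple[str, float]:
    """ASE category and the p-value supporting it.

    With a = P1-allele reads and b = P2-allele reads (a + b > 0):
    if only one allele is observed the single-allele rule applies,
    one-sided p = 0.5^n < ``alpha_mono`` calling P1_only/P2_only;
    otherwise the gene is P1_biased/P2_biased when the counts differ
    at least ``fold``-fold and the two-sided exact binomial p against
    0.5 is below ``alpha_bias``; anything else is biallelic.
    """
    a, b = int(reads_p1_allele), int(reads_p2_allele)
    if a < 0 or b < 0:
        raise DataError("allelic read counts must be non-negative")
    if a + b == 0:
        raise DataError("zero allelic reads: gene not classified")
    if a == 0 or b == 0:
        p_mono = 0.5 ** (a + b)
        if p_mono < alpha_mono:
            return ("P1_only" if b == 0 else "P2_only"), p_mono
        return "biallelic", p_mono
    p_two = float(stats.binomtest(a, a + b, 0.5).pvalue)
    if max(a, b) / min(a, b) >= fold and p_two < alpha_bias:
        return ("P1_biased" if a > b else "P2_biased"), p_two
    return "biallelic", p_two


def ase_table(
    allelic: pd.DataFrame,
    snps: pd.DataFrame,
    fold: float = 5.0,
    alpha_bias: float = 0.05,
    alpha_mono: float = 0.001,
    alpha_ael_rel: float = 0.01,
) -> pd.DataFrame:
    """Joint ASE classification and AEL/REL concordance per gene.

    ``allelic`` comes from :func:`gene_allelic_counts`; parental reads
    at the same SNP sites (the REL side of the 2x2) are summed from the
    site coverages in ``snps``.  Genes with a zero margin in the 2x2
    (e.g. not expressed in one parent at those sites) get no
    concordance p-value, mirroring their exclusion from the published
    tally.  BH q-values are reported alongside both raw p columns.
    """
    parent = snps.groupby("gene_id")[["cov_p1", "cov_p2"]].sum()
    rows = []
    for rec in allelic.itertuples():
        category, p_allelic = classify_allele_specific(
            rec.reads_p1_allele, rec.reads_p2_allele, fold, alpha_bias,
            alpha_mono,
        )
        p_ael_rel = np.nan
        if rec.gene_id in parent.index:
            pp1 = int(parent.loc[rec.gene_id, "cov_p1"])
            pp2 = int(parent.loc[rec.gene_id, "cov_p2"])
            try:
                p_ael_rel = ael_vs_rel_test(
                    rec.reads_p1_allele, rec.reads_p2_allele, pp1, pp2
                )
            except DataError:
                pass
        rows.append(
            {
                "gene_id": rec.gene_id,
                "n_sites": rec.n_sites,
                "reads_p1_allele": rec.reads_p1_allele,
                "reads_p2_allele": rec.reads_p2_allele,
                "category": category,
                "p_allelic": p_allelic,
                "p_ael_rel": p_ael_rel,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_allelic"] = multipletests(out["p_allelic"], method="fdr_bh")[1]
        tested = out["p_ael_rel"].notna()
        out["q_ael_rel"] = np.nan
        if tested.any():
            out.loc[tested, "q_ael_rel"] = multipletests(
                out.loc[tested, "p_ael_rel"], method="fdr_bh"
            )[1]
        out["discordant"] = out["p_ael_rel"] < alpha_ael_rel
    return out


def summarize_ase(results: pd.DataFrame) -> dict[str, float]:
    """Category counts and the discordance rate among allele-specific genes."""
    counts = {cat: 0 for cat in CATEGORIES}
    if len(results):
        counts.update(results["category"].value_counts().to_dict())
    p1_specific = counts["P1_only"] + counts["P1_biased"]
    p2_specific = counts["P2_only"] + counts["P2_biased"]
    total_as = p1_specific + p2_specific
    summary: dict[str, float] = {
        **counts,
        "P1_specific": p1_specific,
        "P2_specific": p2_specific,
        "total_allele_specific": total_as,
    }
    if len(results) and "discordant" in results:
        as_mask = results["category"] != "biallelic"
        n_disc = int(
            (results.loc[as_mask, "discordant"].fillna(False)).sum()
        )
        summary["discordant_allele_specific"] = n_disc
        if total_as:
            summary["pct_discordant"] = percent(n_disc, total_as)
    return summary
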