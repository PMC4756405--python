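"""Synthetic two-inbred-parent / F1-hybrid data with known ground truth.

The generator emulates the data structures of a heterosis RNA-seq study
of two homozygous inbred lines (P1, P2) and their F1 hybrid:

* phenotype tables (per-individual trait measurements per line and
  stage) with Gaussian noise truncated at zero, defaulting to the
  published cotyledon/leaf-area and fresh-weight group means (SDs
  recovered from the printed standard errors and group sizes);
* gene-level read counts under a gamma-Poisson (negative binomial)
  model with a configurable dispersion, a stated fraction of genes
  differentially expressed between the parents at a stated log2 fold
  change, and library sizes around a common mean;
* fixed parental SNPs in a stated fraction of genes (31% by default,
  matching the fraction of annotated genes carrying SNPs between the
  study's parents), with homozygous parental pileups and F1 allelic
  reads drawn per site as Binomial(coverage, true allelic ratio) —
  a ratio of fold/(1+fold) for the allele-specifically expressed
  fraction of SNP genes, 0.5 otherwise;
* hormone concentration tables with per-analyte per-line means/SDs and
  a detection limit (analytes can be below detection in some or all
  lines);
* a term-to-gene annotation map in which enriched terms preferentially
  recruit true-DE genes at a configurable odds ratio.

All randomness flows from a single seed through fixed per-component
substreams, so identical (seed, config) pairs give byte-identical
outputs and components can be regenerated independently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .util import ConfigError, DataError, logger

__all__ = [
    "SimConfig",
    "SimData",
    "gen_phenotypes",
    "gen_hormones",
    "gen_transcriptomes",
    "gen_f1",
    "gen_annotation",
    "simulate_all",
]

LINES = ("P1", "P2", "F1")
_BASES = ("A", "C", "G", "T")
# fixed substream indices for independent regeneration
_STREAMS = {
    "phenotypes": 1,
    "transcriptome": 2,
    "f1": 3,
    "annotation": 4,
    "hormones": 5,
}
# genes tiled along one chromosome at this spacing (bp)
_GENE_SPACING = 10_000


def _default_phenotype_params() -> dict:
    # (trait, stage DAS) -> line -> (mean, SD); SD = printed SE * sqrt(n)
    return {
        ("cotyledon_area_mm2", 2): {
            "P1": (10.77, 2.57), "P2": (11.69, 2.15), "F1": (13.04, 3.33)},
        ("cotyledon_area_mm2", 4): {
            "P1": (52.87, 15.94), "P2": (53.59, 12.84), "F1": (68.82, 17.23)},
        ("cotyledon_area_mm2", 6): {
            "P1": (80.14, 21.35), "P2": (77.13, 16.95), "F1": (100.52, 28.14)},
        ("leaf_area_mm2", 14): {
            "P1": (146.48, 30.12), "P2": (114.62, 26.94), "F1": (179.13, 41.76)},
        ("fresh_weight_mg", 14): {
            "P1": (239.86, 37.78), "P2": (182.75, 28.13), "F1": (257.63, 34.36)},
    }


def _default_hormone_params() -> dict:
    # analyte -> line -> (mean, SD) in pmol/g FW at 2 DAS; None = below
    # detection in that line.  The pattern mirrors the study's report:
    # salicylic acid overdominant in the F1, gibberellin precursors
    # higher in P2, trans-zeatin undetected in the parents, and a few
    # analytes below detection in every line.
    return {
        "IAA": {"P1": (250.0, 40.0), "P2": (230.0, 40.0), "F1": (240.0, 40.0)},
        "ABA": {"P1": (120.0, 20.0), "P2": (140.0, 25.0), "F1": (130.0, 20.0)},
        "SA": {"P1": (900.0, 90.0), "P2": (850.0, 90.0), "F1": (1400.0, 120.0)},
        "JA": {"P1": (60.0, 12.0), "P2": (75.0, 14.0), "F1": (68.0, 12.0)},
        "GA8": {"P1": (14.0, 3.0), "P2": (30.0, 5.0), "F1": None},
        "GA12": {"P1": (8.0, 2.0), "P2": (22.0, 4.0), "F1": (9.0, 2.0)},
        "GA20": {"P1": (5.0, 1.5), "P2": (16.0, 3.0), "F1": (6.0, 1.5)},
        "GA53": {"P1": (11.0, 2.5), "P2": (28.0, 4.0), "F1": (12.0, 2.5)},
        "tZ": {"P1": None, "P2": None, "F1": (4.0, 1.0)},
        "iP": {"P1": (3.5, 0.8), "P2": (3.0, 0.8), "F1": (3.2, 0.8)},
        "IAA-Asp": {"P1": (40.0, 8.0), "P2": (35.0, 8.0), "F1": (38.0, 8.0)},
        "GA1": {"P1": None, "P2": None, "F1": None},
        "GA4": {"P1": None, "P2": None, "F1": None},
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study; defaults are desk-scale.

    Desk scale means 2,000 genes at ~500k mapped reads per library
    (one library per line, as in the study) instead of 41,174 genes at
    ~16M reads; fractions (DE genes, SNP-bearing genes, allele-biased
    genes) keep the published proportions where the study states them.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_line: int = 1
    mean_library_size: int = 500_000
    nb_dispersion: float = 0.05
    frac_de_parents: float = 0.05
    de_log2fc: float = 2.0
    frac_ase: float = 0.03
    ase_fold: float = 5.0
    frac_snp_genes: float = 0.31
    snps_per_gene: int = 3
    site_coverage_mean: float = 40.0
    log_expr_sigma: float = 1.0
    frac_nonadditive: float = 0.005
    nonadd_log2fc: float = 1.5
    n_individuals_per_line: int = 30
    phenotype_group_params: Mapping = field(
        default_factory=_default_phenotype_params
    )
    n_hormone_replicates: int = 4
    hormone_stage: int = 2
    detection_limit: float = 1.0
    hormone_group_params: Mapping = field(
        default_factory=_default_hormone_params
    )
    n_go_terms: int = 50
    frac_enriched_terms: float = 0.1
    enriched_odds: float = 8.0

    def validate(self) -> None:
        for name in (
            "frac_de_parents", "frac_ase", "frac_snp_genes",
            "frac_nonadditive", "frac_enriched_terms",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_genes", "n_samples_per_line", "mean_library_size",
            "snps_per_gene", "n_individuals_per_line",
            "n_hormone_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if self.de_log2fc < 0 or self.ase_fold < 1:
            raise ConfigError("effect sizes out of range")
        if self.site_coverage_mean <= 0:
            raise ConfigError("site_coverage_mean must be positive")
        if self.n_go_terms < 0:
            raise ConfigError("n_go_terms must be non-negative")
        for group in self.phenotype_group_params.values():
            for mean, sd in group.values():
                if sd < 0:
                    raise ConfigError("phenotype SD must be non-negative")
        for group in self.hormone_group_params.values():
            for params in group.values():
                if params is not None and params[1] < 0:
                    raise ConfigError("hormone SD must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Substream generator derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )


@dataclass
class SimData:
    """Everything one synthetic study produces, truth included."""

    config: SimConfig
    phenotypes: pd.DataFrame
    hormones: pd.DataFrame
    counts: CountMatrix          # P1/P2 sample columns plus F1
    snp_sites: pd.DataFrame      # true fixed differences
    pileup: pd.DataFrame         # per-site base counts per sample
    truth: pd.DataFrame          # per-gene ground truth
    annotation: pd.DataFrame     # term_id, gene_id
    term_truth: pd.DataFrame     # term_id, enriched


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Gaussian draws redrawn (then clipped) to stay positive."""
    if sd == 0:
        return np.full(n, float(mean))
    vals = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = vals <= 0
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
    else:
        vals = np.clip(vals, np.finfo(float).tiny, None)
    return vals


def gen_phenotypes(config: SimConfig) -> pd.DataFrame:
    """Per-individual phenotype table (individual_id, line, stage,
    trait, value)."""
    config.validate()
    rng = config.rng("phenotypes")
    rows = []
    for (trait, stage), group in config.phenotype_group_params.items():
        for line in LINES:
            if line not in group:
                raise ConfigError(
                    f"phenotype params missing line {line!r} for {trait!r}"
                )
            mean, sd = group[line]
            vals = _truncated_normal(
                rng, mean, sd, config.n_individuals_per_line
            )
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "individual_id": f"{line}_{trait}_{stage}_{i:03d}",
                        "line": line,
                        "stage": stage,
                        "trait": trait,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


def gen_hormones(config: SimConfig) -> pd.DataFrame:
    """Hormone table (analyte, stage, line, replicate, concentration,
    detected); values below the detection limit are undetected and
    carry no concentration."""
    config.validate()
    rng = config.rng("hormones")
    rows = []
    for analyte, group in config.hormone_group_params.items():
        for line in LINES:
            params = group.get(line)
            for rep in range(config.n_hormone_replicates):
                if params is None:
                    conc, detected = np.nan, False
                else:
                    v = float(
                        _truncated_normal(rng, params[0], params[1], 1)[0]
                    )
                    detected = v >= config.detection_limit
                    conc = v if detected else np.nan
                rows.append(
                    {
                        "analyte": analyte,
                        "stage": config.hormone_stage,
                        "line": line,
                        "replicate": rep,
                        "concentration": conc,
                        "detected": detected,
                    }
                )
    return pd.DataFrame(rows)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws; dispersion 0 is the Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, dispersion * mean)
    return rng.poisson(lam)


def gen_transcriptomes(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Parental count matrix, true SNP sites, and the truth table.

    Baseline relative expression is lognormal across genes; DE genes
    split the stated log2 fold change symmetrically between the two
    parents so the mid-parent level is preserved.  The truth table
    carries one row per gene: DE status and signed log2FC (P1 vs P2),
    F1 non-additivity, SNP count, ASE status and the true F1 allelic
    ratio (P1-allele share; NaN for genes without SNPs).
    """
    config.validate()
    if config.n_genes == 0:
        raise ConfigError("n_genes must be positive")
    rng = config.rng("transcriptome")
    n = config.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    lengths = np.clip(
        rng.lognormal(math.log(1500.0), 0.35, n), 200, 10_000
    ).astype(int)

    rel = rng.lognormal(0.0, config.log_expr_sigma, n)
    is_de = rng.random(n) < config.frac_de_parents
    de_sign = rng.choice([-1.0, 1.0], n)
    log2fc = np.where(is_de, de_sign * config.de_log2fc, 0.0)

    mult_p1 = np.power(2.0, log2fc / 2.0)
    mult_p2 = np.power(2.0, -log2fc / 2.0)
    counts = {}
    libs = {}
    for line, mult in (("P1", mult_p1), ("P2", mult_p2)):
        weights = rel * mult
        frac = weights / weights.sum()
        for k in range(config.n_samples_per_line):
            name = (
                line
                if config.n_samples_per_line == 1
                else f"{line}_{k + 1}"
            )
            lib = int(rng.lognormal(math.log(config.mean_library_size), 0.05))
            counts[name] = _nb_counts(rng, frac * lib, config.nb_dispersion)
            libs[name] = lib
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids),
        pd.Series(lengths, index=gene_ids, name="length_bp"),
        pd.Series(libs, name="library_size"),
    )

    # fixed parental differences
    has_snp = rng.random(n) < config.frac_snp_genes
    snp_rows = []
    for g in np.flatnonzero(has_snp):
        start = g * _GENE_SPACING
        offsets = rng.choice(
            int(lengths[g]), size=min(config.snps_per_gene, int(lengths[g])),
            replace=False,
        )
        for off in np.sort(offsets):
            a1 = _BASES[rng.integers(4)]
            a2 = _BASES[
                (rng.integers(3) + _BASES.index(a1) + 1) % 4
            ]
            snp_rows.append(
                {
                    "chrom": "chr1",
                    "pos": int(start + off),
                    "gene_id": gene_ids[g],
                    "allele_p1": a1,
                    "allele_p2": a2,
                }
            )
    snp_sites = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "gene_id", "allele_p1", "allele_p2"]
    )

    # allele-specific expression truth (only meaningful with >=1 SNP)
    is_ase = has_snp & (rng.random(n) < config.frac_ase)
    toward_p1 = rng.random(n) < 0.5
    biased = config.ase_fold / (1.0 + config.ase_fold)
    ratio = np.where(is_ase, np.where(toward_p1, biased, 1.0 - biased), 0.5)
    ratio = np.where(has_snp, ratio, np.nan)

    is_nonadd = rng.random(n) < config.frac_nonadditive
    nonadd_sign = rng.choice([-1.0, 1.0], n)
    f1_log2fc = np.where(is_nonadd, nonadd_sign * config.nonadd_log2fc, 0.0)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "rel_expr": rel,
            "length_bp": lengths,
            "is_de": is_de,
            "log2fc_p1_vs_p2": log2fc,
            "is_nonadditive": is_nonadd,
            "f1_log2fc_vs_mpv": f1_log2fc,
            "n_snps": np.where(has_snp, config.snps_per_gene, 0),
            "is_ase": is_ase,
            "true_allelic_ratio": ratio,
        }
    ).reset_index(drop=True)
    logger.info(
        "simulated %d genes: %d DE, %d with SNPs, %d allele-biased",
        n, int(is_de.sum()), int(has_snp.sum()), int(is_ase.sum()),
    )
    return cm, snp_sites, truth


def gen_f1(
    config: SimConfig, truth: pd.DataFrame, snp_sites: pd.DataFrame
) -> tuple[pd.Series, int, pd.DataFrame]:
    """F1 count column (with its library size) and the three-sample
    pileup at the true SNP sites.

    F1 gene totals are additive (the gene's mid-parent relative level)
    except for the designated non-additive genes.  At each SNP site the
    parents are homozygous for their own allele with Poisson coverage;
    F1 reads carrying the P1 allele are Binomial(coverage, true
    allelic ratio).
    """
    config.validate()
    required = {
        "gene_id", "rel_expr", "log2fc_p1_vs_p2", "f1_log2fc_vs_mpv",
        "true_allelic_ratio",
    }
    if not required <= set(truth.columns):
        raise DataError("truth table missing required columns")
    if len(truth) != config.n_genes:
        raise DataError("truth table does not cover every gene")
    rng = config.rng("f1")

    rel = truth["rel_expr"].to_numpy()
    lfc = truth["log2fc_p1_vs_p2"].to_numpy()
    mpv_rel = rel * (np.power(2.0, lfc / 2.0) + np.power(2.0, -lfc / 2.0)) / 2.0
    f1_rel = mpv_rel * np.power(2.0, truth["f1_log2fc_vs_mpv"].to_numpy())
    frac = f1_rel / f1_rel.sum()
    lib = int(rng.lognormal(math.log(config.mean_library_size), 0.05))
    f1_counts = pd.Series(
        _nb_counts(rng, frac * lib, config.nb_dispersion),
        index=pd.Index(truth["gene_id"], name="gene_id"),
        name="F1",
    )

    ratio_by_gene = dict(
        zip(truth["gene_id"], truth["true_allelic_ratio"])
    )
    rows = []
    for site in snp_sites.itertuples():
        if site.gene_id not in ratio_by_gene:
            raise DataError(f"truth missing for gene {site.gene_id!r}")
        ratio = ratio_by_gene[site.gene_id]
        cov_p1 = int(rng.poisson(config.site_coverage_mean))
        cov_p2 = int(rng.poisson(config.site_coverage_mean))
        cov_f1 = int(rng.poisson(config.site_coverage_mean))
        a = int(rng.binomial(cov_f1, ratio)) if cov_f1 else 0
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "gene_id": site.gene_id,
                "base": site.allele_p1,
                "count_P1": cov_p1,
                "count_P2": 0,
                "count_F1": a,
            }
        )
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "gene_id": site.gene_id,
                "base": site.allele_p2,
                "count_P1": 0,
                "count_P2": cov_p2,
                "count_F1": cov_f1 - a,
            }
        )
    pileup = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "gene_id", "base",
            "count_P1", "count_P2", "count_F1",
        ],
    )
    return f1_counts, lib, pileup


def gen_annotation(
    config: SimConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Term-to-gene annotation plus the per-term enrichment truth.

    Enriched terms draw their member genes with weights that favour
    true-DE genes by ``enriched_odds``; at odds 1 every term is null
    and downstream overrepresentation p-values are uniform.
    """
    config.validate()
    rng = config.rng("annotation")
    if config.n_go_terms == 0:
        warnings.warn("n_go_terms = 0: empty annotation map")
        return (
            pd.DataFrame(columns=["term_id", "gene_id"]),
            pd.DataFrame(columns=["term_id", "enriched"]),
        )
    genes = truth["gene_id"].to_numpy()
    is_de = truth["is_de"].to_numpy()
    n = len(genes)
    n_enriched = int(round(config.frac_enriched_terms * config.n_go_terms))
    enriched_flags = np.zeros(config.n_go_terms, dtype=bool)
    if n_enriched:
        enriched_flags[
            rng.choice(config.n_go_terms, n_enriched, replace=False)
        ] = True
    lo = max(5, n // 100)
    hi = max(lo + 1, n // 10)
    ann_rows = []
    term_rows = []
    for t in range(config.n_go_terms):
        term_id = f"GO:{t:07d}"
        size = int(rng.integers(lo, hi + 1))
        if enriched_flags[t]:
            w = np.where(is_de, config.enriched_odds, 1.0)
            p = w / w.sum()
            members = rng.choice(genes, size=size, replace=False, p=p)
        else:
            members = rng.choice(genes, size=size, replace=False)
        for g in members:
            ann_rows.append({"term_id": term_id, "gene_id": g})
        term_rows.append({"term_id": term_id, "enriched": bool(enriched_flags[t])})
    return pd.DataFrame(ann_rows), pd.DataFrame(term_rows)


def simulate_all(config: SimConfig) -> SimData:
    """Run every generator and bundle the study with its ground truth."""
    config.validate()
    phenotypes = gen_phenotypes(config)
    hormones = gen_hormones(config)
    cm, snp_sites, truth = gen_transcriptomes(config)
    f1_counts, f1_lib, pileup = gen_f1(config, truth, snp_sites)
    counts = cm.counts.copy()
    counts["F1"] = f1_counts
    libs = cm.lib_sizes.copy()
    libs["F1"] = f1_lib
    full = CountMatrix(counts, cm.lengths, libs)
    annotation, term_truth = gen_annotation(config, truth)
    return SimData(
        config=config,
        phenotypes=phenotypes,
        hormones=hormones,
        counts=full,
        snp_sites=snp_sites,
        pileup=pileup,
        truth=truth,
        annotation=annotation,
        term_truth=term_truth,
    )
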