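"""FPKM quantification, merged-read mid-parent expression, and two-library
differential-expression calling.

The container is a gene x sample matrix of raw read counts with per-gene
transcript lengths and per-sample library sizes (uniquely mapped reads).
Expression is scored as FPKM; the mid-parent expression value (MPV) of the
two inbred parents is computed by merging their reads (counts and library
sizes summed) rather than by averaging FPKM, which matters when the two
libraries differ in depth.

Differential expression between two libraries without replicates is tested
with the exact conditional binomial test: conditional on the total count
n = a + b of a gene, a is Binomial(n, La/(La+Lb)) under the null of equal
relative expression, where La and Lb are library sizes.  The two-sided
p-value sums all outcomes no more probable than the observed one
(Audic-Claverie-equivalent at fixed totals).  A gene is called
differentially expressed when |log2 FPKM ratio| >= 1 and p < 0.05; raw p
governs the call and Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .util import DataError, logger

__all__ = [
    "CountMatrix",
    "fpkm",
    "mpv_expression",
    "de_test",
    "classify_de",
    "de_table",
    "VennPartition",
    "venn_partition",
    "ratio_correlation",
]

# Relative tolerance for probability ties in the exact two-sided test;
# guards against float noise when pmf values are analytically equal.
_TIE_RTOL = 1e-7


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with lengths and library sizes.

    ``lib_sizes`` stores total uniquely mapped reads per sample; it is a
    scalar per sample and is not required to equal the column sum.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataError(f"duplicate gene id: {dup!r}")
        if not self.counts.index.equals(self.lengths.index):
            raise DataError("gene ids of counts and lengths differ")
        if not set(self.counts.columns) == set(self.lib_sizes.index):
            raise DataError("samples of counts and library sizes differ")
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if (self.lengths <= 0).any():
            raise DataError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("read counts must be non-negative")
        if (self.lib_sizes <= 0).any():
            raise DataError("library sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def fpkm_frame(self) -> pd.DataFrame:
        """FPKM for every gene and sample."""
        return self.counts.div(self.lengths / 1e3, axis=0).div(
            self.lib_sizes / 1e6, axis=1
        )

    def with_merged(self, samples: Sequence[str], name: str) -> "CountMatrix":
        """Return a copy with an extra column merging ``samples``."""
        merged, lib = mpv_expression(
            self.counts[samples[0]],
            self.counts[samples[1]],
            float(self.lib_sizes[samples[0]]),
            float(self.lib_sizes[samples[1]]),
        )
        counts = self.counts.copy()
        counts[name] = merged
        libs = self.lib_sizes.copy()
        libs[name] = lib
        return CountMatrix(counts, self.lengths.copy(), libs)


def fpkm(count: float, length_bp: float, library: float):
    """Fragments per kilobase of transcript per million mapped reads.

    Scale-invariant: multiplying count and library by the same factor
    leaves the value unchanged.
    """
    length_bp = np.asarray(length_bp, dtype=float)
    library = np.asarray(library, dtype=float)
    if np.any(length_bp <= 0):
        raise DataError("gene length must be positive")
    if np.any(library <= 0):
        raise DataError("library size must be positive")
    out = np.asarray(count, dtype=float) / (length_bp / 1e3) / (library / 1e6)
    return float(out) if out.ndim == 0 else out


def mpv_expression(
    counts_p1: pd.Series,
    counts_p2: pd.Series,
    lib_p1: float,
    lib_p2: float,
) -> tuple[pd.Series, float]:
    """Merge the two parental libraries into a mid-parent sample.

    Per-gene counts and library sizes are summed; FPKM computed on the
    merged sample is the depth-weighted average of the parental FPKMs
    (the plain average when depths are equal).
    """
    if not counts_p1.index.equals(counts_p2.index):
        raise DataError("parental samples cover different gene sets")
    return counts_p1 + counts_p2, float(lib_p1) + float(lib_p2)


def de_test(count_a: int, count_b: int, lib_a: float, lib_b: float) -> float:
    """Exact conditional binomial two-library test.

    Under the null of equal relative expression, conditional on
    n = count_a + count_b, count_a ~ Binomial(n, lib_a/(lib_a+lib_b)).
    Two-sided p sums all outcomes with probability <= the observed one.
    """
    a, b = int(count_a), int(count_b)
    if a < 0 or b < 0:
        raise DataError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise DataError("both counts zero: p-value undefined")
    p_null = lib_a / (lib_a + lib_b)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p_null)
    p = pmf[pmf <= pmf[a] * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def classify_de(
    fpkm_a: float,
    fpkm_b: float,
    p: float,
    min_log2_fold: float = 1.0,
    alpha: float = 0.05,
) -> bool:
    """Two-fold / 95%-confidence call on one gene.

    A gene expressed in only one of the two samples has an infinite
    fold change, so the fold criterion is taken as satisfied and the
    call is decided by the p-value alone.  A gene expressed in neither
    sample is not evaluated (DataError).
    """
    if fpkm_a == 0 and fpkm_b == 0:
        raise DataError("gene expressed in neither sample: not evaluated")
    if fpkm_a == 0 or fpkm_b == 0:
        fold_ok = True
    else:
        fold_ok = abs(math.log2(fpkm_a / fpkm_b)) >= min_log2_fold
    return bool(fold_ok and p < alpha)


def de_table(
    cm: CountMatrix,
    sample_a: str,
    sample_b: str,
    min_log2_fold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene DE comparison of two samples of a count matrix.

    Genes with zero counts in both samples are skipped, mirroring the
    exclusion of no-read genes from the published tallies.  Returns
    columns gene_id, fpkm_a, fpkm_b, log2_ratio, p_value, q_value,
    de_flag; log2_ratio is +/-inf when one sample is silent.
    """
    a = cm.counts[sample_a].to_numpy()
    b = cm.counts[sample_b].to_numpy()
    lib_a = float(cm.lib_sizes[sample_a])
    lib_b = float(cm.lib_sizes[sample_b])
    keep = (a + b) > 0
    fa = fpkm(a[keep], cm.lengths.to_numpy()[keep], lib_a)
    fb = fpkm(b[keep], cm.lengths.to_numpy()[keep], lib_b)
    with np.errstate(divide="ignore"):
        log2_ratio = np.log2(fa) - np.log2(fb)
    pvals = np.array(
        [de_test(ai, bi, lib_a, lib_b) for ai, bi in zip(a[keep], b[keep])]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    flags = np.array(
        [
            classify_de(fai, fbi, pi, min_log2_fold, alpha)
            for fai, fbi, pi in zip(fa, fb, pvals)
        ]
    )
    out = pd.DataFrame(
        {
            "gene_id": cm.gene_ids[keep],
            "fpkm_a": fa,
            "fpkm_b": fb,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
            "q_value": qvals,
            "de_flag": flags,
        }
    ).reset_index(drop=True)
    logger.info(
        "DE %s vs %s: %d/%d genes tested, %d flagged",
        sample_a, sample_b, keep.sum(), len(keep), int(flags.sum()),
    )
    return out


@dataclass
class VennPartition:
    """Region cardinalities of a family of gene sets.

    ``intersections`` maps each non-empty subset of set names (joined
    with '&') to the size of the plain intersection; ``exclusive`` maps
    it to the size of the region belonging to exactly those sets.
    """

    intersections: dict[str, int]
    exclusive: dict[str, int]


def venn_partition(sets: Mapping[str, Iterable]) -> VennPartition:
    """All intersection-region cardinalities of up to a handful of sets."""
    names = list(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    inter: dict[str, int] = {}
    excl: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask >> i & 1]
        others = [n for n in names if n not in members]
        region = set.intersection(*(as_sets[m] for m in members))
        key = "&".join(members)
        inter[key] = len(region)
        for o in others:
            region = region - as_sets[o]
        excl[key] = len(region)
    return VennPartition(inter, excl)


def ratio_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between two measurement methods' ratios."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise DataError("need at least three (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
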