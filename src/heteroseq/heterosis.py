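"""Heterosis ratio statistics, letter-grouped comparisons, hormone
dominance classes, profile clustering, and chlorophyll quantification.

Heterosis of a trait is expressed as the ratio of the F1 mean to the
mid-parent value (MPV, the arithmetic mean of the two parental means) and
to the best-parent value (BPV, the larger parental mean).  Ratios are
rounded half-up to two decimals, matching how such tables are printed.
Group differences use the two-sided equal-variance Student t-test at
alpha = 0.05 by default (Welch behind a flag), summarised as a compact
letter display: lines that are not significantly different share at
least one letter.

Hormone profiles (analyte x condition concentration matrices) are
median-centered per analyte and clustered by agglomerative average
linkage (UPGMA); concentrations below the detection limit are missing
for distance purposes and treated as zero when classifying the F1
relative to the parental range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .util import DataError, round_half_up

__all__ = [
    "mid_parent_value",
    "best_parent_value",
    "heterosis_ratios",
    "heterosis_table",
    "pairwise_letter_groups",
    "dominance_class",
    "dominance_table",
    "total_chlorophyll",
    "chlorophyll_per_mg_fw",
    "median_center",
    "hormone_matrix",
    "Dendrogram",
    "cluster_profiles",
]

LINES = ("P1", "P2", "F1")


def mid_parent_value(mean_p1: float, mean_p2: float) -> float:
    """Arithmetic mean of the two parental means."""
    if not (np.isfinite(mean_p1) and np.isfinite(mean_p2)):
        raise DataError("parental means must be finite")
    return (mean_p1 + mean_p2) / 2.0


def best_parent_value(mean_p1: float, mean_p2: float) -> float:
    """The larger of the two parental means."""
    return max(mean_p1, mean_p2)


def heterosis_ratios(
    mean_p1: float, mean_p2: float, mean_f1: float
) -> tuple[float, float]:
    """(F1/MPV, F1/BPV), each rounded half-up to two decimals.

    Ratios are computed on the unrounded means and only the final
    ratio is rounded.  For positive means F1/MPV >= F1/BPV always,
    because BPV >= MPV.
    """
    if mean_p1 <= 0 or mean_p2 <= 0:
        raise DataError("heterosis ratios need positive parental means")
    mpv = mid_parent_value(mean_p1, mean_p2)
    bpv = best_parent_value(mean_p1, mean_p2)
    return round_half_up(mean_f1 / mpv, 2), round_half_up(mean_f1 / bpv, 2)


def _ttest(
    x: np.ndarray, y: np.ndarray, equal_var: bool = True
) -> float:
    """Two-sided two-sample t-test p-value with degenerate handling.

    Groups of fewer than two observations cannot be tested.  If both
    groups are constant the t statistic is undefined; identical
    constants are reported as p = 1 and distinct constants as p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("each group needs at least two values for a t-test")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def _maximal_cliques(adj: list[set[int]]) -> list[set[int]]:
    """Bron-Kerbosch enumeration of maximal cliques (no pivoting;
    group counts here are tiny)."""
    cliques: list[set[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(range(len(adj))), set())
    return cliques


def pairwise_letter_groups(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> dict[str, str]:
    """Compact letter display from all-pairs Student t-tests.

    Two groups share at least one letter exactly when their difference
    is not significant at ``alpha``.  Letters a, b, c... are assigned in
    descending order of group mean (ties broken by group name), by
    enumerating the maximal cliques of the non-significance graph: each
    clique is one letter, so the shared-letter relation equals the
    non-significance relation on every pair.
    """
    names = sorted(
        samples, key=lambda k: (-np.mean(np.asarray(samples[k], float)), k)
    )
    n = len(names)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            p = _ttest(samples[names[i]], samples[names[j]], equal_var)
            if p >= alpha:
                adj[i].add(j)
                adj[j].add(i)
    cliques = _maximal_cliques(adj)
    cliques.sort(key=lambda c: (min(c), -len(c), sorted(c)))
    letters: dict[str, list[str]] = {name: [] for name in names}
    for rank, clique in enumerate(cliques):
        symbol = chr(ord("a") + rank)
        for idx in clique:
            letters[names[idx]].append(symbol)
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


def dominance_class(
    p1: Sequence[float],
    p2: Sequence[float],
    f1: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> str:
    """Classify the F1 level relative to the parental range.

    'above-both' (overdominant) when the F1 mean exceeds each parent
    with a significant t-test against each; 'below-both'
    (underdominant) symmetrically; otherwise 'within-parental-range'.
    A non-significant excess stays within-parental-range.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    f1 = np.asarray(f1, float)
    pa = _ttest(f1, p1, equal_var)
    pb = _ttest(f1, p2, equal_var)
    mf, m1, m2 = f1.mean(), p1.mean(), p2.mean()
    if mf > m1 and mf > m2 and pa < alpha and pb < alpha:
        return "above-both"
    if mf < m1 and mf < m2 and pa < alpha and pb < alpha:
        return "below-both"
    return "within-parental-range"


def dominance_table(
    hormones: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per (analyte, stage) dominance class of the F1 hormone level.

    ``hormones`` has columns analyte, stage, line, replicate,
    concentration, detected.  Values below detection are treated as
    zero for range classification; an analyte undetected in every line
    at a stage is excluded (class undefined).
    """
    rows = []
    for (analyte, stage), grp in hormones.groupby(["analyte", "stage"]):
        if not grp["detected"].any():
            continue
        vals = {
            line: grp.loc[grp["line"] == line, "concentration"]
            .fillna(0.0)
            .to_numpy()
            for line in LINES
        }
        rows.append(
            {
                "analyte": analyte,
                "stage": stage,
                "mean_p1": vals["P1"].mean(),
                "mean_p2": vals["P2"].mean(),
                "mean_f1": vals["F1"].mean(),
                "dominance": dominance_class(
                    vals["P1"], vals["P2"], vals["F1"], alpha
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["analyte", "stage", "mean_p1", "mean_p2", "mean_f1", "dominance"],
    )


def total_chlorophyll(a646: float, a663: float) -> float:
    """Total chlorophyll (ug/mL) of an 80% acetone extract.

    Linear spectrophotometric form 17.76 x A646.6 + 7.34 x A663.6.
    """
    if a646 < 0 or a663 < 0:
        raise DataError("absorbances must be non-negative")
    return 17.76 * a646 + 7.34 * a663


def chlorophyll_per_mg_fw(
    a646: float, a663: float, extract_volume_ml: float, fresh_weight_mg: float
) -> float:
    """Chlorophyll normalised to ug per mg fresh weight."""
    if extract_volume_ml <= 0 or fresh_weight_mg <= 0:
        raise DataError("volume and mass must be positive")
    return total_chlorophyll(a646, a663) * extract_volume_ml / fresh_weight_mg


def heterosis_table(
    measurements: pd.DataFrame, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Per (trait, stage) heterosis summary of a phenotype table.

    ``measurements`` has columns individual_id, line, stage, trait,
    value.  Returns group means, MPV, BPV, both ratios (2 dp) and the
    compact letter display across P1/P2/F1.
    """
    if not np.isfinite(measurements["value"]).all():
        raise DataError("measurement values must be finite")
    rows = []
    for (trait, stage), grp in measurements.groupby(["trait", "stage"]):
        samples = {
            line: grp.loc[grp["line"] == line, "value"].to_numpy()
            for line in LINES
        }
        if any(len(v) == 0 for v in samples.values()):
            raise DataError(f"empty line group for trait {trait!r} at {stage}")
        m1, m2, mf = (samples[ln].mean() for ln in LINES)
        r_mpv, r_bpv = heterosis_ratios(m1, m2, mf)
        letters = pairwise_letter_groups(samples, alpha, equal_var)
        rows.append(
            {
                "trait": trait,
                "stage": stage,
                "mean_p1": m1,
                "mean_p2": m2,
                "mean_f1": mf,
                "mpv": mid_parent_value(m1, m2),
                "bpv": best_parent_value(m1, m2),
                "ratio_mpv": r_mpv,
                "ratio_bpv": r_bpv,
                "letters_p1": letters["P1"],
                "letters_p2": letters["P2"],
                "letters_f1": letters["F1"],
            }
        )
    return pd.DataFrame(rows)


# --- profile clustering -------------------------------------------------


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's median (computed over observed values)."""
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def hormone_matrix(hormones: pd.DataFrame) -> pd.DataFrame:
    """Analyte x (line at stage) mean-concentration matrix.

    Undetected measurements are missing.  Analytes observed in no more
    than half of the conditions are dropped: distances are computed
    pairwise-complete, and two rows each observed in more than half of
    the columns are guaranteed to share at least one column.
    """
    df = hormones.copy()
    df.loc[~df["detected"].astype(bool), "concentration"] = np.nan
    mat = df.pivot_table(
        index="analyte",
        columns=["line", "stage"],
        values="concentration",
        aggfunc="mean",
    )
    mat.columns = [f"{line}_{stage}DAS" for line, stage in mat.columns]
    keep = mat.notna().sum(axis=1) > mat.shape[1] / 2
    return mat.loc[keep]


def _pairwise_complete_euclidean(x: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances ignoring missing coordinates.

    Each pair's squared distance over its jointly observed coordinates
    is rescaled by p/m (p coordinates total, m observed) so rows with
    missing values remain comparable to complete rows.
    """
    n, p = x.shape
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(x[i]) & np.isfinite(x[j])
            m = int(mask.sum())
            if m == 0:
                raise DataError(
                    "rows share no observed coordinates; distance undefined"
                )
            d2 = float(np.sum((x[i, mask] - x[j, mask]) ** 2))
            out[k] = np.sqrt(d2 * p / m)
            k += 1
    return out


@dataclass
class Dendrogram:
    """UPGMA merge history over named leaves.

    ``merges`` lists (member set, height) in merge order; heights are
    non-decreasing.  ``linkage`` is the scipy linkage matrix for
    downstream plotting.
    """

    labels: list[str]
    linkage: np.ndarray

    @property
    def merges(self) -> list[tuple[frozenset, float]]:
        clusters: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for step, (a, b, h, _size) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[len(self.labels) + step] = merged
            out.append((merged, float(h)))
        return out

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return recurse(tree, tree.dist).rsplit(":", 1)[0] + ";"


def cluster_profiles(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
    center: bool = True,
) -> tuple[Dendrogram, pd.DataFrame]:
    """Average-linkage (UPGMA) clustering of median-centered profiles.

    Returns the dendrogram over rows and the median-centered display
    matrix (each row has median zero over its observed values).
    ``center=False`` clusters the raw values, e.g. for profiles that
    are already normalised.  Missing values are handled
    pairwise-complete; rows missing everywhere must be removed
    beforehand (DataError otherwise).
    """
    matrix = matrix.astype(float)
    if matrix.isna().all(axis=1).any():
        raise DataError("all-missing row reached clustering")
    if len(matrix) < 2:
        raise DataError("need at least two profiles to cluster")
    display = median_center(matrix) if center else matrix
    x = display.to_numpy()
    if np.isnan(x).any():
        dists = _pairwise_complete_euclidean(x)
        if metric != "euclidean":
            raise DataError(
                "only euclidean distances support missing values"
            )
    else:
        from scipy.spatial.distance import pdist

        dists = pdist(x, metric=metric)
    z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(list(matrix.index), z), display
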