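"""Comparative evaluation of graph-construction combinations.

Four analyses: (i) significance scans of mean graph properties between
condition pairs, using an F-test to pick Student's vs Welch's t-test;
(ii) rank profiles of subjects per combination and their Euclidean-distance
dendrogram, quantifying robustness of the subject ordering to method
choice; (iii) pairwise leave-one-out SVM classification with greedy forward
feature selection; (iv) the correlation between per-combination negative
surprise and SVM accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import SVC

__all__ = [
    "mean_difference_test",
    "significance_scan",
    "rank_profiles",
    "rank_distance_linkage",
    "linkage_to_newick",
    "svm_pairwise_loo",
    "surprise_vs_svm",
    "CorrelationResult",
]

CONDITION_PAIRS: tuple[tuple[str, str], ...] = (("C", "MCI"), ("C", "AD"), ("MCI", "AD"))


def mean_difference_test(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, str, str]:
    """Two-sided mean-difference test with variance-based test selection.

    A two-sided F-test on the sample variances at level ``alpha`` selects
    Student's t-test (variances equal) or Welch's t-test.  Returns
    (p_value, direction, test_used) where direction is '<' or '>' from the
    sign of mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    direction = "<" if x.mean() < y.mean() else ">"
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 1.0, direction, "student"
        return 0.0, direction, "student"
    if vx == 0 or vy == 0:
        p_f = 0.0
    else:
        f = vx / vy
        cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
        p_f = 2 * min(cdf, 1 - cdf)
    equal_var = p_f >= alpha
    test_used = "student" if equal_var else "welch"
    p = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
    return float(p), direction, test_used


def significance_scan(
    table: pd.DataFrame,
    properties: list[str] | None = None,
    pairs: tuple[tuple[str, str], ...] = CONDITION_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fractions of significant mean differences per class of method.

    ``table`` is a tidy per-subject feature table with metadata columns
    ``subject``, ``condition``, ``clustering_family``, ``clustering``,
    ``edge_family``, ``edge``, ``w_min``, ``subgraph`` plus property
    columns.  For each clustering family x edge family x property x
    condition pair x direction, the fraction of method variants (clustering
    parameters x edge variants x thresholds x subgraphs) with p < alpha in
    that direction is reported; variants lacking two subjects in either
    condition are excluded from the denominator.
    """
    if properties is None:
        properties = [
            c
            for c in ("weight_mean", "degree_n_mean", "shortest_path_mean", "clustering_mean")
            if c in table.columns
        ]
    variant_cols = ["clustering", "edge", "w_min", "subgraph"]
    rows = []
    for (cf, ef), chunk in table.groupby(["clustering_family", "edge_family"]):
        for prop in properties:
            for pair in pairs:
                counts = {"<": 0, ">": 0}
                n_variants = 0
                for _, variant in chunk.groupby(variant_cols):
                    a = variant.loc[variant["condition"] == pair[0], prop].to_numpy()
                    b = variant.loc[variant["condition"] == pair[1], prop].to_numpy()
                    if len(a) < 2 or len(b) < 2:
                        continue
                    n_variants += 1
                    p, direction, _ = mean_difference_test(a, b, alpha)
                    if p < alpha:
                        counts[direction] += 1
                if n_variants == 0:
                    continue
                for direction in ("<", ">"):
                    rows.append(
                        {
                            "clustering_family": cf,
                            "edge_family": ef,
                            "property": prop,
                            "pair": f"{pair[0]}-{pair[1]}",
                            "direction": direction,
                            "fraction": counts[direction] / n_variants,
                            "n_variants": n_variants,
                        }
                    )
    return pd.DataFrame(rows)


def rank_profiles(
    table: pd.DataFrame, property_col: str, combo_cols: list[str] | None = None
) -> pd.DataFrame:
    """Subject ranks by a property's per-subject value, per combination.

    Subjects are ordered by ascending value (ties broken by subject id);
    each subject's rank (1..n) forms the combination's profile.  Returns a
    DataFrame indexed by subject with one column per combination;
    combinations missing subjects are dropped.
    """
    if combo_cols is None:
        combo_cols = [
            c
            for c in ("clustering", "edge", "w_min", "subgraph")
            if c in table.columns
        ]
    subjects = sorted(table["subject"].unique())
    profiles = {}
    for combo, chunk in table.groupby(combo_cols):
        chunk = chunk.drop_duplicates(subset="subject")
        if sorted(chunk["subject"]) != subjects:
            continue
        ordered = chunk.sort_values([property_col, "subject"])["subject"].tolist()
        ranks = {s: i + 1 for i, s in enumerate(ordered)}
        name = combo if isinstance(combo, str) else "|".join(str(c) for c in combo)
        profiles[name] = [ranks[s] for s in subjects]
    return pd.DataFrame(profiles, index=subjects)


def rank_distance_linkage(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree on Euclidean distances between rank profiles."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least two profiles")
    d = pdist(profiles.to_numpy().T, metric="euclidean")
    return linkage(d, method="average"), list(profiles.columns)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for idx, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        new = n + idx
        nodes[new] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[new] = h
    return nodes[n + len(z) - 1] + ";"


def _loo_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    hits = 0
    for train, test in LeaveOneOut().split(x):
        if len(np.unique(y[train])) < 2:
            raise ValueError("degenerate single-class training fold")
        clf = SVC()  # default RBF kernel and regularization
        clf.fit(x[train], y[train])
        hits += int(clf.predict(x[test])[0] == y[test][0])
    return hits / len(y)


def svm_pairwise_loo(
    features: np.ndarray, labels: np.ndarray
) -> tuple[float, list[int]]:
    """Leave-one-out SVM accuracy on one condition pair with greedy forward
    feature selection.

    Starting from no features, the column whose addition most improves the
    LOO accuracy is added (lowest index on ties); selection stops when no
    strict improvement remains, so duplicated columns never change the
    result.  Returns (best accuracy, selected column indices).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("both classes need at least 2 subjects")
    selected: list[int] = []
    best_acc = 0.0
    # exact duplicate columns are redundant and would only rescale the RBF
    # metric; keep the first occurrence of each
    seen: dict[bytes, int] = {}
    remaining = []
    for j in range(x.shape[1]):
        key = x[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            remaining.append(j)
    while remaining:
        best_j, best_j_acc = None, best_acc
        for j in remaining:
            acc = _loo_accuracy(x[:, selected + [j]], y)
            if acc > best_j_acc + 1e-12:
                best_j, best_j_acc = j, acc
        if best_j is None:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        best_acc = best_j_acc
    return best_acc, selected


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n_included: int
    excluded_families: tuple[str, ...]


def surprise_vs_svm(
    table: pd.DataFrame, exclude_families: tuple[str, ...] = ("TE",)
) -> CorrelationResult:
    """Pearson correlation and regression of SVM accuracy on negative
    surprise across method combinations, excluding the given edge families
    (reported separately in the paper-style analysis)."""
    included = table[~table["edge_family"].isin(exclude_families)]
    if len(included) < 3:
        raise ValueError("need at least 3 included combinations")
    x = included["surprise"].to_numpy(dtype=float)
    y = included["accuracy"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    lr = stats.linregress(x, y)
    return CorrelationResult(
        r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n_included=len(included),
        excluded_families=tuple(exclude_families),
    )
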