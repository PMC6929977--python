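"""Verification and cohort statistics.

Contains the agreement/diagnostic toolbox used downstream of methylation
quantification: Bland-Altman agreement against known truth, ROC with the
Youden-optimal operating point, classification trees (CART, Gini), Fisher's
exact test for r x c contingency tables, confusion metrics, and an
end-to-end cohort report.

ROC, CART and the exact test are implemented here rather than delegated:
the required conventions (midpoint thresholds with the tie broken toward
sensitivity; greedy Gini splits with deterministic tie-breaks; the
sum-of-less-probable-tables two-sided rule for arbitrary r x c) are not
jointly available in any single installed library.  scipy/scikit-learn
serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, DataError

__all__ = [
    "BlandAltmanStats",
    "ROCResult",
    "TreeNode",
    "bland_altman",
    "roc_youden",
    "cart_fit",
    "cart_predict",
    "tree_to_text",
    "tree_to_dict",
    "fisher_exact",
    "confusion_metrics",
    "cohort_report",
]


# ---------------------------------------------------------- Bland-Altman

@dataclass(frozen=True)
class BlandAltmanStats:
    """Agreement between estimates and truths: difference statistics and
    1.96-sigma limits of agreement; (mean, difference) pairs are the
    plotting coordinates."""

    means: np.ndarray
    diffs: np.ndarray
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    max_abs_diff: float


def bland_altman(estimates: Sequence[float], truths: Sequence[float]) -> BlandAltmanStats:
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise DataError("estimates and truths must be equal-length and nonempty")
    diffs = est - tru
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltmanStats(
        means=(est + tru) / 2.0,
        diffs=diffs,
        mean_diff=mean_diff,
        sd_diff=sd,
        lower_limit=mean_diff - 1.96 * sd,
        upper_limit=mean_diff + 1.96 * sd,
        max_abs_diff=float(np.max(np.abs(diffs))),
    )


# ------------------------------------------------------------------ ROC

@dataclass(frozen=True)
class ROCResult:
    """ROC curve with the Youden-optimal operating point.

    Positive call convention: score >= threshold.  The optimum maximizes
    J = sensitivity + specificity - 1; ties are broken toward the lower
    threshold, i.e. toward higher sensitivity.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_optimal_threshold: float
    sensitivity_at_optimum: float
    specificity_at_optimum: float
    accuracy_at_optimum: float


def roc_youden(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise DataError("scores and labels must be equal-length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present for ROC analysis")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = np.sum(pred & y) / n_pos
        spec[i] = np.sum(~pred & ~y) / n_neg

    j = sens + spec - 1.0
    # lowest threshold among the argmax ties -> highest sensitivity
    best = int(np.flatnonzero(j == j.max())[0])

    # descending threshold sweeps the ROC staircase: FPR and TPR both
    # non-decreasing, so the trapezoid rule integrates the true curve
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    pred_best = s >= thresholds[best]
    acc = float(np.mean(pred_best == y))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_optimal_threshold=float(thresholds[best]),
        sensitivity_at_optimum=float(sens[best]),
        specificity_at_optimum=float(spec[best]),
        accuracy_at_optimum=acc,
    )


# ----------------------------------------------------------------- CART

@dataclass(frozen=True)
class TreeNode:
    """CART node: a leaf (prediction + class counts) or an internal split
    ``feature < threshold`` (left) vs ``>= threshold`` (right)."""

    depth: int
    counts: dict
    prediction: object
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _gini(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p * p))


def _majority(labels: np.ndarray, overall_order: list) -> object:
    vals, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = [v for v, c in zip(vals, counts) if c == top]
    if len(tied) == 1:
        return tied[0]
    # tie: most frequent class overall, then lexicographically first
    for cls in overall_order:
        if cls in tied:
            return cls
    return sorted(tied, key=str)[0]


def _best_split(
    X: pd.DataFrame, y: np.ndarray, min_leaf: int
) -> tuple[str, float] | None:
    best: tuple[float, str, float] | None = None
    n = y.size
    for feature in X.columns:
        values = X[feature].to_numpy(dtype=float)
        distinct = np.unique(values)
        if distinct.size < 2:
            continue
        for thr in (distinct[:-1] + distinct[1:]) / 2.0:
            mask = values < thr
            n_left = int(mask.sum())
            if n_left < min_leaf or n - n_left < min_leaf:
                continue
            score = (
                n_left * _gini(y[mask]) + (n - n_left) * _gini(y[~mask])
            ) / n
            if best is None or score < best[0] - 1e-15:
                best = (score, feature, float(thr))
    return None if best is None else (best[1], best[2])


def cart_fit(
    features: pd.DataFrame,
    labels: Sequence,
    min_leaf: int = 5,
    max_depth: int = 3,
) -> TreeNode:
    """Greedy binary CART minimizing weighted Gini impurity.

    Candidate thresholds are midpoints of sorted distinct feature values
    (binary 0/1 features split at 0.5).  Growth stops at pure nodes, at
    ``max_depth``, or when a child would fall below ``min_leaf`` samples.
    Split ties are resolved by feature (column) order, then by the smaller
    threshold.
    """
    if features.shape[1] == 0:
        raise DataError("empty feature set")
    y = np.asarray(labels)
    if y.size != len(features):
        raise DataError("features and labels must align")
    if y.size < 2 * min_leaf:
        raise DataError(f"need >= {2 * min_leaf} samples for min_leaf={min_leaf}")
    vals, counts = np.unique(y, return_counts=True)
    overall_order = [
        v for _, v in sorted(zip(-counts, vals), key=lambda t: (t[0], str(t[1])))
    ]

    def build(X: pd.DataFrame, yy: np.ndarray, depth: int) -> TreeNode:
        uvals, ucounts = np.unique(yy, return_counts=True)
        node_counts = dict(zip(uvals.tolist(), ucounts.tolist()))
        prediction = _majority(yy, overall_order)
        if uvals.size == 1 or depth >= max_depth:
            return TreeNode(depth, node_counts, prediction)
        split = _best_split(X, yy, min_leaf)
        if split is None:
            return TreeNode(depth, node_counts, prediction)
        feature, thr = split
        mask = X[feature].to_numpy(dtype=float) < thr
        return TreeNode(
            depth,
            node_counts,
            prediction,
            feature=feature,
            threshold=thr,
            left=build(X[mask], yy[mask], depth + 1),
            right=build(X[~mask], yy[~mask], depth + 1),
        )

    return build(features, y, 0)


def cart_predict(tree: TreeNode, features: pd.DataFrame) -> np.ndarray:
    def walk(node: TreeNode, row: pd.Series):
        while not node.is_leaf:
            node = node.left if row[node.feature] < node.threshold else node.right
        return node.prediction

    return np.array([walk(tree, row) for _, row in features.iterrows()])


def tree_to_text(tree: TreeNode) -> str:
    lines: list[str] = []

    def emit(node: TreeNode, indent: str) -> None:
        if node.is_leaf:
            lines.append(f"{indent}predict {node.prediction} {node.counts}")
        else:
            lines.append(f"{indent}if {node.feature} < {node.threshold:.6g}:")
            emit(node.left, indent + "  ")
            lines.append(f"{indent}else:")
            emit(node.right, indent + "  ")

    emit(tree, "")
    return "\n".join(lines)


def tree_to_dict(tree: TreeNode) -> dict:
    if tree.is_leaf:
        return {
            "prediction": tree.prediction,
            "counts": {str(k): v for k, v in tree.counts.items()},
        }
    return {
        "feature": tree.feature,
        "threshold": tree.threshold,
        "counts": {str(k): v for k, v in tree.counts.items()},
        "left": tree_to_dict(tree.left),
        "right": tree_to_dict(tree.right),
    }


# --------------------------------------------------------- Fisher exact

#: Enumeration budget guards: table total and cell count for which full
#: enumeration of margin-fixed tables is attempted.
FISHER_MAX_TOTAL = 200
FISHER_MAX_CELLS = 12
_FISHER_MAX_TABLES = 5_000_000


def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    return log_const - sum(math.lgamma(n + 1) for n in table.flat)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for an r x c contingency table.

    p is the total probability, under the hypergeometric null with both
    margins fixed, of all tables whose point probability does not exceed
    the observed table's (within a 1e-12 relative slack) — the standard
    exact two-sided definition, which reduces to the textbook rule for
    2 x 2 tables.
    """
    obs = np.asarray(table)
    if obs.ndim != 2:
        raise DataError("table must be 2-dimensional")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.allclose(obs, np.round(obs)):
            raise DataError("counts must be integers")
        obs = np.round(obs).astype(int)
    if np.any(obs < 0):
        raise DataError("counts must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise DataError("all row and column margins must be nonzero")
    total = int(obs.sum())
    if total > FISHER_MAX_TOTAL or obs.size > FISHER_MAX_CELLS:
        raise CapacityError(
            f"table (total={total}, cells={obs.size}) exceeds the exact "
            "enumeration budget; bin categories first"
        )

    log_const = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(total + 1)
    )
    log_p_obs = _log_table_prob(obs, log_const)
    slack = 1e-12
    r, c = obs.shape
    p_value = 0.0
    n_tables = 0

    # Depth-first enumeration over rows; each row is a composition of its
    # margin constrained by the remaining column margins.
    def rows(remaining_cols: np.ndarray, row_idx: int, log_acc: float) -> None:
        nonlocal p_value, n_tables
        if row_idx == r - 1:
            # last row forced by the column margins
            log_p = log_acc - sum(
                math.lgamma(n + 1) for n in remaining_cols
            )
            n_tables += 1
            if n_tables > _FISHER_MAX_TABLES:
                raise CapacityError("exact enumeration budget exceeded")
            if log_p <= log_p_obs + slack:
                p_value += math.exp(log_p)
            return
        target = int(row_sums[row_idx])

        def cells(j: int, left: int, cols: np.ndarray, log_row: float) -> None:
            if j == c - 1:
                if left <= cols[c - 1]:
                    new_cols = cols.copy()
                    new_cols[c - 1] -= left
                    rows(new_cols, row_idx + 1, log_row - math.lgamma(left + 1))
                return
            for k in range(min(left, cols[j]) + 1):
                new_cols = cols.copy()
                new_cols[j] -= k
                cells(j + 1, left - k, new_cols, log_row - math.lgamma(k + 1))

        cells(0, target, remaining_cols, log_acc)

    rows(col_sums.astype(int).copy(), 0, log_const)
    return min(1.0, p_value)


# ---------------------------------------------------- confusion metrics

def confusion_metrics(predicted, actual) -> dict[str, float]:
    """Sensitivity, specificity, accuracy of binary predictions."""
    pred = np.asarray(predicted).astype(bool)
    act = np.asarray(actual).astype(bool)
    if pred.shape != act.shape:
        raise DataError("predicted and actual must be equal-length")
    n_pos = int(act.sum())
    n_neg = int((~act).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present in actual")
    return {
        "sensitivity": float(np.sum(pred & act) / n_pos),
        "specificity": float(np.sum(~pred & ~act) / n_neg),
        "accuracy": float(np.mean(pred == act)),
    }


# ------------------------------------------------------- cohort report

_CLINICAL_FEATURES = (
    "gender",
    "age_band",
    "pack_years_band",
    "stage_band",
    "histology",
)


def _tertile_bins(levels: pd.Series) -> pd.Series | None:
    """Tertile-bin continuous levels; None when ties leave < 2 bins."""
    try:
        binned = pd.qcut(levels, q=3, duplicates="drop")
    except ValueError:
        return None
    if binned.nunique() < 2:
        return None
    return binned


def cohort_report(records: pd.DataFrame, threshold: float = 0.05) -> dict:
    """Full cohort evaluation.

    Expects a tidy cohort table (one row per subject) with ``group``
    (cancer/control), the clinical category columns, and per-gene
    ``level_<gene>`` / ``state_<gene>`` columns.  Returns a dict of
    DataFrames/objects:

    - ``group_summary``: per-group per-gene mean level and state frequency
    - ``any_gene``: per-group fraction of subjects with >= 1 methylated gene
    - ``roc``: per-gene ROC/Youden diagnostics on levels
    - ``cart_levels`` / ``cart_states``: fitted trees plus apparent
      confusion metrics
    - ``fisher``: per gene x clinical feature, exact p for states and for
      tertile-binned levels (cancer group only)
    """
    if records.empty:
        raise DataError("empty cohort")
    if "group" not in records.columns:
        raise DataError("cohort table lacks required column 'group'")
    genes = [c.removeprefix("level_") for c in records.columns if c.startswith("level_")]
    if not genes:
        raise DataError("cohort table has no level_<gene> columns")

    df = records.copy()
    for g in genes:
        df[f"state_{g}"] = df[f"level_{g}"] >= threshold

    summary_rows = []
    for group, sub in df.groupby("group"):
        for g in genes:
            summary_rows.append(
                {
                    "group": group,
                    "gene": g,
                    "mean_level": sub[f"level_{g}"].mean(),
                    "state_frequency": sub[f"state_{g}"].mean(),
                    "n": len(sub),
                }
            )
    group_summary = pd.DataFrame(summary_rows)

    any_gene = (
        df.assign(any_methylated=df[[f"state_{g}" for g in genes]].any(axis=1))
        .groupby("group")["any_methylated"]
        .mean()
        .rename("fraction_any_gene_methylated")
        .reset_index()
    )

    labels = (df["group"] == "cancer").to_numpy()
    roc_rows = []
    for g in genes:
        roc = roc_youden(df[f"level_{g}"].to_numpy(), labels)
        roc_rows.append(
            {
                "gene": g,
                "auc": roc.auc,
                "optimal_threshold": roc.youden_optimal_threshold,
                "sensitivity": roc.sensitivity_at_optimum,
                "specificity": roc.specificity_at_optimum,
                "accuracy": roc.accuracy_at_optimum,
            }
        )
    roc_table = pd.DataFrame(roc_rows)

    def _cart(kind: str) -> dict:
        cols = [f"{kind}_{g}" for g in genes]
        X = df[cols].astype(float)
        tree = cart_fit(X, df["group"].to_numpy())
        pred = cart_predict(tree, X)
        metrics = confusion_metrics(pred == "cancer", labels)
        return {"tree": tree, "text": tree_to_text(tree), **metrics}

    cart_levels = _cart("level")
    cart_states = _cart("state")

    cancer = df[df["group"] == "cancer"]
    fisher_rows = []
    for feature in _CLINICAL_FEATURES:
        if feature not in cancer.columns or cancer[feature].nunique() < 2:
            continue
        for g in genes:
            for measure in ("state", "level"):
                if measure == "state":
                    bins = cancer[f"state_{g}"]
                else:
                    bins = _tertile_bins(cancer[f"level_{g}"])
                p = np.nan
                if bins is not None and bins.nunique() >= 2:
                    table = pd.crosstab(bins, cancer[feature])
                    table = table.loc[
                        (table.sum(axis=1) > 0), (table.sum(axis=0) > 0)
                    ]
                    if table.shape[0] >= 2 and table.shape[1] >= 2:
                        try:
                            p = fisher_exact(table.to_numpy())
                        except CapacityError:
                            p = np.nan
                fisher_rows.append(
                    {"clinical_feature": feature, "gene": g, "measure": measure, "p": p}
                )
    fisher_table = pd.DataFrame(fisher_rows)

    return {
        "group_summary": group_summary,
        "any_gene": any_gene,
        "roc": roc_table,
        "cart_levels": cart_levels,
        "cart_states": cart_states,
        "fisher": fisher_table,
    }
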