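"""Instability-panel scoring of expression cohorts.

Implements the expression-side analysis chain: row z-scoring, per-panel
PC1 sample scores, cross-panel Pearson correlation, a clustered heat-map
matrix, and random-forest permutation importance (mean decrease in
accuracy) of panel genes for predicting MDS risk strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeClassifier

from .cohort import SUBTYPES, ExpressionCohort, GenePanel


@dataclass
class PanelScore:
    """Per-sample PC1 projection of a z-scored panel submatrix."""

    panel: str
    scores: pd.Series
    explained_variance_fraction: float
    orientation: int  # +1 or -1, applied to `scores` already


@dataclass
class ImportanceRanking:
    """Permutation-importance ranking of panel genes.

    ``table`` has columns ``mda`` (mean decrease in out-of-bag accuracy)
    and ``rank`` (1 = most important; ties broken by panel gene order).
    """

    panel: str
    table: pd.DataFrame
    n_trees: int
    seed: int
    class_scheme: str

    def rank_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "rank"])


def zscore_rows(cohort: ExpressionCohort) -> ExpressionCohort:
    """Z-score every gene row (population convention, divisor n).

    Zero-variance rows are dropped with a warning; they carry no
    between-sample information and would divide by zero.
    """
    if cohort.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    X = cohort.matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(cohort.matrix.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene row(s): {dropped[:5]}",
            stacklevel=2,
        )
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    matrix = pd.DataFrame(
        Z, index=cohort.matrix.index[keep], columns=cohort.matrix.columns
    )
    return ExpressionCohort(matrix, cohort.labels)


def _panel_submatrix(cohort: ExpressionCohort, panel: GenePanel) -> pd.DataFrame:
    present = [g for g in panel.genes if g in cohort.matrix.index]
    absent = [g for g in panel.genes if g not in cohort.matrix.index]
    if absent:
        warnings.warn(
            f"panel {panel.name!r}: {len(absent)} gene(s) absent from matrix, "
            f"skipped: {absent[:5]}",
            stacklevel=3,
        )
    if len(present) < 2:
        raise ValueError(
            f"panel {panel.name!r}: need >= 2 genes present, found {len(present)}; "
            f"missing {absent}"
        )
    return cohort.matrix.loc[present]


def panel_pc1(cohort: ExpressionCohort, panel: GenePanel) -> PanelScore:
    """First principal component of the z-scored panel submatrix.

    Samples are the observations (columns of the matrix), genes the
    variables. The PC1 sign is fixed so that the scores correlate
    non-negatively with the per-sample mean panel z-score, making the
    reported cross-panel correlation sign reproducible.
    """
    sub = _panel_submatrix(cohort, panel)
    subc = ExpressionCohort(sub, cohort.labels)
    Z = zscore_rows(subc).matrix.to_numpy(dtype=float)  # genes x samples
    X = Z.T  # samples x genes, column means are 0 by construction? (row z-score)
    X = X - X.mean(axis=0, keepdims=True)
    # SVD of the centered sample-by-gene matrix: PC1 scores = U1 * s1
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0] * s[0]
    evf = float(s[0] ** 2 / np.sum(s**2)) if s.size else 0.0
    mean_z = Z.mean(axis=0)
    orientation = 1
    if np.corrcoef(scores, mean_z)[0, 1] < 0:
        orientation = -1
        scores = -scores
    return PanelScore(
        panel=panel.name,
        scores=pd.Series(scores, index=sub.columns, name=f"PC1_{panel.name}"),
        explained_variance_fraction=evf,
        orientation=orientation,
    )


def panel_correlation(a: PanelScore, b: PanelScore) -> tuple[float, float]:
    """Pearson correlation between two panel score vectors.

    Returns ``(r, p)`` with the two-sided p-value from the t distribution
    with n - 2 degrees of freedom.
    """
    if list(a.scores.index) != list(b.scores.index):
        raise ValueError("panel scores cover different samples or orders")
    x = a.scores.to_numpy(dtype=float)
    y = b.scores.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 samples for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance score vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def heatmap_matrix(
    cohort: ExpressionCohort, panel: GenePanel
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-z-scored panel matrix ordered for heat-map display.

    Columns are grouped by subtype in risk order (Control, RA, RARS,
    RAEB1, RAEB2), preserving input order within a subtype; rows are
    ordered by average-linkage hierarchical clustering on
    1 - Pearson-correlation distance.
    """
    sub = _panel_submatrix(cohort, panel)
    Z = zscore_rows(ExpressionCohort(sub, cohort.labels)).matrix

    col_order: list[str] = []
    for subtype in SUBTYPES:
        col_order.extend(cohort.labels.index[cohort.labels == subtype])

    if Z.shape[0] > 2:
        corr = np.corrcoef(Z.to_numpy(dtype=float))
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0, None)
        link = hierarchy.average(squareform(dist, checks=False))
        row_idx = hierarchy.leaves_list(link)
    else:
        row_idx = np.arange(Z.shape[0])
    row_order = [Z.index[i] for i in row_idx]
    return Z.loc[row_order, col_order], row_order, col_order


# ---------------------------------------------------------------------------
# Random-forest permutation importance (mean decrease in accuracy)
# ---------------------------------------------------------------------------


def rf_risk_importance(
    cohort: ExpressionCohort,
    panel: GenePanel,
    n_trees: int = 500,
    seed: int = 0,
    class_scheme: str = "low-high",
) -> ImportanceRanking:
    """Rank panel genes by out-of-bag permutation importance.

    A classification forest (bootstrap sampling with replacement,
    ``sqrt(p)`` features per split, unlimited depth — the defaults of the
    classical randomForest implementation) predicts the per-sample class
    (binary risk stratum by default). For each tree and each gene, the
    out-of-bag accuracy is compared with the accuracy after permuting that
    gene's out-of-bag values; the per-tree differences are averaged into
    the mean decrease in accuracy (MDA). Rank 1 is the largest MDA; ties
    break by panel gene order.
    """
    sub = _panel_submatrix(cohort, panel)
    genes = list(sub.index)
    X = sub.to_numpy(dtype=float).T  # samples x genes
    y = cohort.classes(class_scheme).to_numpy()
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes present")
    counts = np.bincount(y_enc)
    if counts.min() < 2:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has fewer than 2 samples")

    n, p = X.shape
    rng = np.random.default_rng(seed)
    decreases = np.zeros((n_trees, p))
    used = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        used[t] = True
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y_enc[boot])
        # one batched predict: [unpermuted block, one block per permuted gene]
        m = oob.size
        stacked = np.tile(X[oob], (p + 1, 1))
        for j in range(p):
            block = stacked[(j + 1) * m : (j + 2) * m]
            block[:, j] = block[rng.permutation(m), j]
        pred = tree.predict(stacked).reshape(p + 1, m)
        correct = (pred == y_enc[oob]).mean(axis=1)
        decreases[t] = correct[0] - correct[1:]

    n_used = int(used.sum())
    if n_used == 0:  # pragma: no cover - would need n_trees == 0
        raise ValueError("no tree had out-of-bag samples")
    mda = decreases[used].mean(axis=0)
    # stable sort: descending MDA, ties by panel order (the input order)
    order = np.argsort(-mda, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame({"mda": mda, "rank": rank}, index=pd.Index(genes, name="gene"))
    return ImportanceRanking(
        panel=panel.name,
        table=table,
        n_trees=n_trees,
        seed=seed,
        class_scheme=class_scheme,
    )
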