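"""Model evaluation: permutation importance, AUC, paired comparison,
and environmental response curves.

Variable importance follows the classic bagged-forest protocol: each tree
is grown on a bootstrap sample (leaving ~37% of rows out-of-bag), and a
covariate's importance is the drop in out-of-bag accuracy when its values
are permuted among that tree's OOB rows, averaged over trees and
normalized by the standard error (mean decrease in accuracy).  The trees
themselves come from scikit-learn; the bootstrap, OOB bookkeeping,
permutation stream and normalization are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bagged classification trees with out-of-bag bookkeeping


@dataclass
class BaggedForest:
    trees: list
    oob_indices: list          # per tree: row indices never drawn in its bootstrap
    covariate_names: tuple[str, ...]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_accuracy(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-tree accuracy on its own out-of-bag rows."""
        acc = np.empty(self.n_trees)
        for k, (tree, oob) in enumerate(zip(self.trees, self.oob_indices)):
            acc[k] = float(np.mean(tree.predict(X[oob]) == y[oob]))
        return acc


def fit_bagged_trees(
    X: np.ndarray,
    y: np.ndarray,
    covariate_names,
    n_trees: int = 1000,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> BaggedForest:
    """Grow ``n_trees`` classification trees on bootstrap samples.

    Each bootstrap draws n rows with replacement, so about 1/e ~ 37% of the
    rows are out-of-bag for that tree and retained for evaluation.
    Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to fit the forest")
    n = len(y)
    rng = np.random.default_rng(seed)
    trees, oobs = [], []
    for k in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            boot = rng.permutation(n)[: int(0.632 * n)]  # degenerate draw fallback
            oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oobs.append(oob)
    return BaggedForest(trees=trees, oob_indices=oobs, covariate_names=tuple(covariate_names), seed=seed)


def mean_decrease_accuracy(
    forest: BaggedForest, X: np.ndarray, y: np.ndarray, covariate: str, seed: int = 0
) -> float:
    """Normalized permutation importance of one covariate.

    Per tree: OOB accuracy minus OOB accuracy after permuting the
    covariate's values among that tree's OOB rows; the importance is the
    mean over trees divided by its standard error (sd / sqrt(n_trees)).
    A covariate the trees never use gets exactly 0.
    """
    if covariate not in forest.covariate_names:
        raise ValueError(f"covariate {covariate!r} not in the forest")
    j = forest.covariate_names.index(covariate)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    decreases = np.empty(forest.n_trees)
    for k, (tree, oob) in enumerate(zip(forest.trees, forest.oob_indices)):
        Xo = X[oob]
        acc = float(np.mean(tree.predict(Xo) == y[oob]))
        Xp = Xo.copy()
        Xp[:, j] = Xp[rng.permutation(len(oob)), j]
        acc_perm = float(np.mean(tree.predict(Xp) == y[oob]))
        decreases[k] = acc - acc_perm
    mean = float(decreases.mean())
    sd = float(decreases.std(ddof=1)) if forest.n_trees > 1 else 0.0
    if sd == 0.0:
        return 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
    return mean / (sd / np.sqrt(forest.n_trees))


def importance_table(
    forest: BaggedForest, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Mean decrease in accuracy for every covariate, ranked."""
    rows = []
    rng = np.random.default_rng(seed)
    for name in forest.covariate_names:
        rows.append(
            {
                "covariate": name,
                "importance": mean_decrease_accuracy(
                    forest, X, y, name, seed=int(rng.integers(0, 2**31 - 1))
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values("importance", ascending=False)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROC / AUC and paired model comparison


def auc(scores_presence, scores_background) -> float:
    """Mann-Whitney AUC: P(presence score > background score), ties count half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score lists must be nonempty")
    combined = np.concatenate([sp, sb])
    ranks = stats.rankdata(combined)  # average ranks handle ties exactly
    rank_sum = float(ranks[: sp.size].sum())
    u = rank_sum - sp.size * (sp.size + 1) / 2.0
    return u / (sp.size * sb.size)


@dataclass(frozen=True)
class ModelComparison:
    better: str          # "A" | "B" | "tie"
    mean_diff: float     # mean of per-replicate AUC(A) - AUC(B)
    p_value: float


def compare_models(auc_runs_a, auc_runs_b, alpha: float = 0.05) -> ModelComparison:
    """Two-sided paired t-test on per-replicate AUC differences.

    Requires the runs to be paired (same replicate seeds in both sets).
    Identical vectors tie; a constant nonzero shift is a degenerate
    zero-variance case decided by sign with p = 0.
    """
    a = np.asarray(auc_runs_a, dtype=float)
    b = np.asarray(auc_runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired AUC vectors must have identical length")
    d = a - b
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=0), 0.0):
        if mean_diff == 0.0:
            return ModelComparison("tie", 0.0, 1.0)
        return ModelComparison("A" if mean_diff > 0 else "B", mean_diff, 0.0)
    t = stats.ttest_rel(a, b)
    p = float(t.pvalue)
    if p >= alpha:
        return ModelComparison("tie", mean_diff, p)
    return ModelComparison("A" if mean_diff > 0 else "B", mean_diff, p)


# ---------------------------------------------------------------------------
# response curves


@dataclass
class ResponseCurve:
    """Sampled (dwt, probability) points with binned means and a spline trend."""

    dwt: np.ndarray
    probability: np.ndarray
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_means: np.ndarray        # NaN for empty bins
    spline_x: np.ndarray
    spline_y: np.ndarray

    def half_maximum_dwt(self) -> float:
        """Depth at which the spline trend first falls to half its maximum."""
        y = self.spline_y
        target = y.max() / 2.0
        below = np.nonzero(y <= target)[0]
        start = int(np.argmax(y))
        below = below[below >= start]
        if below.size == 0:
            return float(self.spline_x[-1])
        i = below[0]
        if i == 0:
            return float(self.spline_x[0])
        # linear interpolation between the bracketing spline samples
        x0, x1 = self.spline_x[i - 1], self.spline_x[i]
        y0, y1 = y[i - 1], y[i]
        if y1 == y0:
            return float(x1)
        return float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))


def response_curve(
    surface: np.ndarray,
    dwt_layer: np.ndarray,
    n: int = 1000,
    n_bins: int = 20,
    seed: int = 0,
    spline_points: int = 200,
) -> ResponseCurve:
    """Probability-vs-depth trend from random points on a prediction surface.

    Samples ``n`` valid cells uniformly without replacement, bins their
    depths into ``n_bins`` equal-width bins, and fits a cubic smoothing
    spline (smoothing chosen by generalized cross-validation) to the bin
    means.  Deterministic given the seed.
    """
    surface = np.asarray(surface, dtype=float)
    dwt_layer = np.asarray(dwt_layer, dtype=float)
    if surface.shape != dwt_layer.shape:
        raise ValueError("surface and dwt layer must be co-registered")
    valid = np.isfinite(surface) & np.isfinite(dwt_layer)
    idx = np.nonzero(valid.ravel())[0]
    if idx.size == 0:
        raise ValueError("no valid cells")
    if n > idx.size:
        logger.warning("requested %d points but only %d valid cells; taking all", n, idx.size)
        n = idx.size
    rng = np.random.default_rng(seed)
    take = rng.choice(idx, size=n, replace=False)
    d = dwt_layer.ravel()[take]
    p = surface.ravel()[take]

    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            means[b] = p[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])

    ok = np.isfinite(means)
    xs = centers[ok]
    ys = means[ok]
    spline_x = np.linspace(xs.min(), xs.max(), spline_points)
    if xs.size >= 5:
        spline = make_smoothing_spline(xs, ys)  # GCV-selected smoothing
        spline_y = spline(spline_x)
    else:  # too few bins for a spline; fall back to linear interpolation
        spline_y = np.interp(spline_x, xs, ys)
    return ResponseCurve(
        dwt=d,
        probability=p,
        bin_edges=edges,
        bin_centers=centers,
        bin_means=means,
        spline_x=spline_x,
        spline_y=spline_y,
    )
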