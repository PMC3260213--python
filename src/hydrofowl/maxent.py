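"""Presence-background maximum-entropy species distribution model.

Given presence cells and background cells described by environmental
covariates, the model estimates the Gibbs distribution

    q(x) = exp(lambda . f(x)) / Z

over the background that maximizes the L1-penalized log-likelihood of the
presences,

    (1/m) sum_i lambda . f(x_i)  -  log Z(lambda)  -  sum_j beta_j |lambda_j|,

where f are features derived from the covariates (linear, quadratic,
product and hinge classes, each affinely scaled to [0, 1] over the fitting
cells) and the per-feature penalties beta_j shrink toward the uniform
distribution.  The penalty relaxes the defining maximum-entropy constraint
"fitted feature expectations equal presence means" into a band of width
beta_j, which is what makes the estimate robust at small sample sizes.

The logistic output ``p = e^H q / (1 + e^H q)`` (H the entropy of the
fitted distribution, implying a default prevalence of 0.5) is the
"probability of occurrence" scale used for maps and response curves; the
raw ``q`` is retained for diagnostics and model evaluation.

Fitting uses monotone proximal-gradient ascent with backtracking (ISTA);
the objective never decreases and the fit is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .background import sample_background

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

# Per-class regularization rates interpolated by presence sample size,
# following the defaults of the reference maxent implementation.
_BETA_TABLES = {
    "linear": ((10, 30, 100), (1.0, 0.2, 0.05)),
    "quadratic": ((10, 17, 30, 100), (1.3, 0.8, 0.5, 0.05)),
    "product": ((10, 30, 100), (2.6, 1.6, 0.9)),
    "hinge": ((0, 100), (0.5, 0.5)),
}


class MaxentConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


def auto_feature_classes(n_presences: int) -> tuple[str, ...]:
    """Feature classes enabled at a given presence sample size."""
    classes = ["linear"]
    if n_presences >= 10:
        classes.append("quadratic")
    if n_presences >= 15:
        classes.append("hinge")
    if n_presences >= 80:
        classes.append("product")
    return tuple(classes)


def beta_rate(feature_class: str, n_presences: int) -> float:
    xs, ys = _BETA_TABLES[feature_class]
    return float(np.interp(n_presences, xs, ys))


@dataclass
class FeatureSet:
    """Covariate scaling bounds plus the derived feature expansion."""

    covariate_names: tuple[str, ...]
    bounds: np.ndarray              # (n_cov, 2) min/max over the fitting cells
    classes: tuple[str, ...]
    n_hinge_knots: int = 10
    dropped: tuple[str, ...] = ()   # constant covariates, excluded

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        self._build_labels()

    def _build_labels(self) -> None:
        names = self.covariate_names
        labels: list[str] = []
        kinds: list[str] = []
        if "linear" in self.classes:
            labels += [f"lin({n})" for n in names]
            kinds += ["linear"] * len(names)
        if "quadratic" in self.classes:
            labels += [f"quad({n})" for n in names]
            kinds += ["quadratic"] * len(names)
        if "product" in self.classes:
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    labels.append(f"prod({names[i]},{names[j]})")
                    kinds.append("product")
        if "hinge" in self.classes:
            knots = self._knots()
            for orient in ("fwd", "rev"):
                for n in names:
                    for t in knots:
                        labels.append(f"hinge_{orient}({n},{t:.2f})")
                        kinds.append("hinge")
        self.feature_labels = tuple(labels)
        self.feature_classes_per_column = tuple(kinds)

    def _knots(self) -> np.ndarray:
        k = self.n_hinge_knots
        return np.arange(1, k + 1) / (k + 1)  # strictly inside (0, 1)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Affine rescale of raw covariates to [0,1], clamped to the bounds."""
        X = np.asarray(X, dtype=float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return np.clip((X - lo) / (hi - lo), 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Feature matrix (n_cells x n_features), each column in [0, 1]."""
        Z = self.scale(X)
        cols: list[np.ndarray] = []
        if "linear" in self.classes:
            cols.append(Z)
        if "quadratic" in self.classes:
            cols.append(Z**2)
        if "product" in self.classes:
            n = Z.shape[1]
            prods = [Z[:, i] * Z[:, j] for i in range(n) for j in range(i + 1, n)]
            if prods:
                cols.append(np.column_stack(prods))
        if "hinge" in self.classes:
            knots = self._knots()
            fwd = np.clip((Z[:, :, None] - knots) / (1.0 - knots), 0.0, None)
            rev = np.clip((knots - Z[:, :, None]) / knots, 0.0, None)
            cols.append(fwd.reshape(len(Z), -1))
            cols.append(rev.reshape(len(Z), -1))
        return np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])


def build_features(
    X: np.ndarray,
    covariate_names: Sequence[str],
    classes: str | Sequence[str] = "auto",
    n_presences: int | None = None,
    n_hinge_knots: int = 10,
) -> FeatureSet:
    """Derive the feature expansion from covariates at the fitting cells.

    With ``classes='auto'`` the enabled classes follow the presence sample
    size: linear always; quadratic from 10; hinge from 15; product from 80.
    Constant covariates are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D covariate matrix with at least 2 cells")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite over the fitting cells")
    if classes == "auto":
        if n_presences is None:
            raise ValueError("auto feature classes require n_presences")
        classes = auto_feature_classes(n_presences)
    else:
        classes = tuple(classes)
        unknown = set(classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    keep = hi > lo
    names = tuple(covariate_names)
    if not keep.all():
        dropped = tuple(n for n, k in zip(names, keep) if not k)
        logger.warning("dropping constant covariates: %s", ", ".join(dropped))
        names = tuple(n for n, k in zip(names, keep) if k)
        lo, hi = lo[keep], hi[keep]
    else:
        dropped = ()
    if len(names) == 0:
        raise ValueError("all covariates are constant over the fitting cells")
    return FeatureSet(
        covariate_names=names,
        bounds=np.column_stack([lo, hi]),
        classes=tuple(classes),
        n_hinge_knots=n_hinge_knots,
        dropped=dropped,
    )


@dataclass
class MaxentModel:
    """Fitted weights plus everything needed to predict on new cells."""

    feature_set: FeatureSet
    covariate_names: tuple[str, ...]
    weights: np.ndarray          # lambda, one per feature
    beta: np.ndarray             # per-feature L1 penalty actually used
    log_z: float                 # normalizer over the fitting background
    entropy: float               # H of the fitted distribution q
    n_presences: int
    iterations: int
    objective: float             # final penalized objective
    objective_trace: list = field(default_factory=list, repr=False)

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = [self.covariate_names.index(n) for n in self.feature_set.covariate_names]
        return self.feature_set.transform(X[:, cols])

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Gibbs density q(x) relative to the fitting background (sums to 1 there)."""
        return np.exp(self._features(X) @ self.weights - self.log_z)

    def predict_logistic(self, X: np.ndarray) -> np.ndarray:
        """Probability-of-occurrence output at default prevalence 0.5."""
        qe = np.exp(
            self._features(X) @ self.weights - self.log_z + self.entropy
        )
        return qe / (1.0 + qe)


def _smooth_objective(lam, F_bg, f_mean_pres):
    log_z = float(logsumexp(F_bg @ lam))
    return float(f_mean_pres @ lam) - log_z, log_z


def fit_maxent(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    covariate_names: Sequence[str],
    classes: str | Sequence[str] = "auto",
    beta_multiplier: float = 1.0,
    beta: np.ndarray | float | None = None,
    tol: float = 1e-5,
    max_iter: int = 5000,
    feature_set: FeatureSet | None = None,
) -> MaxentModel:
    """Fit the L1-regularized maxent model.

    ``X_background`` is the normalization set and should contain the
    presence cells (samples-with-data convention; the replicate protocol
    arranges this).  ``beta`` overrides the per-feature penalties directly;
    otherwise ``beta_j = beta_multiplier * rate(class, m) * sd(f_j) / sqrt(m)``
    with the class-specific rate interpolated by presence count m.

    Raises
    ------
    MaxentConvergenceError
        If the objective improvement has not dropped below ``tol`` within
        ``max_iter`` iterations (carries the objective trace).
    """
    X_presence = np.atleast_2d(np.asarray(X_presence, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    m = len(X_presence)
    if m == 0:
        raise ValueError("need at least one presence")
    if len(X_background) < 2:
        raise ValueError("need at least two background cells")

    if feature_set is None:
        X_fit = np.vstack([X_background, X_presence])
        feature_set = build_features(
            X_fit, covariate_names, classes=classes, n_presences=m
        )
    cols = [list(covariate_names).index(n) for n in feature_set.covariate_names]
    F_bg = feature_set.transform(X_background[:, cols])
    F_pres = feature_set.transform(X_presence[:, cols])
    n_feat = feature_set.n_features
    f_mean_pres = F_pres.mean(axis=0)

    if beta is None:
        rates = np.array(
            [beta_rate(k, m) for k in feature_set.feature_classes_per_column]
        )
        sd = F_bg.std(axis=0, ddof=0)
        beta_vec = beta_multiplier * rates * sd / np.sqrt(m)
    else:
        beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (n_feat,)).copy()
    if np.any(beta_vec < 0):
        raise ValueError("beta must be non-negative")

    lam = np.zeros(n_feat)
    smooth, log_z = _smooth_objective(lam, F_bg, f_mean_pres)
    obj = smooth - float(beta_vec @ np.abs(lam))
    trace = [obj]
    step = 1.0
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        w = F_bg @ lam
        q = np.exp(w - logsumexp(w))
        grad = f_mean_pres - q @ F_bg
        # monotone ISTA with backtracking on the concave smooth part
        for _ in range(60):
            lam_new = lam + step * grad
            lam_new = np.sign(lam_new) * np.maximum(np.abs(lam_new) - step * beta_vec, 0.0)
            delta = lam_new - lam
            smooth_new, log_z_new = _smooth_objective(lam_new, F_bg, f_mean_pres)
            if smooth_new >= smooth + grad @ delta - (delta @ delta) / (2.0 * step):
                break
            step *= 0.5
        obj_new = smooth_new - float(beta_vec @ np.abs(lam_new))
        improvement = obj_new - obj
        lam, smooth, log_z, obj = lam_new, smooth_new, log_z_new, obj_new
        trace.append(obj)
        step *= 1.2  # cautiously re-grow the step after successful moves
        if 0 <= improvement < tol:
            converged = True
            break
    if not converged:
        raise MaxentConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(last improvement {improvement:.3g})",
            trace=trace,
        )

    q = np.exp(F_bg @ lam - log_z)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    return MaxentModel(
        feature_set=feature_set,
        covariate_names=tuple(covariate_names),
        weights=lam,
        beta=beta_vec,
        log_z=log_z,
        entropy=entropy,
        n_presences=m,
        iterations=iteration,
        objective=obj,
        objective_trace=trace,
    )


def predict_surface(model: MaxentModel, layers: dict, output: str = "logistic") -> np.ndarray:
    """Grid-aligned prediction surface; NaN wherever any covariate is NaN."""
    shape = next(iter(layers.values())).shape
    X = np.column_stack([np.asarray(layers[n], dtype=float).ravel() for n in model.covariate_names])
    valid = np.all(np.isfinite(X), axis=1)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        fn = model.predict_logistic if output == "logistic" else model.predict_raw
        out[valid] = fn(X[valid])
    return out.reshape(shape)


@dataclass
class ReplicateResult:
    run: int
    seed: int
    auc: float
    model: MaxentModel


def replicate_fit(
    presence_cells: Sequence,
    background_candidates: Sequence,
    values_at: Callable[[Sequence], np.ndarray],
    covariate_names: Sequence[str],
    n_runs: int = 100,
    train_frac: float = 0.7,
    n_background: int = 10_000,
    classes: str | Sequence[str] = "auto",
    beta_multiplier: float = 1.0,
    seed: int = 0,
    min_success: float = 0.9,
) -> list[ReplicateResult]:
    """The replicated evaluation protocol: randomized splits and backgrounds.

    Each of ``n_runs`` runs draws a fresh 70-30 split of the presence cells
    and a fresh background sample, fits on the training portion and scores
    the held-out presences against the background by AUC.  Run seeds are a
    pure function of the master seed, so two covariate sets evaluated with
    the same seed see identical splits and backgrounds (paired runs).
    """
    from .evaluate import auc as auc_fn

    presence_cells = list(presence_cells)
    if len(presence_cells) < 10:
        raise ValueError("replicate protocol needs at least 10 presence cells")
    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=n_runs)
    results: list[ReplicateResult] = []
    failures: list[tuple[int, Exception]] = []
    for run, run_seed in enumerate(run_seeds):
        rng = np.random.default_rng(run_seed)
        try:
            order = rng.permutation(len(presence_cells))
            n_train = max(1, int(round(train_frac * len(presence_cells))))
            train = [presence_cells[i] for i in order[:n_train]]
            test = [presence_cells[i] for i in order[n_train:]]
            if not test:
                raise ValueError("empty test split")
            bg = sorted(
                sample_background(
                    background_candidates,
                    min(n_background, len(background_candidates)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            X_train = values_at(train)
            X_bg = values_at(bg)
            model = fit_maxent(
                X_train,
                np.vstack([X_bg, X_train]),  # samples-with-data normalization
                covariate_names,
                classes=classes,
                beta_multiplier=beta_multiplier,
            )
            scores_test = model.predict_raw(values_at(test))
            scores_bg = model.predict_raw(X_bg)
            results.append(
                ReplicateResult(run=run, seed=int(run_seed), auc=auc_fn(scores_test, scores_bg), model=model)
            )
        except Exception as exc:  # single-run failures recorded, run skipped
            failures.append((run, exc))
            logger.warning("replicate %d failed: %s", run, exc)
    if len(results) < min_success * n_runs:
        raise RuntimeError(
            f"only {len(results)}/{n_runs} replicates succeeded; first failure: "
            f"{failures[0][1] if failures else 'n/a'}"
        )
    return results
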