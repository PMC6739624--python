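"""Base feature rankers and the accuracy-producing classifier.

Three heterogeneous selectors map a training split (beta matrix + binary
labels) to a nonnegative per-locus weight vector, max-normalized to [0, 1]:

``elastic_net_rank``
    Penalized least squares on standardized features with labels coded {0,1}:

        argmin_w  sum_i (y_i - w'x_i)^2 + lambda [ alpha ||w||_1 + (1-alpha) ||w||_2^2 ]

    The ranking weight of locus j is |w_j|.  The L1 component makes the vector
    sparse: loci the model does not use get weight exactly 0.

``info_gain_rank``
    Information gain of the class given the beta value discretized into
    equal-width bins on [0, 1] (base-2 logs, 0*log 0 = 0).  Because a plug-in
    information-gain estimate is positively biased at small n, loci whose
    G-statistic (2 N ln2 * IG, asymptotically chi-square) is not significant
    after Benjamini-Hochberg control are zeroed; pass ``ig_fdr=None`` for the
    raw estimate.

``mc_subspace_rank``
    A Monte Carlo random-subspace selector: repeatedly draw small random locus
    subspaces, grow decision trees on bootstrap resamples, and credit each
    locus with its impurity-decrease share weighted by the tree's out-of-bag
    balanced accuracy, averaged over the subspaces that contained it.  A
    shadow run with permuted labels sets a null cutoff below which relative
    importances are zeroed, so uninformative loci do not accumulate weight.

``svm_accuracy`` trains a linear soft-margin SVM on a locus subset and returns
held-out accuracy; the ensemble uses it to weight each selector's ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import MethylationMatrix, SampleLabels, ValidationError

__all__ = [
    "SelectorConfig",
    "FeatureRanking",
    "elastic_net_rank",
    "info_gain_rank",
    "mc_subspace_rank",
    "svm_accuracy",
    "SELECTOR_NAMES",
]


@dataclass
class SelectorConfig:
    """Tunables for the three base selectors and the SVM.

    enet_alpha : L1/L2 mixing in [0, 1] (1 = lasso, 0 = ridge); default 0.5.
    enet_lambda : penalty strength, or "auto" for internal 5-fold CV with the
        one-standard-error rule on the training split only.
    ig_bins : equal-width bins on [0, 1] for discretization; default 10.
    ig_fdr : BH level for the information-gain significance screen; ``None``
        disables the screen (raw plug-in estimate).  The default (0.01) is
        deliberately stricter than a stand-alone analysis would use because
        the ensemble unions the screen's rejections over ~10 highly correlated
        cross-validation folds per iteration, which inflates the effective
        false-discovery rate of the unioned set several-fold.
    mc_subspaces / mc_subspace_size / mc_trees : number of random subspaces,
        loci per subspace (default ceil(sqrt(p))*5 capped at p), and bootstrap
        trees per subspace.
    mc_null_quantile : quantile of the permuted-label importances used as the
        null cutoff (1.0 = max, Boruta-style).
    svm_c : soft-margin constant of the linear SVM.
    svm_class_weight : ``None`` (default, no class weighting) or "balanced".
    logistic : solve the elastic net with logistic instead of squared loss.
    """

    enet_alpha: float = 0.5
    enet_lambda: float | str = "auto"
    enet_cv_folds: int = 5
    enet_n_lambdas: int = 20
    ig_bins: int = 10
    ig_fdr: float | None = 0.01
    mc_subspaces: int = 300
    mc_subspace_size: int | None = None
    mc_trees: int = 1
    mc_null_quantile: float = 1.0
    svm_c: float = 1.0
    svm_class_weight: str | None = None
    logistic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.enet_alpha <= 1.0:
            raise ValueError("enet_alpha must be in [0, 1]")
        if isinstance(self.enet_lambda, str):
            if self.enet_lambda != "auto":
                raise ValueError("enet_lambda must be a number or 'auto'")
        elif self.enet_lambda < 0:
            raise ValueError("enet_lambda must be >= 0")
        if self.ig_bins < 2:
            raise ValueError("ig_bins must be >= 2")
        for name in ("enet_cv_folds", "enet_n_lambdas", "mc_subspaces", "mc_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")


@dataclass
class FeatureRanking:
    """One selector's nonnegative, max-normalized per-locus weights."""

    selector_name: str
    locus_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.locus_ids),):
            raise ValidationError("one weight per locus required")
        if (self.weights < 0).any():
            raise ValidationError("ranking weights must be nonnegative")

    @classmethod
    def from_raw(
        cls, selector_name: str, locus_ids: Sequence[str], raw: np.ndarray
    ) -> "FeatureRanking":
        """Max-normalize |raw| to [0, 1] (all-zero vectors stay all-zero)."""
        w = np.abs(np.asarray(raw, dtype=float))
        top = w.max(initial=0.0)
        if top > 0:
            w = w / top
        return cls(selector_name, list(locus_ids), w)

    def top_loci(self, n: int) -> list[str]:
        """The n loci with largest weight; ties broken by lexicographic id."""
        order = sorted(range(len(self.locus_ids)),
                       key=lambda i: (-self.weights[i], self.locus_ids[i]))
        return [self.locus_ids[i] for i in order[:n]]

    def supported_loci(self, tau: float) -> list[str]:
        return [l for l, w in zip(self.locus_ids, self.weights) if w >= tau]


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _check_supervised(mat: MethylationMatrix, labels: SampleLabels) -> np.ndarray:
    labels = labels.aligned_to(mat)
    labels.require_both_classes()
    if np.isnan(mat.values).any():
        raise ValidationError("selectors require a complete (imputed) matrix")
    return labels.labels.astype(float)


# ---------------------------------------------------------------------------
# elastic net


def _sklearn_enet(X: np.ndarray, y: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    """Solve the printed objective via sklearn's (1/2m)-scaled parameterization."""
    m = X.shape[0]
    if alpha == 0.0:
        p = X.shape[1]
        return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
    a = lam * (2.0 - alpha) / (2.0 * m)
    l1_ratio = alpha / (2.0 - alpha)
    est = ElasticNet(alpha=a, l1_ratio=l1_ratio, fit_intercept=False,
                     max_iter=20000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est.coef_


def lasso_null_lambda(X: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> float:
    """Smallest penalty at which w = 0 solves the objective (alpha > 0)."""
    if alpha <= 0:
        raise ValueError("null threshold requires alpha > 0")
    return 2.0 * np.abs(X.T @ y).max() / alpha


def _path_coefs(
    X: np.ndarray, y: np.ndarray, grid: np.ndarray, alpha: float
) -> np.ndarray:
    """Coefficients (p × n_lambdas) along a decreasing lambda grid."""
    m, p = X.shape
    if alpha == 0.0:
        # ridge path via one SVD per design
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        uty = U.T @ y
        return Vt.T @ (s[:, None] * uty[:, None] / (s[:, None] ** 2 + grid[None, :]))
    from sklearn.linear_model import enet_path

    a = grid * (2.0 - alpha) / (2.0 * m)
    l1_ratio = alpha / (2.0 - alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(X, y, l1_ratio=l1_ratio, alphas=a, tol=1e-4)
    return coefs


def _auto_lambda(
    X: np.ndarray, y: np.ndarray, cfg: SelectorConfig, y_int: np.ndarray
) -> float:
    """Internal k-fold CV on a log grid down from the null threshold; 1-SE rule."""
    from sklearn.model_selection import StratifiedKFold

    anchor_alpha = cfg.enet_alpha if cfg.enet_alpha > 0 else 1.0
    lam_max = lasso_null_lambda(X, y, anchor_alpha)
    if lam_max <= 0:
        return 1.0
    # lambda floor 0.01*lam_max: the p >> n convention of penalized-path solvers
    grid = lam_max * np.logspace(0, -2, cfg.enet_n_lambdas)
    n_splits = min(cfg.enet_cv_folds, int(np.bincount(y_int).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=0)
    mse = np.empty((n_splits, len(grid)))
    for f, (tr, va) in enumerate(skf.split(X, y_int)):
        coefs = _path_coefs(X[tr], y[tr], grid, cfg.enet_alpha)
        resid = y[va][:, None] - X[va] @ coefs
        mse[f] = np.mean(resid**2, axis=0)
    mean = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(n_splits)
    best = int(np.argmin(mean))
    ok = np.flatnonzero(mean <= mean[best] + se[best])
    return float(grid[ok[0]])  # grid is decreasing: first ok entry = largest lambda


def elastic_net_rank(
    mat: MethylationMatrix, labels: SampleLabels, cfg: SelectorConfig | None = None
) -> FeatureRanking:
    """Rank loci by |w_j| of the elastic-net fit (squared loss as printed).

    Features are standardized and labels coded {0, 1}; the penalty enters
    exactly as written, with no 1/m or 1/2 scaling.  ``enet_lambda="auto"``
    runs internal cross-validation on the training split only.  Deterministic
    given the configuration and data.
    """
    cfg = cfg or SelectorConfig()
    y = _check_supervised(mat, labels)
    X = _standardize(mat.X)
    m, p = X.shape
    lam = cfg.enet_lambda
    if lam == "auto":
        lam = _auto_lambda(X, y, cfg, labels.aligned_to(mat).labels)
    if lam == 0 and p > m:
        raise ValidationError(
            "lambda = 0 with more loci than samples: unpenalized fit is underdetermined"
        )
    if cfg.logistic:
        # logistic-loss variant: C = 1/lambda, same L1/L2 mixing
        est = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=cfg.enet_alpha,
            C=1.0 / max(lam, 1e-12), fit_intercept=True, max_iter=5000, tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y.astype(int))
        coef = est.coef_.ravel()
    else:
        coef = _sklearn_enet(X, y, float(lam), cfg.enet_alpha)
    return FeatureRanking.from_raw("elastic_net", mat.locus_ids, coef)


# ---------------------------------------------------------------------------
# information gain


def _entropy_bits(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    tot = counts.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
    return -xlogy(p, p).sum(axis=axis) / np.log(2)


def info_gain_raw(
    values: np.ndarray, y: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in IG (bits) per locus and the occupied-bin count, vectorized.

    ``values`` is loci × samples in [0, 1]; bins are equal-width on [0, 1].
    """
    p, n = values.shape
    bins = np.clip((values * n_bins).astype(int), 0, n_bins - 1)
    flat = (np.arange(p)[:, None] * (2 * n_bins) + bins * 2 + y[None, :]).ravel()
    counts = np.bincount(flat, minlength=p * 2 * n_bins).reshape(p, n_bins, 2)
    h_class = float(_entropy_bits(np.bincount(y, minlength=2).astype(float)))
    bin_tot = counts.sum(axis=2)  # (p, n_bins)
    h_cond_per_bin = _entropy_bits(counts.astype(float), axis=2)  # (p, n_bins)
    h_cond = (bin_tot / n * h_cond_per_bin).sum(axis=1)
    ig = np.maximum(h_class - h_cond, 0.0)
    occupied = (bin_tot > 0).sum(axis=1)
    return ig, occupied


def info_gain_rank(
    mat: MethylationMatrix, labels: SampleLabels, cfg: SelectorConfig | None = None
) -> FeatureRanking:
    """Rank loci by class information gain over equal-width beta bins.

    With ``cfg.ig_fdr`` set (default 0.05), loci whose G-statistic is not
    BH-significant are zeroed before max-normalization, emulating the
    significance screen a dedicated information-gain selector applies.
    """
    cfg = cfg or SelectorConfig()
    _check_supervised(mat, labels)
    y = labels.aligned_to(mat).labels
    ig, occupied = info_gain_raw(mat.values, y, cfg.ig_bins)
    if cfg.ig_fdr is not None:
        n = mat.n_samples
        g_stat = 2.0 * n * np.log(2) * ig
        dof = np.maximum(occupied - 1, 1)
        pvals = chi2.sf(g_stat, dof)
        pvals[occupied <= 1] = 1.0
        ig = np.where(_bh_reject(pvals, cfg.ig_fdr), ig, 0.0)
    return FeatureRanking.from_raw("info_gain", mat.locus_ids, ig)


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg rejection mask."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = q * (np.arange(1, m + 1) / m)
    below = np.flatnonzero(ranked <= thresh)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


# ---------------------------------------------------------------------------
# Monte Carlo random-subspace selector


def _balanced_accuracy(truth: np.ndarray, pred: np.ndarray) -> float:
    recalls = [
        float((pred[truth == c] == c).mean()) for c in np.unique(truth)
    ]
    return float(np.mean(recalls))


def _mc_accumulate(
    X: np.ndarray, y: np.ndarray, cfg: SelectorConfig, m_mc: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One pass of subspace × bootstrap-tree importance accumulation."""
    m, p = X.shape
    scores = np.zeros(p)
    appearances = np.zeros(p)
    for _ in range(cfg.mc_subspaces):
        sub = rng.choice(p, size=m_mc, replace=False)
        appearances[sub] += 1
        for _ in range(cfg.mc_trees):
            boot = rng.integers(0, m, size=m)
            oob = np.setdiff1d(np.arange(m), boot)
            tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31)))
            tree.fit(X[boot][:, sub], y[boot])
            if oob.size == 0:
                continue
            acc = _balanced_accuracy(y[oob], tree.predict(X[oob][:, sub]))
            scores[sub] += acc * tree.feature_importances_
    return scores / np.maximum(appearances, 1.0)


def mc_subspace_rank(
    mat: MethylationMatrix,
    labels: SampleLabels,
    cfg: SelectorConfig | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Monte Carlo random-subspace ranking with a permutation null cutoff.

    Each locus accumulates (out-of-bag balanced accuracy) × (impurity-decrease
    share) over the subspaces containing it; the relative importance is that
    sum divided by the number of containing subspaces.  A second pass with
    permuted labels yields a null importance distribution whose
    ``mc_null_quantile`` (default: max) is subtracted as a hard cutoff.
    Reproducible given ``seed``.
    """
    cfg = cfg or SelectorConfig()
    _check_supervised(mat, labels)
    y = labels.aligned_to(mat).labels
    X = mat.X
    p = mat.n_loci
    m_mc = cfg.mc_subspace_size
    if m_mc is None:
        m_mc = min(p, int(np.ceil(np.sqrt(p)) * 5))
    if m_mc > p:
        raise ValidationError(f"subspace size {m_mc} exceeds locus count {p}")
    rng = np.random.default_rng(seed)
    rel = _mc_accumulate(X, y, cfg, m_mc, rng)
    y_perm = rng.permutation(y)
    rel_null = _mc_accumulate(X, y_perm, cfg, m_mc, rng)
    cutoff = float(np.quantile(rel_null, cfg.mc_null_quantile))
    rel = np.where(rel > cutoff, rel, 0.0)
    return FeatureRanking.from_raw("mc_subspace", mat.locus_ids, rel)


# ---------------------------------------------------------------------------
# SVM accuracy


def svm_accuracy(
    mat_train: MethylationMatrix,
    labels_train: SampleLabels,
    mat_test: MethylationMatrix,
    labels_test: SampleLabels,
    loci: Sequence[str],
    cfg: SelectorConfig | None = None,
) -> float:
    """Held-out accuracy of a linear soft-margin SVM on a locus subset.

    Features are standardized with training-set statistics.  Deterministic
    for fixed inputs.
    """
    cfg = cfg or SelectorConfig()
    loci = list(loci)
    if not loci:
        raise ValidationError("svm_accuracy requires a non-empty locus subset")
    ytr = labels_train.aligned_to(mat_train)
    ytr.require_both_classes()
    yte = labels_test.aligned_to(mat_test)
    Xtr = mat_train.subset_loci(loci).X
    Xte = mat_test.subset_loci(loci).X
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=cfg.svm_c, class_weight=cfg.svm_class_weight)
    clf.fit((Xtr - mu) / sd, ytr.labels)
    pred = clf.predict((Xte - mu) / sd)
    return float((pred == yte.labels).mean())


SELECTOR_NAMES = ("elastic_net", "info_gain", "mc_subspace")


def run_selector(
    name: str,
    mat: MethylationMatrix,
    labels: SampleLabels,
    cfg: SelectorConfig,
    seed: int = 0,
) -> FeatureRanking:
    """Dispatch a selector by name (mc_subspace is the only seeded one)."""
    if name == "elastic_net":
        return elastic_net_rank(mat, labels, cfg)
    if name == "info_gain":
        return info_gain_rank(mat, labels, cfg)
    if name == "mc_subspace":
        return mc_subspace_rank(mat, labels, cfg, seed=seed)
    raise ValueError(f"unknown selector {name!r}; choose from {SELECTOR_NAMES}")
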