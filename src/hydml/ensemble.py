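"""The HyDML orchestration: fold splitting, aggregation, and bagging consensus.

One iteration draws stratified k-folds (default 10).  For each fold the held-in
samples train every base selector; each selector's ranking is accuracy-weighted
by a linear SVM evaluated on the held-out fold (using the loci the selector
itself supports at the weight threshold), and the weighted rankings are summed:

    f_j = sum_i acc_i * f_ij

Loci with aggregated weight below the threshold tau (default 0.01) are dropped;
the per-fold survivors are unioned across folds, summing weights, to give one
locus set per iteration.  After T iterations (default 10, each with fresh
folds) a bagging consensus keeps loci recurring in at least c iterations
(default 5).  The whole run is reproducible from a single master seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import DMLSet, MethylationMatrix, SampleLabels, ValidationError
from .selectors import (
    SELECTOR_NAMES,
    FeatureRanking,
    SelectorConfig,
    run_selector,
    svm_accuracy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "FoldResult",
    "HyDMLResult",
    "iteration_seed",
    "stratified_folds",
    "aggregate_fold",
    "threshold_filter",
    "union_folds",
    "bagging_select",
    "run_hydml",
]


@dataclass
class EnsembleConfig:
    """Pipeline constants: k folds, T iterations, weight threshold, bagging count."""

    n_folds: int = 10
    n_iterations: int = 10
    weight_threshold: float = 0.01
    bagging_min_count: int = 5
    selectors: tuple[str, ...] = SELECTOR_NAMES
    selector_config: SelectorConfig = field(default_factory=SelectorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 1 <= self.bagging_min_count <= self.n_iterations:
            raise ValueError("bagging_min_count must be in [1, n_iterations]")
        if self.weight_threshold < 0:
            raise ValueError("weight_threshold must be >= 0")
        if isinstance(self.selectors, list):
            self.selectors = tuple(self.selectors)
        unknown = set(self.selectors) - set(SELECTOR_NAMES)
        if not self.selectors or unknown:
            raise ValueError(f"selectors must be a non-empty subset of {SELECTOR_NAMES}")


@dataclass
class FoldResult:
    """Everything one fold produced: rankings, accuracies, aggregate, survivors."""

    iteration: int
    fold_index: int
    rankings: dict[str, FeatureRanking]
    accuracies: dict[str, float]
    aggregated: np.ndarray
    surviving: set[str]


@dataclass
class HyDMLResult:
    final: DMLSet
    iteration_sets: list[DMLSet]
    fold_results: list[FoldResult]
    config: EnsembleConfig


def iteration_seed(master_seed: int, t: int) -> int:
    """Deterministic per-iteration seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(t)]).generate_state(1)[0] % (2**31))


def _fold_seed(master_seed: int, t: int, fold: int, tag: int = 0) -> int:
    return int(
        np.random.SeedSequence([int(master_seed), int(t), int(fold), int(tag)])
        .generate_state(1)[0] % (2**31)
    )


def stratified_folds(
    labels: SampleLabels | np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Partition sample indices into k disjoint, class-stratified folds.

    Per class, shuffled members are dealt round-robin onto the folds with a
    cumulative offset, so fold sizes differ by at most one and each fold's
    class counts are within one of proportional.  Classes smaller than k are
    simply absent from some folds.  Reproducible given ``seed``.
    """
    y = labels.labels if isinstance(labels, SampleLabels) else np.asarray(labels, int)
    n = len(y)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise ValidationError(f"class {cls} has no samples")
        rng.shuffle(idx)
        for i, s in enumerate(idx):
            folds[(offset + i) % k].append(int(s))
        offset += idx.size
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def aggregate_fold(
    rankings: Sequence[FeatureRanking], accs: Sequence[float]
) -> np.ndarray:
    """Accuracy-weighted sum of selector rankings: f_j = sum_i acc_i * f_ij."""
    if len(rankings) != len(accs):
        raise ValueError("one accuracy per ranking required")
    if not rankings:
        raise ValueError("at least one ranking required")
    axis = rankings[0].locus_ids
    for r in rankings[1:]:
        if r.locus_ids != axis:
            raise ValidationError("rankings must share the same locus axis")
    out = np.zeros(len(axis))
    for r, a in zip(rankings, accs):
        out += float(a) * r.weights
    return out


def threshold_filter(
    weights: np.ndarray, locus_ids: Sequence[str], tau: float
) -> set[str]:
    """Loci whose aggregated weight is >= tau (boundary kept)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return {l for l, w in zip(locus_ids, weights) if w >= tau}


def union_folds(
    fold_sets: Sequence[set[str]],
    fold_weights: Sequence[Mapping[str, float]] | None = None,
    name: str = "iteration",
) -> DMLSet:
    """Union of per-fold survivor sets; weights sum over the folds containing
    a locus (the second-level aggregation f = sum_i f_i), counts record fold
    occurrences."""
    if not fold_sets:
        raise ValueError("at least one fold set required")
    loci: set[str] = set().union(*fold_sets)
    counts = {l: sum(l in s for s in fold_sets) for l in loci}
    weights = None
    if fold_weights is not None:
        weights = {
            l: float(sum(fw.get(l, 0.0) for s, fw in zip(fold_sets, fold_weights) if l in s))
            for l in loci
        }
    return DMLSet(name=name, loci=loci, counts=counts, weights=weights)


def bagging_select(
    iteration_sets: Sequence[DMLSet], min_count: int, name: str = "final"
) -> DMLSet:
    """Bagging consensus: keep loci present in >= min_count iteration sets.

    Final weight of a kept locus is the mean of its iteration weights over the
    iterations that contained it.
    """
    T = len(iteration_sets)
    if T < 1:
        raise ValueError("at least one iteration set required")
    if not 1 <= min_count <= T:
        raise ValueError("min_count must be in [1, T]")
    occurrence: dict[str, int] = {}
    weight_sum: dict[str, float] = {}
    for s in iteration_sets:
        for l in s.loci:
            occurrence[l] = occurrence.get(l, 0) + 1
            if s.weights is not None:
                weight_sum[l] = weight_sum.get(l, 0.0) + s.weights[l]
    kept = {l for l, c in occurrence.items() if c >= min_count}
    counts = {l: occurrence[l] for l in kept}
    weights = (
        {l: weight_sum.get(l, 0.0) / occurrence[l] for l in kept}
        if any(s.weights is not None for s in iteration_sets)
        else None
    )
    return DMLSet(name=name, loci=kept, counts=counts, weights=weights)


def run_hydml(
    mat: MethylationMatrix, labels: SampleLabels, cfg: EnsembleConfig | None = None
) -> HyDMLResult:
    """Run the full hybrid ensemble pipeline on a preprocessed matrix.

    Every iteration draws fresh stratified folds from a seed derived
    deterministically from the master seed and the iteration index; the Monte
    Carlo selector is reseeded per (iteration, fold).  An empty final set is a
    warning, not an error.
    """
    cfg = cfg or EnsembleConfig()
    labels = labels.aligned_to(mat)
    labels.require_both_classes()
    scfg = cfg.selector_config
    tau = cfg.weight_threshold
    all_idx = np.arange(mat.n_samples)

    fold_results: list[FoldResult] = []
    iteration_sets: list[DMLSet] = []
    for t in range(1, cfg.n_iterations + 1):
        folds = stratified_folds(labels, cfg.n_folds, iteration_seed(cfg.seed, t))
        fold_sets: list[set[str]] = []
        fold_weight_maps: list[dict[str, float]] = []
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            mat_tr = mat.subset_samples(train_idx)
            lab_tr = SampleLabels(mat_tr.sample_ids, labels.labels[train_idx])
            mat_te = mat.subset_samples(test_idx)
            lab_te = SampleLabels(mat_te.sample_ids, labels.labels[test_idx])
            rankings: dict[str, FeatureRanking] = {}
            accs: dict[str, float] = {}
            for s_i, name in enumerate(cfg.selectors):
                ranking = run_selector(
                    name, mat_tr, lab_tr, scfg, seed=_fold_seed(cfg.seed, t, f, s_i)
                )
                rankings[name] = ranking
                support = ranking.supported_loci(tau)
                if support and len(np.unique(lab_te.labels)) >= 1:
                    accs[name] = svm_accuracy(mat_tr, lab_tr, mat_te, lab_te, support, scfg)
                else:
                    accs[name] = 0.0
            agg = aggregate_fold(
                [rankings[n] for n in cfg.selectors], [accs[n] for n in cfg.selectors]
            )
            surviving = threshold_filter(agg, mat.locus_ids, tau)
            fold_results.append(FoldResult(t, f, rankings, accs, agg, surviving))
            fold_sets.append(surviving)
            wmap = dict(zip(mat.locus_ids, agg))
            fold_weight_maps.append({l: wmap[l] for l in surviving})
            logger.info(
                "iteration %d fold %d: %s -> %d surviving loci",
                t, f, {n: round(a, 3) for n, a in accs.items()}, len(surviving),
            )
        iteration_sets.append(
            union_folds(fold_sets, fold_weight_maps, name=f"iteration_{t}")
        )
    final = bagging_select(iteration_sets, cfg.bagging_min_count)
    if not final.loci:
        warnings.warn("final DML set is empty", stacklevel=2)
    return HyDMLResult(final, iteration_sets, fold_results, cfg)
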