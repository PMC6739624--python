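"""Feature-selection stability and classification performance metrics.

Stability of a selection method is measured by how similar the locus
signatures it returns are under instance perturbation: the pairwise Jaccard
index S(f_i, f_j) = |f_i ∩ f_j| / |f_i ∪ f_j| and its average over all
k(k-1)/2 pairs,

    S_tot = 2 * sum_{i<j} S(f_i, f_j) / (k (k - 1)).

Classification performance uses the confusion-matrix suite (TPR, FPR, ACC,
precision, recall, F1; positive class = tumor) and an exact pair-counting AUC
(Mann–Whitney statistic, ties counted 1/2).

:func:`stability_experiment` ties both together: a method is run on repeated
stratified 90% subsamples, rankings are truncated to each requested signature
size, and per size it reports S_tot across subsamples plus the held-out AUC of
a linear SVM trained on each signature.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import MethylationMatrix, SampleLabels
from .ensemble import EnsembleConfig, run_hydml
from .selectors import SELECTOR_NAMES, SelectorConfig, run_selector

__all__ = [
    "ConfusionMetrics",
    "StabilityReport",
    "jaccard",
    "stability_total",
    "confusion_metrics",
    "auc_score",
    "stability_experiment",
]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets are defined as identical (1.0)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass
class StabilityReport:
    """Pairwise Jaccard matrix over signatures and the scalar S_tot."""

    signatures: list[set[str]]
    pairwise: np.ndarray
    s_tot: float


def stability_total(signatures: Sequence[Iterable[str]]) -> StabilityReport:
    """Mean pairwise Jaccard over all k(k-1)/2 signature pairs (k >= 2)."""
    sigs = [set(s) for s in signatures]
    k = len(sigs)
    if k < 2:
        raise ValueError("stability requires at least 2 signatures")
    pairwise = np.ones((k, k))
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            s = jaccard(sigs[i], sigs[j])
            pairwise[i, j] = pairwise[j, i] = s
            vals.append(s)
    return StabilityReport(sigs, pairwise, float(np.mean(vals)))


@dataclass
class ConfusionMetrics:
    """Confusion-matrix counts and derived rates (0/0 conventions -> 0)."""

    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    fpr: float
    acc: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None

    def to_dict(self) -> dict[str, float]:
        d = {
            "TPR": self.tpr, "FPR": self.fpr, "ACC": self.acc,
            "Precision": self.precision, "Recall": self.recall, "F1": self.f1,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_metrics(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionMetrics:
    """Confusion counts and rates with positive class = tumor (label 1)."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    tpr = _safe_div(tp, tp + fn)
    fpr = _safe_div(fp, fp + tn)
    acc = _safe_div(tp + tn, len(t))
    precision = _safe_div(tp, tp + fp)
    recall = tpr
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return ConfusionMetrics(tp, tn, fp, fn, tpr, fpr, acc, precision, recall, f1)


def auc_score(truth: Sequence[int], scores: Sequence[float]) -> float:
    """Exact ROC AUC as the Mann–Whitney probability P(s+ > s-) + P(tie)/2."""
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in truth")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# stability experiment


def _stratified_subsample(
    y: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    keep: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_keep = max(1, int(round(frac * idx.size)))
        keep.extend(rng.choice(idx, size=n_keep, replace=False).tolist())
    return np.sort(np.array(keep, dtype=int))


def _hydml_ranking(
    mat: MethylationMatrix, labels: SampleLabels, cfg: EnsembleConfig
) -> tuple[list[str], np.ndarray]:
    res = run_hydml(mat, labels, cfg)
    w = res.final.weights or {}
    c = res.final.counts or {}
    weights = np.array(
        [w.get(l, 0.0) + 1e-9 * c.get(l, 0) if l in res.final.loci else 0.0
         for l in mat.locus_ids]
    )
    return list(mat.locus_ids), weights


def _truncate(locus_ids: Sequence[str], weights: np.ndarray, size: int) -> set[str]:
    order = sorted(range(len(locus_ids)), key=lambda i: (-weights[i], locus_ids[i]))
    # never pad with zero-weight loci beyond what the method actually selected
    chosen = [i for i in order[:size] if weights[i] > 0] or order[:size]
    return {locus_ids[i] for i in chosen}


def stability_experiment(
    mat: MethylationMatrix,
    labels: SampleLabels,
    methods: Sequence[str],
    signature_sizes: Sequence[int],
    n_subsamples: int = 5,
    seed: int = 0,
    subsample_frac: float = 0.9,
    selector_config: SelectorConfig | None = None,
    hydml_config: EnsembleConfig | None = None,
    svm_scorer: bool = True,
) -> pd.DataFrame:
    """Stability (S_tot) and held-out AUC curves per method and signature size.

    Each method ("hydml", a single selector name, or a callable
    ``(mat, labels, seed) -> (locus_ids, weights)``) is run on
    ``n_subsamples`` stratified ``subsample_frac`` subsamples drawn without
    replacement; its ranking is truncated to each signature size (ties broken
    by locus id).
    Returns a tidy frame (method, signature_size, replicate, metric, value):
    one ``s_tot`` row per (method, size) and, when ``svm_scorer``, one ``auc``
    row per (method, size, subsample) computed on the held-out complement.
    """
    from sklearn.svm import SVC

    labels = labels.aligned_to(mat)
    labels.require_both_classes()
    if max(signature_sizes) > mat.n_loci:
        raise ValueError("signature size exceeds locus count")
    known = set(SELECTOR_NAMES) | {"hydml"}
    if unknown := {m for m in methods if isinstance(m, str)} - known:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    scfg = selector_config or SelectorConfig()
    hcfg = hydml_config or EnsembleConfig(selector_config=scfg)
    rng = np.random.default_rng(seed)
    draws = []
    for r in range(n_subsamples):
        idx = _stratified_subsample(labels.labels, subsample_frac, rng)
        draws.append((idx, np.setdiff1d(np.arange(mat.n_samples), idx)))

    rows = []
    for method in methods:
        method_name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
        rankings = []
        for r, (idx, heldout) in enumerate(draws):
            sub = mat.subset_samples(idx)
            sub_lab = SampleLabels(sub.sample_ids, labels.labels[idx])
            mtag = zlib.crc32(method_name.encode()) % 2**31  # stable across runs
            mseed = int(np.random.SeedSequence([seed, r, mtag]).generate_state(1)[0] % 2**31)
            if callable(method):
                lids, w = method(sub, sub_lab, mseed)
                w = np.asarray(w, dtype=float)
            elif method == "hydml":
                from dataclasses import replace

                lids, w = _hydml_ranking(sub, sub_lab, replace(hcfg, seed=mseed))
            else:
                rk = run_selector(method, sub, sub_lab, scfg, seed=mseed)
                lids, w = rk.locus_ids, rk.weights
            rankings.append((lids, w, idx, heldout))
        for size in signature_sizes:
            sigs = [_truncate(lids, w, size) for lids, w, _, _ in rankings]
            rows.append(
                dict(method=method_name, signature_size=size, replicate=np.nan,
                     metric="s_tot", value=stability_total(sigs).s_tot)
            )
            if not svm_scorer:
                continue
            for r, ((lids, w, idx, heldout), sig) in enumerate(zip(rankings, sigs)):
                if heldout.size == 0 or len(np.unique(labels.labels[heldout])) < 2:
                    continue
                loci = sorted(sig)
                Xtr = mat.subset_loci(loci).X[idx]
                Xte = mat.subset_loci(loci).X[heldout]
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="linear", C=scfg.svm_c)
                clf.fit((Xtr - mu) / sd, labels.labels[idx])
                auc = auc_score(
                    labels.labels[heldout], clf.decision_function((Xte - mu) / sd)
                )
                rows.append(
                    dict(method=method_name, signature_size=size, replicate=r,
                         metric="auc", value=auc)
                )
    return pd.DataFrame(rows, columns=["method", "signature_size", "replicate", "metric", "value"])
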