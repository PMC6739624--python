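"""In-scope preprocessing for beta-value matrices.

Array-level normalization (probe-type correction, batch correction) is assumed
to have been applied upstream by the usual external tools; :func:`normalize_hook`
is a pass-through slot where such a step would sit.  What this module owns is:

* dropping loci with excessive missingness and median-imputing the rest, so the
  selectors downstream see a complete matrix;
* class-agnostic minimal-variance filtering (either the top-k most variable
  loci or a minimum-variance cutoff);
* propagating SNP-overlap flags so SNP-confounded loci are *marked* in results
  rather than removed — the stringency decision is left to the user.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np

from .core import LocusAnnotation, MethylationMatrix, ValidationError

__all__ = [
    "variance_filter",
    "impute_missing",
    "flag_snp_loci",
    "apply_snp_flags",
    "read_snp_list",
    "normalize_hook",
]


def normalize_hook(
    mat: MethylationMatrix,
    fn: Callable[[MethylationMatrix], MethylationMatrix] | None = None,
) -> MethylationMatrix:
    """Pass-through slot for externally supplied normalization."""
    return mat if fn is None else fn(mat)


def impute_missing(
    mat: MethylationMatrix, max_missing_frac: float = 0.2
) -> tuple[MethylationMatrix, list[str]]:
    """Drop loci with > ``max_missing_frac`` missing entries; median-impute the rest.

    Imputation is per-locus and class-agnostic (labels are never consulted).
    Returns the complete matrix and the list of dropped locus ids.
    """
    frac = np.isnan(mat.values).mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = [l for l, k in zip(mat.locus_ids, keep) if not k]
    values = mat.values[keep].copy()
    if np.isnan(values).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows already dropped
            med = np.nanmedian(values, axis=1)
        rows, cols = np.nonzero(np.isnan(values))
        values[rows, cols] = med[rows]
    kept_ids = [l for l, k in zip(mat.locus_ids, keep) if k]
    return MethylationMatrix(kept_ids, list(mat.sample_ids), values), dropped


def _variances(mat: MethylationMatrix) -> np.ndarray:
    """Unbiased sample variance per locus over non-missing entries."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanvar(mat.values, axis=1, ddof=1)
    return np.nan_to_num(v, nan=0.0)


def variance_filter(
    mat: MethylationMatrix, mode: str = "top_k", threshold: float = 1000.0
) -> MethylationMatrix:
    """Remove minimal-variance loci, keeping the sample axis unchanged.

    ``mode="top_k"`` keeps the ``threshold`` loci with largest sample variance
    (ties broken by lexicographic locus id, so the retained set is
    deterministic); ``mode="min_variance"`` keeps loci with variance >=
    ``threshold``.  Retained values are never altered, and the operation is
    idempotent for fixed parameters.
    """
    if mat.n_loci == 0:
        raise ValidationError("variance_filter requires a non-empty matrix")
    var = _variances(mat)
    if mode == "top_k":
        k = int(threshold)
        if k <= 0:
            raise ValueError("top_k must be a positive integer (empty result forbidden)")
        if k > mat.n_loci:
            raise ValueError(f"top_k={k} exceeds locus count {mat.n_loci}")
        order = sorted(range(mat.n_loci), key=lambda i: (-var[i], mat.locus_ids[i]))
        keep_idx = sorted(order[:k])  # preserve original row order
    elif mode == "min_variance":
        if threshold < 0:
            raise ValueError("min_variance threshold must be >= 0")
        keep_idx = [i for i in range(mat.n_loci) if var[i] >= threshold]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MethylationMatrix(
        [mat.locus_ids[i] for i in keep_idx], list(mat.sample_ids), mat.values[keep_idx]
    )


def read_snp_list(path: str | Path) -> set[str]:
    """Plain-text SNP-overlap list, one locus id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def flag_snp_loci(mat: MethylationMatrix, snp_list: Iterable[str]) -> dict[str, bool]:
    """Per-locus SNP flags for every locus in ``mat``; no locus is removed."""
    snp = set(snp_list)
    return {l: l in snp for l in mat.locus_ids}


def apply_snp_flags(
    ann: Mapping[str, LocusAnnotation], flags: Mapping[str, bool]
) -> dict[str, LocusAnnotation]:
    """Merge SNP flags into an annotation collection (returns updated copies)."""
    out: dict[str, LocusAnnotation] = {}
    for lid, a in ann.items():
        out[lid] = LocusAnnotation(
            a.locus_id, a.chromosome, a.position, a.strand,
            a.cpg_island, bool(flags.get(lid, a.snp_flag)), a.gene_id,
        )
    return out
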