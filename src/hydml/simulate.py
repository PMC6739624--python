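"""Synthetic methylation cohorts with known ground truth.

Array beta values have a characteristic multi-modal landscape: most loci sit
near fully unmethylated (~0.1) or fully methylated (~0.9), with a smaller mid
fraction.  The generator mimics this by drawing a baseline mean per locus from
a low/mid/high mixture and sampling both classes from a beta distribution
parameterized by (mean, concentration).  A minority of planted differential
loci shift the tumor-class mean by ±effect_size (exactly, by re-drawing their
baseline inside the feasible range), alternating hyper/hypo; entries can be
masked missing at a fixed rate.  Class sizes may be unbalanced and the
feature:sample ratio can be made extreme, matching the regime the selection
pipeline targets.  Everything is reproducible from a single seed.

:func:`simulate_pan_cancer` builds several such cohorts over a common locus
universe, planting a configurable fraction of DML shared by all cancers (the
ground-truth pan-cancer loci) and the rest cancer-private.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import MethylationMatrix, SampleLabels

__all__ = [
    "SyntheticTruth",
    "PanCancerTruth",
    "simulate_cohort",
    "simulate_pan_cancer",
    "write_truth",
    "read_truth",
]

_EPS = 1e-6
_MODES = (0.1, 0.5, 0.9)
_MODE_PROBS = (0.4, 0.2, 0.4)
_MODE_JITTER = 0.04


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    planted: list[str]
    direction: dict[str, str]  # locus -> hyper|hypo
    effect_size: dict[str, float]  # difference of class means, in (0, 1]
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.direction) != set(self.planted) or set(self.effect_size) != set(self.planted):
            raise ValueError("direction/effect_size must be keyed by planted loci")
        if any(not 0.0 < e <= 1.0 for e in self.effect_size.values()):
            raise ValueError("effect sizes must be in (0, 1]")


@dataclass
class PanCancerTruth:
    shared: list[str]  # planted in every cancer: the expected pDML candidates
    private: dict[str, list[str]]  # cancer -> its private planted loci
    params: dict[str, Any] = field(default_factory=dict)


def _locus_ids(n: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(1, n + 1)]


def _beta_draw(
    rng: np.random.Generator, mean: np.ndarray, concentration: float, size: tuple[int, ...]
) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return np.clip(rng.beta(a, b, size=size), _EPS, 1.0 - _EPS)


def simulate_cohort(
    n_normal: int = 30,
    n_tumor: int = 30,
    n_loci: int = 2000,
    n_dml: int = 50,
    effect_size: float = 0.35,
    concentration: float = 20.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    locus_ids: list[str] | None = None,
    planted_ids: list[str] | None = None,
    batch_logit_shift: float = 0.0,
) -> tuple[MethylationMatrix, SampleLabels, SyntheticTruth]:
    """Simulate a tumor/normal beta-value cohort with planted DML.

    Null loci draw a trimodal baseline mean; planted loci draw a baseline
    uniform on the sub-interval where the ±effect_size shift stays inside
    (0.05, 0.95), so the realized difference of class means equals
    ``effect_size`` exactly in expectation.  Directions alternate hyper/hypo
    along the planted list.  ``missing_rate`` masks entries as NaN.

    ``batch_logit_shift`` > 0 adds a label-independent additive shift of
    ±shift/2 on the logit scale to two alternating sample batches — a stress
    test for robustness claims, off by default.
    """
    if not 0 <= n_dml <= n_loci:
        raise ValueError("n_dml must be in [0, n_loci]")
    if n_dml > 0 and not 0.0 < effect_size < 1.0:
        raise ValueError("effect_size must be in (0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if min(n_normal, n_tumor) < 1:
        raise ValueError("both classes need at least one sample")
    rng = np.random.default_rng(seed)
    ids = list(locus_ids) if locus_ids is not None else _locus_ids(n_loci)
    if len(ids) != n_loci:
        raise ValueError("locus_ids length must equal n_loci")

    modes = rng.choice(len(_MODES), size=n_loci, p=_MODE_PROBS)
    mu = np.clip(
        np.array(_MODES)[modes] + rng.normal(0.0, _MODE_JITTER, size=n_loci),
        0.02, 0.98,
    )

    if planted_ids is not None:
        planted = [ids.index(l) for l in planted_ids]
    else:
        planted = sorted(rng.choice(n_loci, size=n_dml, replace=False).tolist())
    directions = ["hyper" if i % 2 == 0 else "hypo" for i in range(len(planted))]

    mu_normal = mu.copy()
    mu_tumor = mu.copy()
    for j, d in zip(planted, directions):
        if d == "hyper":
            base = rng.uniform(0.05, 0.95 - effect_size)
            mu_normal[j], mu_tumor[j] = base, base + effect_size
        else:
            base = rng.uniform(0.05 + effect_size, 0.95)
            mu_normal[j], mu_tumor[j] = base, base - effect_size

    normal = _beta_draw(rng, mu_normal[:, None], concentration, (n_loci, n_normal))
    tumor = _beta_draw(rng, mu_tumor[:, None], concentration, (n_loci, n_tumor))
    values = np.concatenate([normal, tumor], axis=1)
    if batch_logit_shift:
        batch = np.arange(values.shape[1]) % 2  # alternating, label-independent
        shift = np.where(batch == 0, -0.5, 0.5) * batch_logit_shift
        logit = np.log(values / (1.0 - values)) + shift[None, :]
        values = np.clip(1.0 / (1.0 + np.exp(-logit)), _EPS, 1.0 - _EPS)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan

    sample_ids = [f"N{i:03d}" for i in range(1, n_normal + 1)] + [
        f"T{i:03d}" for i in range(1, n_tumor + 1)
    ]
    labels = SampleLabels(sample_ids, np.r_[np.zeros(n_normal, int), np.ones(n_tumor, int)])
    mat = MethylationMatrix(ids, sample_ids, values)
    truth = SyntheticTruth(
        planted=[ids[j] for j in planted],
        direction={ids[j]: d for j, d in zip(planted, directions)},
        effect_size={ids[j]: float(effect_size) for j in planted},
        params=dict(
            n_normal=n_normal, n_tumor=n_tumor, n_loci=n_loci, n_dml=len(planted),
            effect_size=effect_size, concentration=concentration,
            missing_rate=missing_rate, seed=seed,
            batch_logit_shift=batch_logit_shift,
        ),
    )
    return mat, labels, truth


def simulate_pan_cancer(
    n_cancers: int = 13,
    shared_dml_frac: float = 0.5,
    per_cancer_params: dict[str, Any] | None = None,
    seed: int = 0,
) -> tuple[dict[str, tuple[MethylationMatrix, SampleLabels, SyntheticTruth]], PanCancerTruth]:
    """Simulate several cohorts over one locus universe with shared DML.

    Per cancer, round(shared_dml_frac * n_dml) planted loci come from a common
    shared pool (planted in *every* cancer — the ground-truth pan-cancer
    candidates); the remainder are cancer-private and disjoint across cancers
    where the universe allows.
    """
    if n_cancers < 2:
        raise ValueError("n_cancers must be >= 2")
    if not 0.0 <= shared_dml_frac <= 1.0:
        raise ValueError("shared_dml_frac must be in [0, 1]")
    params = dict(
        n_normal=30, n_tumor=30, n_loci=2000, n_dml=50,
        effect_size=0.35, concentration=20.0, missing_rate=0.0,
    )
    if per_cancer_params:
        unknown = set(per_cancer_params) - set(params)
        if unknown:
            raise ValueError(f"unknown cohort parameters {sorted(unknown)}")
        params.update(per_cancer_params)
    n_loci, n_dml = params["n_loci"], params["n_dml"]
    n_shared = int(round(shared_dml_frac * n_dml))
    n_private = n_dml - n_shared
    if n_shared + n_cancers * n_private > n_loci:
        raise ValueError("locus universe too small for disjoint private DML")

    rng = np.random.default_rng(seed)
    ids = _locus_ids(n_loci)
    pool = rng.permutation(n_loci)
    shared = sorted(pool[:n_shared].tolist())
    private_pool = pool[n_shared:]

    cancers: dict[str, tuple[MethylationMatrix, SampleLabels, SyntheticTruth]] = {}
    private: dict[str, list[str]] = {}
    for c in range(n_cancers):
        name = f"cancer{c + 1:02d}"
        priv = sorted(private_pool[c * n_private : (c + 1) * n_private].tolist())
        planted = [ids[j] for j in sorted(shared + priv)]
        cohort_seed = int(
            np.random.SeedSequence([seed, 1000 + c]).generate_state(1)[0] % 2**31
        )
        cancers[name] = simulate_cohort(
            seed=cohort_seed, locus_ids=ids, planted_ids=planted, **params
        )
        private[name] = [ids[j] for j in priv]
    truth = PanCancerTruth(
        shared=[ids[j] for j in shared],
        private=private,
        params=dict(n_cancers=n_cancers, shared_dml_frac=shared_dml_frac,
                    seed=seed, **params),
    )
    return cancers, truth


def write_truth(truth: SyntheticTruth, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "locus_id": truth.planted,
            "direction": [truth.direction[l] for l in truth.planted],
            "effect_size": [truth.effect_size[l] for l in truth.planted],
        }
    ).to_csv(path, sep=sep, index=False)


def read_truth(path: str | Path, sep: str = "\t") -> SyntheticTruth:
    df = pd.read_csv(path, sep=sep, dtype={"locus_id": str})
    return SyntheticTruth(
        planted=list(df["locus_id"]),
        direction=dict(zip(df["locus_id"], df["direction"])),
        effect_size=dict(zip(df["locus_id"], df["effect_size"].astype(float))),
    )
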