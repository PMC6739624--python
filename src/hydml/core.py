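"""Domain containers and delimited-text I/O for methylation analyses.

The central object is the :class:`MethylationMatrix`, a loci × samples matrix
of beta values (ratio of methylated to total signal, in [0, 1], ``NaN`` for
missing).  Around it sit binary sample labels (0 = normal, 1 = tumor), per-locus
annotations (chromosome, position, strand, CpG-island and SNP flags), simple
gene models for region annotation, and :class:`DMLSet` — a named set of locus
identifiers with optional occurrence counts and weights, the unit the ensemble
pipeline produces and the pan-cancer analyses consume.

All tables are read and written as delimited text (tab by default) with ``NA``
as the missing token.  Input genomic coordinates are 1-based (manifest
convention); BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

__all__ = [
    "ValidationError",
    "ParseError",
    "MethylationMatrix",
    "SampleLabels",
    "LocusAnnotation",
    "GeneModel",
    "DMLSet",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_annotations",
    "write_annotations",
    "read_gene_models",
    "write_gene_models",
    "read_dml_set",
    "write_dml_set",
    "write_dml_bed",
]


class ValidationError(ValueError):
    """A container invariant was violated (range, uniqueness, shape...)."""


class ParseError(ValueError):
    """A delimited-text file could not be parsed into a valid container."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {axis} identifier: {dup!r}")


@dataclass
class MethylationMatrix:
    """Beta values indexed (locus, sample); ``NaN`` entries are missing."""

    locus_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = [str(i) for i in self.locus_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples"
            )
        _check_unique(self.locus_ids, "locus")
        _check_unique(self.sample_ids, "sample")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value out of [0,1] at locus {self.locus_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def X(self) -> np.ndarray:
        """Samples × loci view, the orientation ML estimators expect."""
        return self.values.T

    def locus_index(self, loci: Iterable[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            return np.array([pos[l] for l in loci], dtype=int)
        except KeyError as e:
            raise KeyError(f"locus {e.args[0]!r} not in matrix") from None

    def subset_loci(self, loci: Sequence[str]) -> "MethylationMatrix":
        idx = self.locus_index(loci)
        return MethylationMatrix(
            [self.locus_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, idx: Sequence[int]) -> "MethylationMatrix":
        idx = np.asarray(idx, dtype=int)
        return MethylationMatrix(
            list(self.locus_ids), [self.sample_ids[i] for i in idx], self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.locus_ids, columns=self.sample_ids)


@dataclass
class SampleLabels:
    """Binary class labels, order-matched to a matrix's sample axis."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(i) for i in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValidationError("labels length does not match sample_ids")
        _check_unique(self.sample_ids, "sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 (normal) or 1 (tumor)")

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValidationError("both classes (0 and 1) must be present")

    def aligned_to(self, mat: MethylationMatrix) -> "SampleLabels":
        """Reorder to the matrix's sample axis, erroring on mismatch."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in mat.sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        idx = [pos[s] for s in mat.sample_ids]
        return SampleLabels(list(mat.sample_ids), self.labels[idx])


@dataclass
class LocusAnnotation:
    """Per-locus genomic annotation (1-based position)."""

    locus_id: str
    chromosome: str
    position: int
    strand: str = "unknown"
    cpg_island: bool = False
    snp_flag: bool = False
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.position = int(self.position)
        if self.position < 1:
            raise ValidationError(f"position must be >= 1 for {self.locus_id!r}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"bad strand {self.strand!r} for {self.locus_id!r}")


@dataclass
class GeneModel:
    """A gene span with its transcription start site (all 1-based, inclusive)."""

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        self.tss, self.gene_start, self.gene_end = (
            int(self.tss),
            int(self.gene_start),
            int(self.gene_end),
        )
        if self.gene_start > self.gene_end:
            raise ValidationError(f"gene_start > gene_end for {self.gene_id!r}")
        if not self.gene_start <= self.tss <= self.gene_end:
            raise ValidationError(f"tss outside gene span for {self.gene_id!r}")


@dataclass
class DMLSet:
    """A named set of differentially methylated loci.

    ``counts`` record how often a locus recurred (across folds, iterations or
    cancers); ``weights`` carry aggregated selection weights.  Both, when
    present, are keyed exactly by ``loci``.
    """

    name: str
    loci: set[str] = field(default_factory=set)
    counts: dict[str, int] | None = None
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.loci = set(map(str, self.loci))
        for attr in ("counts", "weights"):
            d = getattr(self, attr)
            if d is not None:
                d = {str(k): d[k] for k in d}
                if set(d) != self.loci:
                    raise ValidationError(f"{attr} keys must equal loci in {self.name!r}")
                if any(v < 0 for v in d.values()):
                    raise ValidationError(f"{attr} must be nonnegative in {self.name!r}")
                setattr(self, attr, d)

    def __len__(self) -> int:
        return len(self.loci)

    def sorted_loci(self) -> list[str]:
        """Loci by descending weight, then count, then lexicographic id."""
        w = self.weights or {}
        c = self.counts or {}
        return sorted(self.loci, key=lambda l: (-w.get(l, 0.0), -c.get(l, 0), l))


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_matrix(
    path: str | Path,
    orientation: str = "loci-as-rows",
    sep: str = "\t",
    missing: str = MISSING_TOKEN,
) -> MethylationMatrix:
    """Read a beta-value matrix; first row/column carry identifiers.

    ``orientation`` is ``"loci-as-rows"`` (default) or ``"samples-as-rows"``;
    the returned matrix is always loci-as-rows.
    """
    if orientation not in ("loci-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[missing], keep_default_na=False, dtype=str
    )
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"malformed numeric field at row {row!r}, column {col!r} in {path}"
            )
        num[col] = converted
    if orientation == "samples-as-rows":
        num = num.T
    return MethylationMatrix(list(num.index), list(num.columns), num.to_numpy(float))


def write_matrix(
    mat: MethylationMatrix, path: str | Path, sep: str = "\t", missing: str = MISSING_TOKEN
) -> None:
    mat.to_frame().to_csv(path, sep=sep, na_rep=missing, index_label="locus_id")


def read_labels(path: str | Path, sep: str = "\t") -> SampleLabels:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if not {"sample_id", "label"}.issubset(df.columns):
        raise ParseError(f"label table {path} must have columns sample_id, label")
    return SampleLabels(list(df["sample_id"]), df["label"].to_numpy())


def write_labels(labels: SampleLabels, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=sep, index=False
    )


_ANN_COLS = ["locus_id", "chrom", "pos", "strand", "cpg_island", "snp_flag", "gene_id"]


def read_annotations(path: str | Path, sep: str = "\t") -> dict[str, LocusAnnotation]:
    df = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN], keep_default_na=False)
    missing_cols = set(_ANN_COLS[:3]) - set(df.columns)
    if missing_cols:
        raise ParseError(f"annotation table {path} lacks columns {sorted(missing_cols)}")
    out: dict[str, LocusAnnotation] = {}
    for rec in df.to_dict("records"):
        lid = str(rec["locus_id"])
        if lid in out:
            raise ValidationError(f"duplicate annotation for locus {lid!r}")
        gene = rec.get("gene_id")
        out[lid] = LocusAnnotation(
            locus_id=lid,
            chromosome=str(rec["chrom"]),
            position=int(rec["pos"]),
            strand=str(rec.get("strand", "unknown")),
            cpg_island=bool(int(rec.get("cpg_island", 0))),
            snp_flag=bool(int(rec.get("snp_flag", 0))),
            gene_id=None if gene is None or pd.isna(gene) else str(gene),
        )
    return out


def write_annotations(
    ann: Mapping[str, LocusAnnotation], path: str | Path, sep: str = "\t"
) -> None:
    rows = [
        {
            "locus_id": a.locus_id,
            "chrom": a.chromosome,
            "pos": a.position,
            "strand": a.strand,
            "cpg_island": int(a.cpg_island),
            "snp_flag": int(a.snp_flag),
            "gene_id": a.gene_id if a.gene_id is not None else MISSING_TOKEN,
        }
        for a in ann.values()
    ]
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep=sep, index=False)


def read_gene_models(path: str | Path, sep: str = "\t") -> list[GeneModel]:
    df = pd.read_csv(path, sep=sep)
    need = {"gene_id", "chrom", "strand", "tss", "gene_start", "gene_end"}
    if not need.issubset(df.columns):
        raise ParseError(f"gene-model table {path} lacks columns {sorted(need - set(df.columns))}")
    return [
        GeneModel(
            str(r["gene_id"]), str(r["chrom"]), str(r["strand"]),
            int(r["tss"]), int(r["gene_start"]), int(r["gene_end"]),
        )
        for r in df.to_dict("records")
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chromosome, "strand": g.strand,
            "tss": g.tss, "gene_start": g.gene_start, "gene_end": g.gene_end,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "gene_start", "gene_end"]).to_csv(
        path, sep=sep, index=False
    )


def write_dml_set(dml: DMLSet, path: str | Path, sep: str = "\t") -> None:
    """Write a DMLSet as TSV (locus_id, count, weight), name in a # header."""
    with open(path, "w") as fh:
        fh.write(f"#name={dml.name}\n")
        fh.write(sep.join(("locus_id", "count", "weight")) + "\n")
        for l in dml.sorted_loci():
            count = str(dml.counts[l]) if dml.counts is not None else MISSING_TOKEN
            weight = repr(dml.weights[l]) if dml.weights is not None else MISSING_TOKEN
            fh.write(sep.join((l, count, weight)) + "\n")


def read_dml_set(path: str | Path, sep: str = "\t", name: str | None = None) -> DMLSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#name="):
        name = name or first[len("#name=") :].strip()
    name = name or path.stem
    df = pd.read_csv(
        path, sep=sep, comment="#", na_values=[MISSING_TOKEN], keep_default_na=False,
        dtype={"locus_id": str},
    )
    loci = set(df["locus_id"])
    counts = None
    if "count" in df.columns and df["count"].notna().all() and len(df):
        counts = {r["locus_id"]: int(r["count"]) for r in df.to_dict("records")}
    weights = None
    if "weight" in df.columns and df["weight"].notna().all() and len(df):
        weights = {r["locus_id"]: float(r["weight"]) for r in df.to_dict("records")}
    return DMLSet(name=name, loci=loci, counts=counts, weights=weights)


def write_dml_bed(
    dml: DMLSet, ann: Mapping[str, LocusAnnotation], path: str | Path
) -> None:
    """Write a DMLSet as BED6+1 (0-based half-open single-CpG intervals).

    The score column scales the set's weights (or counts) into 0–1000; the
    trailing column marks SNP-overlapping loci ``SNP`` so they are visible in
    the output rather than silently dropped, leaving stringency to the user.
    """
    unannotated = sorted(l for l in dml.loci if l not in ann)
    if unannotated:
        raise ValidationError(f"loci without annotation: {unannotated[:10]}")
    if dml.weights is not None:
        raw = dml.weights
    elif dml.counts is not None:
        raw = {l: float(c) for l, c in dml.counts.items()}
    else:
        raw = {l: 0.0 for l in dml.loci}
    top = max(raw.values(), default=0.0)
    rows = []
    for l in dml.loci:
        a = ann[l]
        score = int(round(1000.0 * raw[l] / top)) if top > 0 else 0
        strand = a.strand if a.strand in ("+", "-") else "."
        rows.append(
            (a.chromosome, a.position - 1, a.position, l, score, strand,
             "SNP" if a.snp_flag else ".")
        )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tsnp\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
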