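"""Cross-cancer consensus and genomic characterization of DML sets.

A locus selected as a DML in at least ``min_cancers`` of the per-cancer sets
is a pan-cancer DML (pDML); the reference rule is "at least 10 of 13".  For
each cancer, loci are called hyper- or hypomethylated by the sign of
median(tumor) - median(normal).  Characterization utilities assign each locus
to promoter (2,000 bp upstream of a TSS through the TSS, strand-aware, taking
precedence over gene body), gene body, or intergenic; compute per-chromosome
DML density relative to the array background; and cluster cancers by the
Jaccard similarity of their DML sets (average linkage on 1 - Jaccard).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .core import DMLSet, GeneModel, LocusAnnotation, MethylationMatrix, SampleLabels
from .metrics import jaccard

logger = logging.getLogger(__name__)

__all__ = [
    "PanCancerResult",
    "pdml_select",
    "direction_call",
    "annotate_region",
    "annotate_regions",
    "chromosome_density",
    "cancer_similarity_cluster",
]

PROMOTER_WINDOW = 2000  # bp upstream of the TSS


def _as_locus_set(s: DMLSet | Iterable[str]) -> set[str]:
    return set(s.loci) if isinstance(s, DMLSet) else set(s)


@dataclass
class PanCancerResult:
    per_cancer: dict[str, set[str]]
    occurrence: dict[str, int]
    pdml: DMLSet
    directions: dict[str, dict[str, str]] | None = None  # cancer -> locus -> call


def pdml_select(
    dml_sets: Mapping[str, DMLSet | Iterable[str]], min_cancers: int
) -> DMLSet:
    """Loci occurring in at least ``min_cancers`` of the named sets (inclusive)."""
    if not 1 <= min_cancers <= len(dml_sets):
        raise ValueError("min_cancers must be in [1, number of sets]")
    sets = {name: _as_locus_set(s) for name, s in dml_sets.items()}
    occurrence: dict[str, int] = {}
    for s in sets.values():
        for l in s:
            occurrence[l] = occurrence.get(l, 0) + 1
    kept = {l for l, c in occurrence.items() if c >= min_cancers}
    return DMLSet(name="pDML", loci=kept, counts={l: occurrence[l] for l in kept})


def direction_call(
    mat: MethylationMatrix,
    labels: SampleLabels,
    loci: Iterable[str],
    delta: float = 0.0,
) -> dict[str, str]:
    """Hyper/hypo/none per locus by the tumor-normal difference of medians.

    hyper if median(tumor) - median(normal) > delta, hypo if < -delta.
    """
    labels = labels.aligned_to(mat)
    labels.require_both_classes()
    loci = list(loci)
    idx = mat.locus_index(loci)
    tumor = labels.labels == 1
    med_t = np.nanmedian(mat.values[idx][:, tumor], axis=1)
    med_n = np.nanmedian(mat.values[idx][:, ~tumor], axis=1)
    diff = med_t - med_n
    return {
        l: "hyper" if d > delta else ("hypo" if d < -delta else "none")
        for l, d in zip(loci, diff)
    }


def _promoter_window(gene: GeneModel) -> tuple[int, int]:
    strand = gene.strand
    if strand not in ("+", "-"):
        logger.warning("gene %s has unknown strand %r; treating as +", gene.gene_id, strand)
        strand = "+"
    if strand == "+":
        return gene.tss - PROMOTER_WINDOW, gene.tss
    return gene.tss, gene.tss + PROMOTER_WINDOW


def annotate_region(locus: LocusAnnotation, genes: Sequence[GeneModel]) -> str:
    """Assign exactly one of promoter / gene_body / intergenic.

    The promoter is the strand-aware window from 2,000 bp upstream through the
    TSS (both ends inclusive) of any gene, and takes precedence over gene
    body; gene body is any gene span outside a promoter window; everything
    else is intergenic.
    """
    pos = locus.position
    in_body = False
    for g in genes:
        if g.chromosome != locus.chromosome:
            continue
        lo, hi = _promoter_window(g)
        if lo <= pos <= hi:
            return "promoter"
        if g.gene_start <= pos <= g.gene_end:
            in_body = True
    return "gene_body" if in_body else "intergenic"


def annotate_regions(
    ann: Mapping[str, LocusAnnotation], genes: Sequence[GeneModel]
) -> dict[str, str]:
    return {lid: annotate_region(a, genes) for lid, a in ann.items()}


def chromosome_density(
    dml: DMLSet | Iterable[str], background: Mapping[str, LocusAnnotation]
) -> dict[str, float]:
    """Per-chromosome |DML on chrom| / |background loci on chrom|.

    The background is the full array annotation; a DML locus absent from it is
    an error.  Chromosomes present in the background always get a ratio
    (possibly 0); chromosomes without background loci are simply not reported
    rather than shown as zero.
    """
    loci = _as_locus_set(dml)
    missing = sorted(loci - set(background))
    if missing:
        raise KeyError(f"DML loci absent from background annotation: {missing[:10]}")
    bg_counts: dict[str, int] = {}
    for a in background.values():
        bg_counts[a.chromosome] = bg_counts.get(a.chromosome, 0) + 1
    dml_counts: dict[str, int] = {}
    for l in loci:
        c = background[l].chromosome
        dml_counts[c] = dml_counts.get(c, 0) + 1
    return {c: dml_counts.get(c, 0) / n for c, n in sorted(bg_counts.items())}


def cancer_similarity_cluster(
    dml_sets: Mapping[str, DMLSet | Iterable[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Jaccard similarity matrix + average-linkage dendrogram over DML sets.

    Sets are ordered lexicographically by name before clustering so ties are
    broken deterministically.  Returns (similarity matrix, merge table with
    columns child_a/child_b/height/size, Newick string with ultrametric
    branch lengths).
    """
    names = sorted(dml_sets)
    if len(names) < 2:
        raise ValueError("clustering requires at least 2 sets")
    sets = [_as_locus_set(dml_sets[n]) for n in names]
    k = len(names)
    sim = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = jaccard(sets[i], sets[j])
    condensed = np.array(
        [1.0 - sim[i, j] for i in range(k) for j in range(i + 1, k)]
    )
    Z = linkage(condensed, method="average")
    node_name: dict[int, str] = {i: names[i] for i in range(k)}
    merges = []
    for step, (a, b, h, size) in enumerate(Z):
        a, b = int(a), int(b)
        merges.append(
            dict(child_a=node_name[a], child_b=node_name[b],
                 height=float(h), size=int(size))
        )
        node_name[k + step] = f"({node_name[a]},{node_name[b]})"
    merge_df = pd.DataFrame(merges, columns=["child_a", "child_b", "height", "size"])
    root = to_tree(Z)

    def nwk(node, parent_h: float) -> str:
        if node.is_leaf():
            return f"{names[node.id]}:{parent_h / 2.0:.6g}"
        inner = ",".join(nwk(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{max(parent_h - node.dist, 0.0) / 2.0:.6g}"

    inner = ",".join(nwk(c, root.dist) for c in (root.left, root.right))
    newick = f"({inner});"
    sim_df = pd.DataFrame(sim, index=names, columns=names)
    return sim_df, merge_df, newick
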