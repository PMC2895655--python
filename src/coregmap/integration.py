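"""Integration of binding, differential expression and annotation.

A gene is a high-confidence direct target of a factor when (i) at least
one bound region is assigned to it, (ii) it is differentially expressed
in that factor's loss-of-function mutant at one or more timepoints, and
(iii) it carries the tissue annotation (here: expressed in muscle).
Region-to-gene assignment uses a span-overlap-or-TSS-window candidate
rule ranked by differential-expression evidence, annotation, then TSS
distance. Overlap between the two factors' target sets is scored with a
one-sided hypergeometric (Fisher exact) test, and dual-mutant response
profiles are grouped by k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .chip import BoundRegion

__all__ = [
    "GeneModel",
    "assign_regions_to_genes",
    "define_direct_targets",
    "overlap_significance",
    "build_response_profiles",
    "cluster_response_profiles",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span, TSS and tissue-annotation flag."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    muscle_expressed: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _tss_distance(region: BoundRegion, gene: GeneModel) -> int:
    tss = gene.tss
    if region.start <= tss < region.end:
        return 0
    return min(abs(tss - region.start), abs(tss - (region.end - 1)))


def assign_regions_to_genes(
    regions: list[BoundRegion],
    genes: list[GeneModel],
    de_genes: set[str] | None = None,
    window_bp: int = 10_000,
    overrides: dict[int, str] | None = None,
) -> list[str | None]:
    """Assign each bound region to its most plausible target gene.

    Candidates are genes whose span overlaps the region or whose TSS
    lies within ``window_bp`` of it. Candidates are ranked by
    (differentially expressed in the relevant mutant, tissue-annotated,
    ascending TSS distance, gene id as a deterministic tie-break); the
    top candidate wins. Regions with no candidate are unassigned
    (``None``). ``overrides`` maps region index to a forced gene id,
    supporting manually curated reassignments.
    """
    de_genes = de_genes or set()
    by_id = {g.id: g for g in genes}
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = min(g.start, g.tss - window_bp)
        hi = max(g.end, g.tss + window_bp + 1)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.id)

    assignments: list[str | None] = []
    for i, region in enumerate(regions):
        if overrides and i in overrides:
            gid = overrides[i]
            if gid not in by_id:
                raise ValueError(f"override for region {i} names unknown gene {gid!r}")
            assignments.append(gid)
            continue
        tree = trees.get(region.chrom)
        candidates = []
        if tree is not None:
            for hit in tree.overlap(region.start, region.end):
                g = by_id[hit.data]
                span_overlaps = g.start < region.end and region.start < g.end
                near_tss = _tss_distance(region, g) <= window_bp
                if span_overlaps or near_tss:
                    candidates.append(g)
        if not candidates:
            assignments.append(None)
            continue
        candidates.sort(
            key=lambda g: (
                g.id not in de_genes,
                not g.muscle_expressed,
                _tss_distance(region, g),
                g.id,
            )
        )
        assignments.append(candidates[0].id)
    return assignments


def define_direct_targets(
    assignments: list[str | None],
    de_downstream: set[str],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """High-confidence direct targets of one factor.

    A gene qualifies iff it has >= 1 assigned bound region AND a
    gene-level differential call in the matching mutant AND the tissue
    annotation. Returns one row per target with its supporting region
    indices; row order is deterministic (sorted by gene id) and
    independent of input order.
    """
    by_id = {g.id: g for g in genes}
    regions_per_gene: dict[str, list[int]] = {}
    for idx, gid in enumerate(assignments):
        if gid is not None:
            regions_per_gene.setdefault(gid, []).append(idx)
    rows = []
    for gid in sorted(regions_per_gene):
        gene = by_id.get(gid)
        if gene is None:
            continue
        if gid in de_downstream and gene.muscle_expressed:
            rows.append(
                {
                    "gene": gid,
                    "n_regions": len(regions_per_gene[gid]),
                    "region_indices": ",".join(map(str, sorted(regions_per_gene[gid]))),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "n_regions", "region_indices"])


def overlap_significance(
    targets_A: set[str], targets_B: set[str], universe_size: int
) -> tuple[int, float, float]:
    """Overlap of two target-gene sets against a hypergeometric null.

    Returns (overlap count, percentage of A overlapping B rounded to
    one decimal, one-sided Fisher exact p = P(X >= overlap) for |A|
    draws without replacement from a universe containing |B| successes).
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if len(targets_A) > universe_size or len(targets_B) > universe_size:
        raise ValueError("target sets larger than the universe")
    if not targets_A:
        raise ValueError("targets_A is empty; overlap percentage undefined")
    overlap = len(targets_A & targets_B)
    pct = round(100.0 * overlap / len(targets_A), 1)
    p = float(
        hypergeom.sf(overlap - 1, universe_size, len(targets_B), len(targets_A))
    )
    return overlap, pct, p


def build_response_profiles(
    de_results: pd.DataFrame, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene response vectors over (mutant A timepoints || mutant B).

    Pivots the long DEResult table into one row per gene whose columns
    are mean log2 fold changes ordered by (mutant, timepoint). Missing
    entries are zero-imputed; the imputation mask is kept in
    ``attrs["mask"]``.
    """
    wide = de_results.pivot_table(
        index="gene", columns=["mutant", "timepoint"], values="mean_log2fc",
        sort=True,
    )
    if gene_subset is not None:
        wide = wide.reindex([g for g in gene_subset if g in wide.index])
    mask = wide.isna()
    wide = wide.fillna(0.0)
    wide.attrs["mask"] = mask
    return wide


def cluster_response_profiles(
    profiles: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 50,
    seed: int | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """K-means clustering of response profiles.

    Runs Lloyd's algorithm with k-means++ seeding, keeping the best of
    ``n_restarts`` by within-cluster sum of squares. Labels are
    relabelled canonically by ascending centroid mean (most strongly
    downregulated cluster first) so results are reproducible across
    runs. Supports any k >= 1 up to the number of profiles; the
    co-regulation analysis uses k = 3 or 4 depending on whether
    divergent responses are split.
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(profiles)})")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts,
        random_state=None if seed is None else int(seed) % 2**32,
    )
    raw = km.fit_predict(X)
    order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = pd.Series(relabel[raw], index=profiles.index, name="cluster")
    centroids = km.cluster_centers_[order]
    return labels, centroids
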