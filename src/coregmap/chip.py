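"""ChIP-chip enrichment calling by rank products with permutation FDR.

A tiling-array ChIP experiment hybridises immunoprecipitated DNA against
a total genomic reference, giving per-fragment log2(IP/reference) ratios
for several replicate IPs. Fragments consistently enriched across
replicates are detected with the rank-product statistic: each replicate
ranks fragments by enrichment (rank 1 = most enriched) and a fragment's
score is the geometric mean of its ranks. Significance is assessed by a
permutation null in which each replicate's rank vector is shuffled
independently, and the resulting per-fragment FDR is combined with a
fold-enrichment filter. Binding calls require significance with two
independent antibodies, and significant fragments are merged into unique
non-overlapping bound regions across timepoints.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "TilingFragment",
    "BoundRegion",
    "ChipReplicateMatrix",
    "compute_rank_products",
    "permutation_fdr",
    "call_enriched",
    "intersect_antibodies",
    "merge_bound_regions",
    "co_occupancy",
]


@dataclass(frozen=True)
class TilingFragment:
    """A genomic fragment printed on the tiling array."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.id}: start must be < end "
                f"({self.start} >= {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BoundRegion:
    """A merged, unique genomic region called bound by a factor."""

    chrom: str
    start: int
    end: int
    fragment_ids: list[str] = field(default_factory=list)
    timepoints: set[str] = field(default_factory=set)
    min_fdr: float = float("nan")

    def overlaps(self, other: "BoundRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChipReplicateMatrix:
    """Fragments x replicate-columns of log2(IP/reference) ratios.

    Columns follow the naming convention ``<antibody>_<condition>_<timepoint>_<rep>``
    (for example ``ab1_ip_T1_r2``); condition is ``ip`` or ``mock``.
    """

    def __init__(self, data: pd.DataFrame):
        meta = []
        for col in data.columns:
            parts = col.split("_")
            if len(parts) != 4:
                raise ValueError(
                    f"column {col!r} does not match "
                    "'<antibody>_<condition>_<timepoint>_<rep>'"
                )
            antibody, condition, timepoint, rep = parts
            if condition not in ("ip", "mock"):
                raise ValueError(f"column {col!r}: unknown condition {condition!r}")
            meta.append((col, antibody, condition, timepoint, rep))
        if data.index.has_duplicates:
            raise ValueError("duplicate fragment ids in matrix")
        self.data = data
        self.columns_meta = pd.DataFrame(
            meta, columns=["column", "antibody", "condition", "timepoint", "rep"]
        ).set_index("column")

    @property
    def fragment_ids(self) -> pd.Index:
        return self.data.index

    def select(self, antibody: str, timepoint: str, condition: str = "ip") -> pd.DataFrame:
        m = self.columns_meta
        cols = m.index[
            (m["antibody"] == antibody)
            & (m["timepoint"] == timepoint)
            & (m["condition"] == condition)
        ]
        return self.data[list(cols)]

    def antibodies(self) -> list[str]:
        return sorted(self.columns_meta["antibody"].unique())

    def timepoints(self) -> list[str]:
        return sorted(self.columns_meta["timepoint"].unique())


def _descending_ranks(values: np.ndarray) -> np.ndarray:
    """Rank each column descending (rank 1 = largest), average ties."""
    return rankdata(-values, axis=0, method="average")


def compute_rank_products(
    matrix: ChipReplicateMatrix, antibody: str, timepoint: str
) -> pd.DataFrame:
    """Rank-product enrichment statistic for one antibody at one timepoint.

    Returns a DataFrame indexed by fragment id with columns ``mean_fold``
    (linear-scale mean enrichment, 2**mean(log2 ratio)), ``rp`` (geometric
    mean of per-replicate descending ranks) and the per-replicate rank
    matrix attached as ``DataFrame.attrs["ranks"]`` for the permutation
    null.
    """
    ip = matrix.select(antibody, timepoint, "ip")
    if ip.shape[1] < 2:
        raise ValueError(
            f"need >= 2 IP replicates for {antibody}/{timepoint}, "
            f"got {ip.shape[1]}"
        )
    values = ip.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite log2 ratios in ChIP matrix")
    ranks = _descending_ranks(values)
    rp = np.exp(np.mean(np.log(ranks), axis=1))
    mean_fold = 2.0 ** values.mean(axis=1)
    out = pd.DataFrame(
        {"mean_fold": mean_fold, "rp": rp},
        index=ip.index.rename("fragment"),
    )
    out.attrs["ranks"] = ranks
    out.attrs["antibody"] = antibody
    out.attrs["timepoint"] = timepoint
    return out


def _null_rp_exhaustive(ranks: np.ndarray) -> np.ndarray:
    """All null rank products from every per-replicate rank shuffle.

    Enumerates the (n!)**k ways of independently permuting each
    replicate's rank vector and returns the pooled null rank products,
    an array of shape ((n!)**k * n,).
    """
    n, k = ranks.shape
    perms = list(itertools.permutations(range(n)))
    log_cols = [np.log(ranks[:, j]) for j in range(k)]
    nulls = []
    for combo in itertools.product(perms, repeat=k):
        s = np.zeros(n)
        for j, perm in enumerate(combo):
            s += log_cols[j][list(perm)]
        nulls.append(np.exp(s / k))
    return np.concatenate(nulls)


def _null_rp_sampled(
    ranks: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sampled null rank products; shape (n_perm * n,)."""
    n, k = ranks.shape
    log_ranks = np.log(ranks)
    s = np.zeros((n_perm, n))
    for j in range(k):
        # independent shuffle of replicate j's rank vector in each perm
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        s += log_ranks[idx, j]
    return np.exp(s / k).ravel()


def permutation_fdr(
    results: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> pd.DataFrame:
    """Estimate a per-fragment FDR for observed rank products.

    For the fragment with the i-th smallest observed rank product, the
    expected number of null rank products at or below it (averaged over
    permutations) is divided by i, clipped to [0, 1] and made monotone
    non-decreasing in i by a step-up pass, so significance is nested in
    rank-product order.

    With ``exhaustive=True`` (or by default when (n!)^k <= 10,000) the
    null is enumerated completely instead of sampled.
    """
    if len(results) == 0:
        raise ValueError("no fragments to estimate FDR for")
    ranks = results.attrs.get("ranks")
    if ranks is None:
        raise ValueError("results must come from compute_rank_products")
    n, k = ranks.shape
    if exhaustive is None:
        exhaustive = math.factorial(n) ** k <= 10_000
    if exhaustive:
        null = _null_rp_exhaustive(ranks)
        n_draws = math.factorial(n) ** k
    else:
        if n_perm < 100:
            warnings.warn(
                f"n_perm={n_perm} is small; FDR estimates will be noisy",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        null = _null_rp_sampled(ranks, n_perm, rng)
        n_draws = n_perm

    order = np.argsort(results["rp"].to_numpy(), kind="stable")
    rp_sorted = results["rp"].to_numpy()[order]
    null.sort()
    # mean count of null rp <= observed rp, per permutation
    exp_fp = np.searchsorted(null, rp_sorted, side="right") / n_draws
    fdr_sorted = exp_fp / np.arange(1, n + 1)
    fdr_sorted = np.clip(fdr_sorted, 0.0, 1.0)
    # step-up: q_i = min_{j >= i} fdr_j, non-decreasing in i
    fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    fdr = np.empty(n)
    fdr[order] = fdr_sorted
    out = results.copy()
    out.attrs.update(results.attrs)
    out["fdr"] = fdr
    return out


def call_enriched(
    results: pd.DataFrame,
    fdr_max: float = 0.02,
    min_fold: float = 1.5,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Flag significantly enriched fragments.

    A fragment is significant iff fdr < fdr_max and mean_fold > min_fold.
    ChIP enrichment is directional, so the default is one-sided (upward);
    ``two_sided=True`` additionally admits depletion below 1/min_fold.
    """
    if "fdr" not in results or "mean_fold" not in results:
        raise ValueError("results must carry fdr and mean_fold columns")
    fold = results["mean_fold"].to_numpy()
    passes_fold = fold > min_fold
    if two_sided:
        passes_fold |= fold < 1.0 / min_fold
    out = results.copy()
    out.attrs.update(results.attrs)
    out["significant"] = (results["fdr"].to_numpy() < fdr_max) & passes_fold
    return out


def intersect_antibodies(
    calls_ab1: pd.DataFrame, calls_ab2: pd.DataFrame
) -> set[str]:
    """Fragments significant with both antibodies at one timepoint.

    Requiring two independent antisera to agree removes fragments
    enriched through non-specific antibody effects.
    """
    tp1 = calls_ab1.attrs.get("timepoint")
    tp2 = calls_ab2.attrs.get("timepoint")
    if tp1 is not None and tp2 is not None and tp1 != tp2:
        raise ValueError(
            f"antibody call sets are from different timepoints: {tp1!r} vs {tp2!r}"
        )
    s1 = set(calls_ab1.index[calls_ab1["significant"]])
    s2 = set(calls_ab2.index[calls_ab2["significant"]])
    return s1 & s2


def merge_bound_regions(
    bound_by_timepoint: dict[str, set[str]],
    fragments: dict[str, TilingFragment],
    fdr_by_timepoint: dict[str, pd.Series] | None = None,
) -> list[BoundRegion]:
    """Merge bound fragments across timepoints into unique regions.

    Takes the union of per-timepoint bound fragment sets and
    single-linkage merges intervals that overlap by >= 1 bp (abutting
    half-open intervals do not merge). Each region records which
    timepoints contributed and the minimum FDR among its fragments.
    Output is sorted by (chrom, start).
    """
    records = []
    for tp, frag_ids in bound_by_timepoint.items():
        for fid in frag_ids:
            frag = fragments[fid]
            fdr = float("nan")
            if fdr_by_timepoint is not None and tp in fdr_by_timepoint:
                fdr = float(fdr_by_timepoint[tp].get(fid, float("nan")))
            records.append((frag.chrom, frag.start, frag.end, fid, tp, fdr))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    regions: list[BoundRegion] = []
    for chrom, start, end, fid, tp, fdr in records:
        if regions and regions[-1].chrom == chrom and start < regions[-1].end:
            reg = regions[-1]
            reg.end = max(reg.end, end)
            if fid not in reg.fragment_ids:
                reg.fragment_ids.append(fid)
            reg.timepoints.add(tp)
            if not math.isnan(fdr):
                reg.min_fdr = fdr if math.isnan(reg.min_fdr) else min(reg.min_fdr, fdr)
        else:
            regions.append(
                BoundRegion(chrom, start, end, [fid], {tp}, fdr)
            )
    return regions


def co_occupancy(
    regions_A: list[BoundRegion], regions_B: list[BoundRegion]
) -> tuple[int, int, int, float]:
    """Two-factor co-occupancy at the region level.

    Returns (n_A, n_B, n_A_cobound, pct_A_cobound) where an A-region is
    co-bound if it overlaps at least one B-region by >= 1 bp; the
    percentage is rounded to one decimal.
    """
    if not regions_A:
        raise ValueError("regions_A is empty; co-occupancy percentage undefined")
    by_chrom: dict[str, list[BoundRegion]] = {}
    for reg in regions_B:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    n_cobound = 0
    for reg in regions_A:
        candidates = by_chrom.get(reg.chrom, ())
        if any(reg.start < b.end and b.start < reg.end for b in candidates):
            n_cobound += 1
    pct = round(100.0 * n_cobound / len(regions_A), 1)
    return len(regions_A), len(regions_B), n_cobound, pct
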