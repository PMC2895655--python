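"""Rank-product enrichment calling, permutation FDR and region logic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coregmap.chip import (
    BoundRegion,
    ChipReplicateMatrix,
    TilingFragment,
    call_enriched,
    co_occupancy,
    compute_rank_products,
    intersect_antibodies,
    merge_bound_regions,
    permutation_fdr,
)


def brute_force_fdr(rp_obs: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Independent oracle: exhaustive null over all per-replicate rank
    shuffles, expected false positives divided by rank, step-up pass."""
    n, k = ranks.shape
    null = []
    for combo in itertools.product(itertools.permutations(range(n)), repeat=k):
        for i in range(n):
            prod = 1.0
            for j, perm in enumerate(combo):
                prod *= ranks[perm[i], j]
            null.append(prod ** (1.0 / k))
    n_draws = math.factorial(n) ** k
    order = np.argsort(rp_obs)
    fdr_sorted = []
    for pos, idx in enumerate(order, start=1):
        count = sum(v <= rp_obs[idx] + 1e-12 for v in null) / n_draws
        fdr_sorted.append(min(count / pos, 1.0))
    for i in range(len(fdr_sorted) - 2, -1, -1):
        fdr_sorted[i] = min(fdr_sorted[i], fdr_sorted[i + 1])
    out = np.empty(n)
    out[order] = fdr_sorted
    return out


class TestRankProducts:
    def test_hand_computed_example(self, toy_chip_matrix):
        """Ranks rep1=(1,2,3), rep2=(1,3,2) give rp (1, sqrt6, sqrt6)."""
        res = compute_rank_products(toy_chip_matrix, "ab1", "T1")
        np.testing.assert_allclose(
            res["rp"].to_numpy(), [1.0, math.sqrt(6), math.sqrt(6)], rtol=1e-12
        )
        np.testing.assert_allclose(
            res["mean_fold"].to_numpy()[0], 2 ** ((1.0 + 0.85) / 2)
        )

    def test_top_fragment_has_rp_one(self, toy_chip_matrix):
        res = compute_rank_products(toy_chip_matrix, "ab1", "T1")
        assert res["rp"].iloc[0] == 1.0

    def test_ties_get_average_ranks(self):
        data = pd.DataFrame(
            {
                "ab1_ip_T1_r1": [0.5, 0.5, -1.0],
                "ab1_ip_T1_r2": [1.0, 0.0, -1.0],
            },
            index=["a", "b", "c"],
        )
        res = compute_rank_products(ChipReplicateMatrix(data), "ab1", "T1")
        # a and b tie at rank (1+2)/2 = 1.5 in replicate 1
        assert res.attrs["ranks"][0, 0] == 1.5
        assert res.attrs["ranks"][1, 0] == 1.5

    def test_requires_two_replicates(self):
        data = pd.DataFrame({"ab1_ip_T1_r1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="2 IP replicates"):
            compute_rank_products(ChipReplicateMatrix(data), "ab1", "T1")

    def test_nan_rejected(self):
        data = pd.DataFrame(
            {"ab1_ip_T1_r1": [0.1, np.nan], "ab1_ip_T1_r2": [0.2, 0.3]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="finite"):
            compute_rank_products(ChipReplicateMatrix(data), "ab1", "T1")

    @given(
        st.lists(
            st.floats(-4, 4, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=4,
            max_size=8,
            unique=True,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, values):
        """Rank products depend only on orderings, so any strictly
        increasing transform of the ratios leaves them unchanged."""
        n = len(values)
        data = pd.DataFrame(
            {
                "ab1_ip_T1_r1": values,
                "ab1_ip_T1_r2": values[::-1],
            },
            index=[f"f{i}" for i in range(n)],
        )
        transformed = data.apply(lambda c: np.exp(c) + c**3)
        r1 = compute_rank_products(ChipReplicateMatrix(data), "ab1", "T1")
        r2 = compute_rank_products(ChipReplicateMatrix(transformed), "ab1", "T1")
        np.testing.assert_allclose(r1["rp"], r2["rp"])


class TestPermutationFdr:
    def test_matches_exhaustive_oracle(self, toy_chip_matrix):
        """(3!)^2 = 36 rank shuffles, enumerated both ways."""
        res = compute_rank_products(toy_chip_matrix, "ab1", "T1")
        got = permutation_fdr(res, exhaustive=True)["fdr"].to_numpy()
        want = brute_force_fdr(res["rp"].to_numpy(), res.attrs["ranks"])
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_sampled_estimate_approaches_oracle(self, toy_chip_matrix):
        res = compute_rank_products(toy_chip_matrix, "ab1", "T1")
        want = brute_force_fdr(res["rp"].to_numpy(), res.attrs["ranks"])
        got = permutation_fdr(res, n_perm=20_000, seed=1, exhaustive=False)[
            "fdr"
        ].to_numpy()
        np.testing.assert_allclose(got, want, atol=0.02)

    def test_exhaustive_oracle_larger_instance(self, rng):
        """4 fragments x 2 replicates: (4!)^2 = 576 shuffles."""
        data = pd.DataFrame(
            rng.normal(size=(4, 2)),
            index=list("abcd"),
            columns=["ab1_ip_T1_r1", "ab1_ip_T1_r2"],
        )
        res = compute_rank_products(ChipReplicateMatrix(data), "ab1", "T1")
        got = permutation_fdr(res, exhaustive=True)["fdr"].to_numpy()
        want = brute_force_fdr(res["rp"].to_numpy(), res.attrs["ranks"])
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_fdr_monotone_in_rank_product(self, rng):
        data = pd.DataFrame(
            rng.normal(size=(50, 3)),
            index=[f"f{i}" for i in range(50)],
            columns=["ab1_ip_T1_r1", "ab1_ip_T1_r2", "ab1_ip_T1_r3"],
        )
        res = compute_rank_products(ChipReplicateMatrix(data), "ab1", "T1")
        res = permutation_fdr(res, n_perm=300, seed=2, exhaustive=False)
        ordered = res.sort_values("rp")["fdr"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            permutation_fdr(pd.DataFrame({"rp": []}))


class TestCallEnriched:
    @pytest.mark.parametrize(
        "fdr,fold,expected",
        [
            (0.015, 1.6, True),   # passes both published thresholds
            (0.015, 1.4, False),  # fails the fold filter
            (0.05, 3.0, False),   # fails the FDR filter
        ],
    )
    def test_threshold_boundaries(self, fdr, fold, expected):
        res = pd.DataFrame({"mean_fold": [fold], "fdr": [fdr]}, index=["f1"])
        out = call_enriched(res, fdr_max=0.02, min_fold=1.5)
        assert bool(out["significant"].iloc[0]) is expected

    def test_two_sided_admits_depletion(self):
        res = pd.DataFrame(
            {"mean_fold": [0.5, 0.8], "fdr": [0.001, 0.001]}, index=["f1", "f2"]
        )
        one = call_enriched(res)
        two = call_enriched(res, two_sided=True)
        assert not one["significant"].any()
        assert two["significant"].tolist() == [True, False]


class TestAntibodyIntersection:
    def _calls(self, sig, timepoint="T1"):
        df = pd.DataFrame({"significant": sig}, index=[f"f{i}" for i in range(len(sig))])
        df.attrs["timepoint"] = timepoint
        return df

    def test_intersection_rules(self):
        ab1 = self._calls([True, True, False])
        ab2 = self._calls([True, False, True])
        assert intersect_antibodies(ab1, ab2) == {"f0"}

    def test_empty_second_set(self):
        ab1 = self._calls([True, True])
        ab2 = self._calls([False, False])
        assert intersect_antibodies(ab1, ab2) == set()

    def test_mismatched_timepoints_error(self):
        with pytest.raises(ValueError, match="timepoint"):
            intersect_antibodies(self._calls([True]), self._calls([True], "T2"))

    def test_never_a_superset(self, rng):
        sig1 = rng.random(20) < 0.5
        sig2 = rng.random(20) < 0.5
        ab1, ab2 = self._calls(sig1), self._calls(sig2)
        both = intersect_antibodies(ab1, ab2)
        assert both <= set(ab1.index[sig1])
        assert both <= set(ab2.index[sig2])


def _frag(fid, start, end, chrom="chrS"):
    return TilingFragment(id=fid, chrom=chrom, start=start, end=end)


class TestMergeRegions:
    def test_overlapping_fragments_merge(self):
        frags = {"a": _frag("a", 0, 3000), "b": _frag("b", 1500, 4500)}
        regions = merge_bound_regions({"T1": {"a", "b"}}, frags)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 4500)

    def test_abutting_fragments_stay_separate(self):
        """Half-open intervals sharing only an endpoint do not overlap."""
        frags = {"a": _frag("a", 0, 3000), "b": _frag("b", 3000, 6000)}
        regions = merge_bound_regions({"T1": {"a", "b"}}, frags)
        assert len(regions) == 2

    def test_timepoints_union_on_same_fragment(self):
        frags = {"a": _frag("a", 0, 3000)}
        regions = merge_bound_regions({"T1": {"a"}, "T2": {"a"}}, frags)
        assert len(regions) == 1
        assert regions[0].timepoints == {"T1", "T2"}

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 10)),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_merged_regions_pairwise_disjoint_and_idempotent(self, intervals):
        frags = {
            f"f{i}": _frag(f"f{i}", s, s + w) for i, (s, w) in enumerate(intervals)
        }
        regions = merge_bound_regions({"T1": set(frags)}, frags)
        # pairwise non-overlap, checked against the naive pairwise oracle
        for r1, r2 in itertools.combinations(regions, 2):
            assert not r1.overlaps(r2)
        # every input fragment is covered by exactly one region
        for f in frags.values():
            hits = [
                r for r in regions if r.start <= f.start and f.end <= r.end
            ]
            assert len(hits) == 1
        # merging the merged regions changes nothing
        frags2 = {
            f"m{i}": _frag(f"m{i}", r.start, r.end) for i, r in enumerate(regions)
        }
        again = merge_bound_regions({"T1": set(frags2)}, frags2)
        assert [(r.start, r.end) for r in again] == [
            (r.start, r.end) for r in regions
        ]


class TestCoOccupancy:
    def test_identical_sets_fully_cobound(self):
        regs = [BoundRegion("chrS", 0, 100), BoundRegion("chrS", 500, 700)]
        assert co_occupancy(regs, regs)[3] == 100.0

    def test_disjoint_chromosomes(self):
        a = [BoundRegion("chr2L", 0, 100)]
        b = [BoundRegion("chr3R", 0, 100)]
        assert co_occupancy(a, b) == (1, 1, 0, 0.0)

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            co_occupancy([], [BoundRegion("chrS", 0, 10)])

    def test_single_bp_overlap_counts(self):
        a = [BoundRegion("chrS", 0, 101)]
        b = [BoundRegion("chrS", 100, 200)]
        assert co_occupancy(a, b)[2] == 1
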