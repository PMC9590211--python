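import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizovir.detection import (
    accumulation_curve,
    aggregate_dna_libraries,
    call_presence,
    compute_cpm,
    greedy_dedup,
)
from rhizovir.types import SourceLibrary


def _breadth(values, votus=None, samples=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    votus = votus or [f"v{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=votus, columns=samples)


class TestCallPresence:
    def test_threshold_is_inclusive(self):
        pm = call_presence(_breadth([[0.75, 0.7499]]))
        assert pm.merged.iloc[0, 0]
        assert not pm.merged.iloc[0, 1]

    def test_breadth_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            call_presence(_breadth([[1.2]]))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_presence(_breadth([[0.5]]), threshold=1.01)

    def test_all_zero_sample_warns(self, caplog):
        with caplog.at_level("WARNING", logger="rhizovir"):
            pm = call_presence(_breadth([[0.0], [0.0]]))
        assert not pm.merged.any().any()
        assert any("no vOTU present" in r.message for r in caplog.records)

    def test_merged_is_or_over_libraries(self):
        b1 = _breadth([[0.9, 0.1]])
        b2 = _breadth([[0.1, 0.8]])
        pm = call_presence(
            {SourceLibrary.DNA_VIROME: b1, SourceLibrary.TOTAL_METAGENOME: b2}
        )
        assert pm.merged.iloc[0].tolist() == [True, True]


class TestComputeCpm:
    def test_arithmetic_oracle(self):
        counts = pd.DataFrame({"s1": [100]}, index=["v1"])
        cpm = compute_cpm(
            counts, pd.Series({"v1": 10_000}), pd.Series({"s1": 1_000_000})
        )
        assert cpm.loc["v1", "s1"] == pytest.approx(10.0)

    def test_zero_count_zero_cpm(self):
        counts = pd.DataFrame({"s1": [0]}, index=["v1"])
        cpm = compute_cpm(counts, pd.Series({"v1": 10_000}), pd.Series({"s1": 1e6}))
        assert cpm.loc["v1", "s1"] == 0.0

    def test_zero_library_size_with_counts_rejected(self):
        counts = pd.DataFrame({"s1": [5]}, index=["v1"])
        with pytest.raises(ValueError, match="library size"):
            compute_cpm(counts, pd.Series({"v1": 10_000}), pd.Series({"s1": 0.0}))

    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=3, max_size=3),
        scale=st.integers(2, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_joint_scale_invariance(self, counts, scale):
        lengths = pd.Series({"v0": 10_000, "v1": 25_000, "v2": 5_000})
        base = pd.DataFrame({"s1": counts}, index=lengths.index)
        c1 = compute_cpm(base, lengths, pd.Series({"s1": 2e6}))
        c2 = compute_cpm(base * scale, lengths, pd.Series({"s1": 2e6 * scale}))
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    @given(counts=st.lists(st.integers(0, 1000), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_counts(self, counts):
        lengths = pd.Series({"v0": 10_000, "v1": 20_000})
        size = pd.Series({"s1": 1e6})
        base = pd.DataFrame({"s1": counts}, index=lengths.index)
        assert np.allclose(
            compute_cpm(base * 3, lengths, size).to_numpy(),
            3 * compute_cpm(base, lengths, size).to_numpy(),
        )


class TestAggregate:
    def test_median_of_two_is_mean(self):
        a = pd.DataFrame({"s1": [4.0]}, index=["v1"])
        b = pd.DataFrame({"s1": [6.0]}, index=["v1"])
        assert aggregate_dna_libraries(a, b).loc["v1", "s1"] == 5.0

    def test_single_available_value_used(self):
        a = pd.DataFrame({"s1": [4.0]}, index=["v1"])
        b = pd.DataFrame({"s2": [7.0]}, index=["v1"])  # s1 absent here
        agg = aggregate_dna_libraries(a, b)
        assert agg.loc["v1", "s1"] == 4.0
        assert agg.loc["v1", "s2"] == 7.0

    def test_masking_by_presence(self):
        a = pd.DataFrame({"s1": [4.0], "s2": [5.0]}, index=["v1"])
        pm = call_presence(_breadth([[0.9, 0.1]], votus=["v1"], samples=["s1", "s2"]))
        agg = aggregate_dna_libraries(a, a, presence=pm)
        assert agg.loc["v1", "s1"] == 4.0
        assert agg.loc["v1", "s2"] == 0.0

    def test_support_subset_of_presence(self, small_bundle):
        bundle = small_bundle["bundle"]
        catalog = small_bundle["catalog"]
        lengths = catalog.lengths()
        pm = call_presence(bundle.coverage_breadth)
        cpms = {
            lib: compute_cpm(cnt, lengths, bundle.library_sizes[lib])
            for lib, cnt in bundle.dna_counts.items()
        }
        agg = aggregate_dna_libraries(
            cpms[SourceLibrary.DNA_VIROME],
            cpms[SourceLibrary.TOTAL_METAGENOME],
            presence=pm,
        )
        support = agg.to_numpy() > 0
        mask = pm.merged.reindex(index=agg.index, columns=agg.columns).to_numpy()
        assert (support <= mask).all()


class TestAccumulationCurve:
    def test_ubiquitous_votu_flat_curve(self):
        presence = pd.DataFrame(True, index=["v1"], columns=list("abcd"))
        curve = accumulation_curve(presence, n_permutations=10, seed=0)
        assert (curve["mean_richness"] == 1.0).all()

    def test_disjoint_singletons_linear(self):
        presence = pd.DataFrame(np.eye(4, dtype=bool), columns=list("abcd"))
        curve = accumulation_curve(presence, n_permutations=10, seed=0)
        assert curve["mean_richness"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_monotone_nondecreasing(self, rng):
        presence = pd.DataFrame(
            rng.random((30, 8)) < 0.3, columns=[f"s{j}" for j in range(8)]
        )
        curve = accumulation_curve(presence, n_permutations=50, seed=1)
        assert (np.diff(curve["mean_richness"]) >= -1e-12).all()

    def test_matches_exhaustive_permutation_average(self, rng):
        # brute-force oracle: average over all 5! orderings
        presence = pd.DataFrame(
            rng.random((12, 5)) < 0.4, columns=[f"s{j}" for j in range(5)]
        )
        arr = presence.to_numpy()
        expected = np.zeros(5)
        n_perm = 0
        for order in itertools.permutations(range(5)):
            seen = np.zeros(arr.shape[0], dtype=bool)
            for k, j in enumerate(order):
                seen = seen | arr[:, j]
                expected[k] += seen.sum()
            n_perm += 1
        expected /= n_perm
        curve = accumulation_curve(presence, n_permutations=4000, seed=3)
        assert np.allclose(curve["mean_richness"], expected, atol=0.25)


def _pairs(rows):
    return pd.DataFrame(rows, columns=["a", "b", "identity", "aligned_fraction"])


def _naive_greedy(pairs, lengths, id_thr, cov_thr):
    """Independent re-statement of the greedy rule for cross-checking."""
    lookup = {}
    for _, r in pairs.iterrows():
        if r["a"] == r["b"]:
            continue
        key = frozenset((r["a"], r["b"]))
        cand = (r["identity"], r["aligned_fraction"])
        if key not in lookup or cand > lookup[key]:
            lookup[key] = cand
    order = sorted(lengths.index, key=lambda i: (-lengths[i], i))
    reps, assign = [], {}
    for m in order:
        for rep in reps:
            hit = lookup.get(frozenset((m, rep)))
            if hit and hit[0] >= id_thr and hit[1] >= cov_thr:
                assign[m] = rep
                break
        else:
            reps.append(m)
            assign[m] = m
    return assign


class TestGreedyDedup:
    def test_identical_pair_clusters_longer_representative(self):
        pairs = _pairs([("A", "B", 1.0, 1.0)])
        lengths = pd.Series({"A": 20_000, "B": 15_000})
        out = greedy_dedup(pairs, lengths)
        assert out["A"] == "A" and out["B"] == "A"

    def test_identity_boundary(self):
        pairs = _pairs([("A", "B", 0.94, 1.0)])
        lengths = pd.Series({"A": 20_000, "B": 15_000})
        out = greedy_dedup(pairs, lengths)
        assert out["B"] == "B"

    def test_coverage_boundary(self):
        pairs = _pairs([("A", "B", 0.99, 0.94)])
        lengths = pd.Series({"A": 20_000, "B": 15_000})
        assert greedy_dedup(pairs, lengths)["B"] == "B"

    def test_chain_is_greedy_not_single_linkage(self):
        pairs = _pairs(
            [("A", "B", 0.97, 1.0), ("B", "C", 0.97, 1.0), ("A", "C", 0.5, 1.0)]
        )
        lengths = pd.Series({"A": 30_000, "B": 20_000, "C": 10_000})
        out = greedy_dedup(pairs, lengths)
        assert out["A"] == "A" and out["B"] == "A" and out["C"] == "C"

    def test_matches_naive_oracle_on_random_fixtures(self, rng):
        ids = list("ABCDEF")
        for trial in range(25):
            lengths = pd.Series(
                rng.integers(5_000, 50_000, size=6), index=ids
            )
            rows = [
                (a, b, float(rng.random()), float(rng.random()))
                for a, b in itertools.combinations(ids, 2)
                if rng.random() < 0.7
            ]
            pairs = _pairs(rows)
            got = greedy_dedup(pairs, lengths, 0.5, 0.5)
            want = _naive_greedy(pairs, lengths, 0.5, 0.5)
            assert got.to_dict() == want

    def test_deterministic_with_lexicographic_ties(self):
        pairs = _pairs([("A", "B", 1.0, 1.0)])
        lengths = pd.Series({"A": 10_000, "B": 10_000})
        out = greedy_dedup(pairs, lengths)
        assert out["A"] == "A" and out["B"] == "A"
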