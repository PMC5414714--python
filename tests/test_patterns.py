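"""PAM k-medoids, leading-pattern derivation, and weighted correlation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tumortyper as tt


def brute_force_medoid_cost(points, k):
    """Exhaustive optimum over all medoid subsets (oracle for small n)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 1)
    n = len(pts)
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return min(
        D[:, list(meds)].min(axis=1).sum() for meds in combinations(range(n), k)
    )


class TestKMedoids:
    def test_well_separated_1d_clusters(self):
        pts = np.array([0.0, 0.1, 5.0, 5.1, 10.0])
        labels, medoids = tt.kmedoids(pts, 3)
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, set()).add(i)
        assert sorted(map(frozenset, groups.values()), key=min) == [
            frozenset({0, 1}), frozenset({2, 3}), frozenset({4})
        ]

    def test_k_equals_n_zero_cost(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        labels, medoids = tt.kmedoids(pts, 3)
        assert sorted(medoids.tolist()) == [0, 1, 2]
        assert len(set(labels)) == 3

    def test_k_one_is_geometric_medoid(self):
        pts = np.array([0.0, 1.0, 2.0, 10.0])
        _, medoids = tt.kmedoids(pts, 1)
        # point 2 minimises summed distance (2+1+0+8=11 vs 1: 1+0+1+9=11...)
        sums = [abs(pts - p).sum() for p in pts]
        assert sums[medoids[0]] == min(sums)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            tt.kmedoids(np.zeros((3, 1)), 0)
        with pytest.raises(ValueError):
            tt.kmedoids(np.zeros((3, 1)), 4)

    def test_duplicates_allowed(self):
        labels, medoids = tt.kmedoids(np.zeros((4, 2)), 2)
        assert len(medoids) == 2

    def test_matches_brute_force_on_random_instances(self):
        """PAM cost equals the exhaustive optimum (n <= 8, k <= 3)."""
        rng = np.random.default_rng(13)
        for trial in range(60):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, min(3, n) + 1))
            pts = rng.random((n, int(rng.integers(1, 4))))
            labels, medoids = tt.kmedoids(pts, k)
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            cost = D[:, medoids].min(axis=1).sum()
            assert cost == pytest.approx(brute_force_medoid_cost(pts, k), abs=1e-9)


class TestDerivePatterns:
    @staticmethod
    def votes_frame(mean_by_type, n_samples=12, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        data = {
            t: np.clip(m + noise * rng.standard_normal(n_samples), 0, 12)
            for t, m in mean_by_type.items()
        }
        return pd.DataFrame(data, index=[f"s{i}" for i in range(n_samples)])

    def test_high_and_low_groups_found(self):
        means = {"T1": 10.2, "T2": 9.8, "T3": 10.0, "T4": 9.9,
                 "T5": 1.1, "T6": 0.9,
                 "T7": 6.0, "T8": 6.1, "T9": 5.9}
        votes = self.votes_frame(means, seed=1)
        ps = tt.derive_patterns(votes, tt.PatternConfig())
        assert set(ps.up_types) == {"T1", "T2", "T3", "T4"}
        assert set(ps.bottom_types) == {"T5", "T6"}
        assert ps.k_used == 3

    def test_oversized_up_cluster_truncated_to_cap(self):
        # 7 high types form one tight blob while the remaining types are far
        # apart, so extra medoids always go to the spread-out singletons, the
        # blob never splits, and the cap truncates it to the 5 highest means
        means = {f"H{i}": 10.0 + 0.001 * i for i in range(7)}
        means.update({"L1": 1.0, "M1": 3.0, "M2": 4.5, "M3": 6.0, "M4": 7.5})
        votes = self.votes_frame(means, noise=0.01, seed=2)
        ps = tt.derive_patterns(votes, tt.PatternConfig())
        assert len(ps.up_types) == 5
        assert set(ps.up_types) == {"H6", "H5", "H4", "H3", "H2"}

    def test_identical_profiles_trigger_fallback(self):
        votes = pd.DataFrame(
            np.full((6, 10), 6.0),
            index=[f"s{i}" for i in range(6)],
            columns=[f"T{i}" for i in range(10)],
        )
        ps = tt.derive_patterns(votes, tt.PatternConfig())
        assert ps.k_used == 0
        assert len(ps.up_types) == 5 and len(ps.bottom_types) == 3
        assert not set(ps.up_types) & set(ps.bottom_types)

    def test_reference_type_may_lead_its_own_up_pattern(self, small_model):
        model, _, _ = small_model
        self_in_up = [
            c for c, ps in model.patterns.items() if c in ps.up_types
        ]
        assert self_in_up  # a type votes for itself strongly


class TestPatternWeights:
    def test_weight_assignment(self):
        types = ["OV", "LUAD", "HNSC", "LUSC", "THCA", "LAML", "GBM"]
        ps = tt.PatternSet(
            "LUSC", ("OV", "LUAD", "HNSC", "LUSC"), ("THCA", "LAML"), 3
        )
        w = tt.pattern_weights(ps, types)
        assert w[["OV", "LUAD", "HNSC", "LUSC"]].tolist() == [3.0] * 4
        assert w[["THCA", "LAML"]].tolist() == [0.1, 0.1]
        assert w["GBM"] == 1.0

    def test_empty_patterns_all_ones(self):
        ps = tt.PatternSet("A", (), (), 0)
        w = tt.pattern_weights(ps, ["A", "B", "C"])
        assert (w == 1.0).all()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            tt.PatternSet("A", ("B",), ("B",), 3)


class TestWeightedCorrelation:
    def test_unit_weights_equal_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(18), rng.random(18)
        mine = tt.weighted_correlation(x, y, np.ones(18))
        ref = np.corrcoef(x, y)[0, 1]
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_zero_weight_excludes_component(self):
        r = tt.weighted_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 100.0], [1.0, 1.0, 0.0])
        assert r == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        """Independent direct-formula computation on random 18-vectors."""
        rng = np.random.default_rng(17)
        w = np.ones(18)
        w[:3] = 3.0
        w[-2:] = 0.1
        for _ in range(10):
            x, y = rng.random(18), rng.random(18)
            W = w.sum()
            xb, yb = (w * x).sum() / W, (w * y).sum() / W
            expected = ((w * (x - xb) * (y - yb)).sum()
                        / np.sqrt((w * (x - xb) ** 2).sum() * (w * (y - yb) ** 2).sum()))
            assert tt.weighted_correlation(x, y, w) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_bounds_symmetry_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.random(8), rng.random(8)
        w = rng.random(8) + 0.05
        r = tt.weighted_correlation(x, y, w)
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        assert r == pytest.approx(tt.weighted_correlation(y, x, w), abs=1e-12)
        assert r == pytest.approx(tt.weighted_correlation(a * x + b, y, w), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tt.weighted_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            tt.weighted_correlation([1.0, 2.0], [1.0, 2.0], [-1.0, 1.0])


class TestWeightedRank:
    @staticmethod
    def toy_centroids():
        idx = ["A", "B", "C"]
        C = pd.DataFrame(
            {"A": [8.0, 3.0, 1.0], "B": [3.0, 8.0, 1.0], "C": [1.0, 1.0, 9.0]},
            index=idx,
        )
        return C

    def test_unit_weight_table_reduces_to_plain_ranking(self):
        C = self.toy_centroids()
        x = pd.Series([7.0, 4.0, 1.5], index=C.index)
        table = pd.DataFrame(1.0, index=C.index, columns=C.columns)
        plain = tt.correlation_rank(x, C, k=3)
        weighted = tt.weighted_rank(x, C, table, k=3)
        assert plain.ranking == weighted.ranking  # bit-identical path

    def test_empty_weight_table_reduces_too(self):
        C = self.toy_centroids()
        x = pd.Series([7.0, 4.0, 1.5], index=C.index)
        empty = pd.DataFrame(index=C.index)
        assert tt.weighted_rank(x, C, empty).ranking == tt.correlation_rank(x, C).ranking

    def test_upweighting_discriminative_components_lifts_true_type(self):
        """A vote vector that plain Pearson ranks 2nd is promoted once the
        true type's up-pattern components (its two highest-centroid entries)
        carry weight 3."""
        idx = ["A", "B", "C", "D", "E"]
        C = pd.DataFrame(
            {
                "A": [5.59, 2.99, 2.93, 4.01, 3.53],
                "B": [6.88, 4.23, 0.50, 0.00, 4.24],
            },
            index=idx,
        )
        x = pd.Series([4.48, 1.45, 1.75, 1.67, 4.56], index=idx)
        plain = tt.correlation_rank(x, C, k=1)
        assert plain.top1 == "B"
        # A's up-pattern = its two largest centroid components: A and D
        table = pd.DataFrame({"A": [3.0, 1.0, 1.0, 3.0, 1.0]}, index=idx)
        weighted = tt.weighted_rank(x, C, table, k=1)
        assert weighted.top1 == "A"

    def test_vanishing_bottom_weight_limit(self):
        C = self.toy_centroids()
        x = pd.Series([7.0, 4.0, 1.5], index=C.index)
        # candidate A's bottom-pattern component is C; as its weight -> 0 the
        # score approaches the two-point weighted correlation without C
        score_no_c = tt.weighted_correlation(
            x[["A", "B"]], C.loc[["A", "B"], "A"], [1.0, 1.0]
        )
        w = pd.DataFrame({"A": [1.0, 1.0, 1e-9]}, index=C.index)
        scores = dict(tt.weighted_rank(x, C, w, k=3).ranking)
        assert scores["A"] == pytest.approx(score_no_c, abs=1e-6)
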