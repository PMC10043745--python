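import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import planshare as ps
from planshare.errors import InvalidInputError
from planshare.mechanism import (
    SCALED,
    ClusterModel,
    compute_plan_triplets,
    kmeans_classify,
    label_clusters,
    rank_plan_types,
    scale_triplets,
)
from planshare.rng import substream

from conftest import make_claims
from lloyd_oracle import lloyd_bruteforce


def _claims(copays=None, coins_allowed=None, ded_by_enrollee_year=None, plan="P1"):
    """Build a claims table with explicit cost-share components."""
    rows = []
    i = 0
    for c in copays or []:
        rows.append((f"E{i}", plan, "2016-01-01", "99213", "", 500.0, c, 0.0, 0.0))
        i += 1
    for coins, allowed in coins_allowed or []:
        rows.append((f"E{i}", plan, "2016-01-02", "99213", "", allowed, 0.0, coins, 0.0))
        i += 1
    for eid, year, ded in ded_by_enrollee_year or []:
        rows.append((eid, plan, f"{year}-03-01", "99213", "", ded, 0.0, 0.0, ded))
    return make_claims(rows)


class TestTriplets:
    def test_mode_copay(self):
        tri = compute_plan_triplets(_claims(copays=[25.0, 25.0, 10.0]))
        assert tri["mode_copay"].iloc[0] == 25.0

    def test_mode_copay_tie_breaks_to_smaller(self):
        tri = compute_plan_triplets(_claims(copays=[25.0, 10.0]))
        assert tri["mode_copay"].iloc[0] == 10.0

    def test_mode_coinsurance_ratio_rounded(self):
        tri = compute_plan_triplets(
            _claims(coins_allowed=[(20.0, 100.0), (30.0, 150.0), (10.0, 100.0)])
        )
        assert tri["mode_coinsurance_rate"].iloc[0] == pytest.approx(0.20)

    def test_zero_allowed_claims_skipped_in_ratio(self):
        claims = _claims(coins_allowed=[(20.0, 100.0)])
        zero = claims.iloc[[0]].assign(allowed_amount=0.0, coinsurance=0.0)
        tri = compute_plan_triplets(pd.concat([claims, zero, zero]))
        assert tri["mode_coinsurance_rate"].iloc[0] == pytest.approx(0.20)

    def test_max_deductible_is_max_of_enrollee_annual_sums(self):
        tri = compute_plan_triplets(
            _claims(ded_by_enrollee_year=[("A", 2016, 300.0), ("A", 2016, 200.0),
                                          ("B", 2016, 400.0)])
        )
        assert tri["max_deductible"].iloc[0] == 500.0

    def test_deductible_sums_are_per_year(self):
        tri = compute_plan_triplets(
            _claims(ded_by_enrollee_year=[("A", 2015, 300.0), ("A", 2016, 400.0)])
        )
        assert tri["max_deductible"].iloc[0] == 400.0

    def test_empty_claims_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_plan_triplets(make_claims([]))


class TestScaling:
    def _tri(self, copays):
        return pd.DataFrame(
            {
                "plan_id": [f"P{i}" for i in range(len(copays))],
                "mode_copay": copays,
                "mode_coinsurance_rate": np.linspace(0, 0.3, len(copays)),
                "max_deductible": np.linspace(0, 1000, len(copays)),
            }
        )

    def test_printed_orientation_sends_max_to_zero(self):
        s = scale_triplets(self._tri([0.0, 50.0, 100.0]), "as_printed")
        assert s["s_copay"].tolist() == [1.0, 0.5, 0.0]

    def test_standard_orientation_sends_min_to_zero(self):
        s = scale_triplets(self._tri([0.0, 50.0, 100.0]), "standard")
        assert s["s_copay"].tolist() == [0.0, 0.5, 1.0]

    def test_degenerate_component_maps_to_zero(self):
        tri = self._tri([20.0, 20.0, 20.0])
        s = scale_triplets(tri)
        assert (s["s_copay"] == 0.0).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(0, 1000, allow_nan=False), min_size=3, max_size=10, unique=True
        ),
        scale=st.floats(0.1, 10),
        shift=st.floats(0, 100),
    )
    def test_scaling_invariant_to_affine_transforms(self, values, scale, shift):
        tri = self._tri(values)
        tri2 = tri.assign(mode_copay=tri["mode_copay"] * scale + shift)
        s1 = scale_triplets(tri)["s_copay"]
        s2 = scale_triplets(tri2)["s_copay"]
        assert np.allclose(s1, s2, atol=1e-9)


def _scaled_frame(points):
    return pd.DataFrame(
        {
            "plan_id": [f"P{i}" for i in range(len(points))],
            "s_copay": [p[0] for p in points],
            "s_coinsurance": [p[1] for p in points],
            "s_deductible": [p[2] for p in points],
        }
    )


class TestKmeans:
    def test_planted_blobs_recovered_perfectly(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.9, 0.1, 0.1], [0.1, 0.9, 0.1], [0.1, 0.1, 0.9], [0.5, 0.5, 0.5]])
        pts = np.vstack([c + rng.normal(0, 0.02, size=(25, 3)) for c in centers])
        model = kmeans_classify(_scaled_frame(pts), seed=4)
        labels = model.assignments.to_numpy().reshape(4, 25)
        assert all(len(set(row)) == 1 for row in labels)
        assert len({row[0] for row in labels}) == 4

    def test_identical_points_collapse_to_sse_zero(self):
        pts = np.tile([0.3, 0.3, 0.3], (10, 1))
        model = kmeans_classify(_scaled_frame(pts), seed=1)
        assert model.sse == 0.0
        assert model.assignments.nunique() == 1

    def test_determinism(self):
        rng = np.random.default_rng(3)
        pts = rng.random((30, 3))
        m1 = kmeans_classify(_scaled_frame(pts), seed=7)
        m2 = kmeans_classify(_scaled_frame(pts), seed=7)
        assert np.array_equal(m1.centers, m2.centers)
        assert m1.assignments.equals(m2.assignments)

    def test_fewer_than_four_plans_rejected(self):
        with pytest.raises(InvalidInputError):
            kmeans_classify(_scaled_frame(np.random.rand(3, 3)), seed=0)

    def test_sse_non_increasing_without_reseeds(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            pts = rng.random((60, 3))
            model = kmeans_classify(_scaled_frame(pts), seed=seed)
            if model.reseed_events:
                continue
            diffs = np.diff(model.sse_history)
            assert (diffs <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle_on_tiny_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        pts = rng.random((n, 3))
        init = np.vstack([rng.random((3, 3)), np.zeros((1, 3))])
        model = kmeans_classify(_scaled_frame(pts), seed=seed, init_centers=init)
        o_assign, o_centers, o_sse = lloyd_bruteforce(
            [list(p) for p in pts], [list(c) for c in init]
        )
        assert model.assignments.tolist() == o_assign
        assert np.allclose(model.centers, np.array(o_centers), atol=1e-12)
        assert model.sse == pytest.approx(o_sse, abs=1e-12)


class TestLabeling:
    def _model(self, centers):
        return ClusterModel(
            centers=np.array(centers), assignments=pd.Series(dtype=int),
            n_iterations=1, seed=0,
        )

    def test_one_hot_centers_labeled_by_argmax(self):
        model = self._model(
            [[0.9, 0.1, 0.1], [0.1, 0.9, 0.1], [0.1, 0.1, 0.9], [0.4, 0.4, 0.4]]
        )
        labels = label_clusters(model, orientation="standard")
        assert labels == {0: "copay", 1: "coinsurance", 2: "deductible", 3: "balanced"}

    def test_printed_orientation_is_undone_before_labeling(self):
        # same geometry, inverted coordinates
        model = self._model(
            [[0.1, 0.9, 0.9], [0.9, 0.1, 0.9], [0.9, 0.9, 0.1], [0.6, 0.6, 0.6]]
        )
        labels = label_clusters(model, orientation="as_printed")
        assert labels == {0: "copay", 1: "coinsurance", 2: "deductible", 3: "balanced"}

    def test_conflicting_claims_resolved_by_larger_coordinate(self):
        model = self._model(
            [[0.9, 0.1, 0.1], [0.8, 0.15, 0.1], [0.1, 0.1, 0.9], [0.4, 0.4, 0.4]]
        )
        labels = label_clusters(model, orientation="standard")
        assert labels[0] == "copay"           # wins the copay dimension
        assert labels[1] == "coinsurance"     # falls back to next-largest unclaimed
        assert labels[2] == "deductible"
        assert labels[3] == "balanced"


class TestRanking:
    def _oopc(self, mapping):
        rows = []
        for plan, vals in mapping.items():
            for i, v in enumerate(vals):
                rows.append((f"{plan}-E{i}", plan, v))
        return pd.DataFrame(rows, columns=["enrollee_id", "plan_id", "oopc_all_medical"])

    def test_rank_order_follows_type_means(self):
        assignments = pd.DataFrame(
            {
                "plan_id": ["A", "B", "C", "D"],
                "plan_type": ["coinsurance", "balanced", "copay", "deductible"],
            }
        )
        oopc = self._oopc({"A": [945.0], "B": [1017.0], "C": [1020.0], "D": [1186.0]})
        ranked, stats = rank_plan_types(assignments, oopc)
        order = stats.sort_values("oopc_rank")["plan_type"].tolist()
        assert order == ["coinsurance", "balanced", "copay", "deductible"]
        assert set(stats["oopc_rank"]) == {1, 2, 3, 4}

    def test_statistic_is_unweighted_mean_of_plan_means(self):
        # plan A has many enrollees but its *plan mean* enters once
        assignments = pd.DataFrame(
            {"plan_id": ["A", "B"], "plan_type": ["copay", "copay"]}
        )
        oopc = self._oopc({"A": [100.0] * 10, "B": [300.0]})
        _, stats = rank_plan_types(assignments, oopc)
        assert stats["mean_oopc"].iloc[0] == pytest.approx(200.0)

    def test_rank_invariant_to_plan_order(self):
        assignments = pd.DataFrame(
            {
                "plan_id": ["A", "B", "C", "D"],
                "plan_type": ["coinsurance", "balanced", "copay", "deductible"],
            }
        )
        oopc = self._oopc({"A": [900.0], "B": [1000.0], "C": [1100.0], "D": [1200.0]})
        r1, s1 = rank_plan_types(assignments, oopc)
        r2, s2 = rank_plan_types(assignments.iloc[::-1].reset_index(drop=True), oopc)
        assert s1.set_index("plan_type")["oopc_rank"].to_dict() == \
               s2.set_index("plan_type")["oopc_rank"].to_dict()


class TestRecovery:
    def test_label_accuracy_on_separated_universes(self):
        accs = []
        for seed in range(5):
            plans = ps.generate_plans(200, (0.25, 0.25, 0.25, 0.25),
                                      separation=2.0, seed=seed)
            claims, _ = ps.generate_claims(plans, year=2016, seed=seed)
            assignments, _, _ = ps.classify_plans(claims, seed=seed, n_restarts=3)
            truth = {p.plan_id: p.true_type for p in plans}
            accs.append(
                (assignments["plan_type"] == assignments["plan_id"].map(truth)).mean()
            )
        assert np.mean(accs) >= 0.95

    def test_cross_check_against_sklearn_from_same_init(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(12)
        centers = np.array([[0.9, 0.1, 0.1], [0.1, 0.9, 0.1], [0.1, 0.1, 0.9], [0.5, 0.5, 0.5]])
        pts = np.vstack([c + rng.normal(0, 0.03, size=(20, 3)) for c in centers])
        init = np.vstack([rng.random((3, 3)), np.zeros((1, 3))])
        ours = kmeans_classify(_scaled_frame(pts), seed=0, init_centers=init)
        sk = KMeans(n_clusters=4, init=init, n_init=1, algorithm="lloyd").fit(pts)
        # same partition (cluster indices may permute)
        ours_part = pd.Series(ours.assignments.to_numpy()).groupby(
            sk.labels_
        ).nunique()
        assert (ours_part == 1).all()
        assert ours.sse == pytest.approx(sk.inertia_, rel=1e-9)
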