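"""Tests for dyadic distances, networks, assortativity and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dialectscope import social_tracking as st
from dialectscope.synthetic_data import (
    BirdRecord,
    ExperimentDesign,
    PreferenceModel,
    simulate_tracking,
)


def _bird(bid, sex="M", pop="D1", code="DD"):
    return BirdRecord(
        bird_id=bid, sex=sex, genetic_pop=pop, rearing_pop=pop, lineage_code=code,
        rearing_aviary=f"{pop}-A1", generation=2, body_size=14.0,
    )


def _fixes(rows):
    return pd.DataFrame(rows, columns=["timestamp", "day_index", "bird_id", "x_mm",
                                       "y_mm", "station_id"])


class TestDyadDailyDistances:
    def test_345_triangle(self):
        birds = [_bird("f", "F"), _bird("m", "M")]
        rows = []
        for t in range(5):
            rows.append((2 * t, 0, "f", 0.0, 0.0, "P1"))
            rows.append((2 * t, 0, "m", 3000.0, 4000.0, "P2"))
        daily = st.dyad_daily_distances(_fixes(rows), birds)
        assert len(daily) == 1
        row = daily.iloc[0]
        assert row["mean_distance_mm"] == pytest.approx(5000.0)
        assert row["ln_distance"] == pytest.approx(np.log(5000.0))
        assert row["n_simultaneous_fixes"] == 5
        assert row["bird_a"] == "f"  # female listed first for MF dyads

    def test_undetected_bird_yields_missing_dyads(self):
        birds = [_bird("f", "F"), _bird("m", "M"), _bird("g", "F")]
        rows = [(0, 0, "f", 0, 0, "P1"), (0, 0, "m", 10, 0, "P1")]
        daily = st.dyad_daily_distances(_fixes(rows), birds)
        assert set(zip(daily["bird_a"], daily["bird_b"])) == {("f", "m")}

    def test_duplicate_fix_rejected(self):
        birds = [_bird("f", "F"), _bird("m", "M")]
        rows = [(0, 0, "f", 0, 0, "P1"), (0, 0, "f", 5, 5, "P2")]
        with pytest.raises(ValueError, match="duplicate"):
            st.dyad_daily_distances(_fixes(rows), birds)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        birds = [_bird("a", "F"), _bird("b", "M"), _bird("c", "F", "W1", "WW"),
                 _bird("d", "M", "W1", "WW")]
        rows = []
        for t in range(10):
            for b in birds:
                if rng.random() < 0.7:
                    rows.append((2 * t, 0, b.bird_id, rng.uniform(0, 5000),
                                 rng.uniform(0, 2000), "P1"))
        fixes = _fixes(rows)
        daily = st.dyad_daily_distances(fixes, birds)
        # brute force: loop over all tick/dyad combinations
        pos = {(r.timestamp, r.bird_id): (r.x_mm, r.y_mm) for r in fixes.itertuples()}
        ids = [b.bird_id for b in birds]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ds = []
                for t in range(10):
                    pa, pb = pos.get((2 * t, ids[i])), pos.get((2 * t, ids[j]))
                    if pa and pb:
                        ds.append(np.hypot(pa[0] - pb[0], pa[1] - pb[1]))
                sub = daily[
                    ((daily["bird_a"] == ids[i]) & (daily["bird_b"] == ids[j]))
                    | ((daily["bird_a"] == ids[j]) & (daily["bird_b"] == ids[i]))
                ]
                if ds:
                    assert sub.iloc[0]["mean_distance_mm"] == pytest.approx(np.mean(ds))
                else:
                    assert sub.empty

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        birds = [_bird("a", "F"), _bird("b", "M"), _bird("c", "M")]
        rows = [
            (2 * t, d, b.bird_id, rng.uniform(0, 5000), rng.uniform(0, 2000), "P1")
            for t in range(6) for d in range(2) for b in birds if rng.random() < 0.8
        ]
        f1 = _fixes(rows)
        f2 = f1.sample(frac=1.0, random_state=3).reset_index(drop=True)
        d1 = st.dyad_daily_distances(f1, birds).sort_values(
            ["bird_a", "bird_b", "day_index"]).reset_index(drop=True)
        d2 = st.dyad_daily_distances(f2, birds).sort_values(
            ["bird_a", "bird_b", "day_index"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(d1, d2)


class TestNearest:
    def test_geometrically_closer_male_wins(self):
        birds = [_bird("f", "F"), _bird("m1"), _bird("m2")]
        rows = []
        for t in range(3):
            rows += [(2 * t, 0, "f", 0, 0, "P1"), (2 * t, 0, "m1", 100, 0, "P1"),
                     (2 * t, 0, "m2", 2000, 0, "P2")]
        period = st.aggregate_dyads(st.dyad_daily_distances(_fixes(rows), birds))
        nearest, recip = st.nearest_opposite_sex(period)
        assert nearest.set_index("bird_id").loc["f", "nearest"] == "m1"

    def test_two_bird_reciprocity(self):
        birds = [_bird("f", "F"), _bird("m")]
        rows = [(0, 0, "f", 0, 0, "P1"), (0, 0, "m", 10, 0, "P1")]
        period = st.aggregate_dyads(st.dyad_daily_distances(_fixes(rows), birds))
        _, recip = st.nearest_opposite_sex(period)
        assert recip == 1.0

    def test_no_opposite_sex_data_rejected(self):
        birds = [_bird("m1"), _bird("m2")]
        rows = [(0, 0, "m1", 0, 0, "P1"), (0, 0, "m2", 10, 0, "P1")]
        period = st.aggregate_dyads(st.dyad_daily_distances(_fixes(rows), birds))
        with pytest.raises(ValueError):
            st.nearest_opposite_sex(period)


class TestConcordance:
    def _nearest_frame(self, n, n_hit):
        rows = []
        pairs = []
        for i in range(n):
            rows.append({"bird_id": f"f{i}", "nearest": f"m{i}",
                         "mean_distance_mm": 100.0 + i, "n_simultaneous_fixes": 10})
            partner = f"m{i}" if i < n_hit else f"m{(i + 1) % n}"
            pairs.append((f"f{i}", partner))
        return pd.DataFrame(rows), pairs

    def test_worked_example_74_of_151(self):
        nearest, pairs = self._nearest_frame(151, 74)
        out = st.concordance_with_pairs(nearest, pairs)
        assert out["n_concordant"] == 74
        assert out["percentage"] == 49

    def test_all_and_none(self):
        nearest, pairs = self._nearest_frame(10, 10)
        assert st.concordance_with_pairs(nearest, pairs)["percentage"] == 100
        nearest, pairs = self._nearest_frame(10, 0)
        assert st.concordance_with_pairs(nearest, pairs)["percentage"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.concordance_with_pairs(pd.DataFrame(), [])


def _net(edges, cats, sexes=None):
    """edges: list of (u, v, w); cats: {node: level}."""
    nodes = sorted(cats)
    idx = {n: i for i, n in enumerate(nodes)}
    attrs = {"rearing_pop": dict(cats),
             "sex": sexes or {n: "M" for n in nodes}}
    return st.ProximityNetwork(
        nodes=nodes,
        node_attrs=attrs,
        edges_u=np.array([idx[u] for u, _, _ in edges]),
        edges_v=np.array([idx[v] for _, v, _ in edges]),
        weights=np.array([w for _, _, w in edges], dtype=float),
    )


class TestAssortativity:
    def test_perfectly_assortative(self):
        net = _net([("f1", "m1", 1.0), ("f2", "m2", 1.0)],
                   {"f1": "D", "m1": "D", "f2": "W", "m2": "W"})
        assert st.assortativity(net, "rearing_pop") == pytest.approx(1.0)

    def test_perfectly_disassortative(self):
        net = _net([("f1", "m1", 1.0), ("f2", "m2", 1.0)],
                   {"f1": "D", "m1": "W", "f2": "W", "m2": "D"})
        assert st.assortativity(net, "rearing_pop") == pytest.approx(-1.0)

    def test_independent_mixing_is_zero(self):
        net = _net(
            [("a", "c", 1.0), ("a", "d", 1.0), ("b", "c", 1.0), ("b", "d", 1.0)],
            {"a": "D", "b": "W", "c": "D", "d": "W"},
        )
        assert st.assortativity(net, "rearing_pop") == pytest.approx(0.0, abs=1e-12)

    def test_single_level_rejected(self):
        net = _net([("a", "b", 1.0)], {"a": "D", "b": "D"})
        with pytest.raises(ValueError, match="single level"):
            st.assortativity(net, "rearing_pop")

    def test_oracle_equivalence_random_networks(self):
        # weight-expanded Pearson correlation of endpoint indicators
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(3, 7))
            nodes = [f"n{i}" for i in range(n)]
            cats = {x: ("D" if rng.random() < 0.5 else "W") for x in nodes}
            if len(set(cats.values())) < 2:
                cats[nodes[0]] = "D"
                cats[nodes[1]] = "W"
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.7:
                        edges.append((nodes[i], nodes[j], float(rng.integers(1, 5))))
            if not edges:
                continue
            net = _net(edges, cats)
            try:
                r = st.assortativity(net, "rearing_pop")
            except ValueError:
                continue
            # oracle: expand each integer-weight edge into w copies, both
            # orientations, then plain Pearson of 0/1 endpoint indicators
            xs, ys = [], []
            for u, v, w in edges:
                for _ in range(int(w)):
                    xs += [cats[u] == "D", cats[v] == "D"]
                    ys += [cats[v] == "D", cats[u] == "D"]
            xs_a, ys_a = np.array(xs, float), np.array(ys, float)
            if xs_a.std() == 0:  # all stubs one category: oracle undefined
                continue
            expected = np.corrcoef(xs_a, ys_a)[0, 1]
            assert r == pytest.approx(expected, abs=1e-12)


class TestPermutationTest:
    def test_perfect_assortativity_p_zero(self):
        net = _net([("f1", "m1", 1.0), ("f2", "m2", 1.0)],
                   {"f1": "D", "m1": "D", "f2": "W", "m2": "W"})
        res = st.permutation_test(net, "rearing_pop", n_perm=500, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm == 0.0
        assert res.p_conservative > 0.0

    def test_determinism(self):
        net = _net(
            [("a", "c", 1.0), ("a", "d", 2.0), ("b", "c", 3.0), ("b", "d", 1.0)],
            {"a": "D", "b": "W", "c": "D", "d": "W"},
        )
        r1 = st.permutation_test(net, "rearing_pop", n_perm=500, seed=7)
        r2 = st.permutation_test(net, "rearing_pop", n_perm=500, seed=7)
        assert r1.p_perm == r2.p_perm

    def test_relabel_invariance(self):
        edges = [("a", "c", 1.0), ("a", "d", 2.0), ("b", "c", 3.0), ("b", "d", 1.0),
                 ("a", "b", 2.0)]
        cats = {"a": "D", "b": "W", "c": "D", "d": "W"}
        swapped = {k: ("W" if v == "D" else "D") for k, v in cats.items()}
        p1 = st.permutation_test(_net(edges, cats), "rearing_pop", 400, seed=5).p_perm
        p2 = st.permutation_test(_net(edges, swapped), "rearing_pop", 400, seed=5).p_perm
        assert p1 == p2

    def test_small_nperm_warns(self):
        net = _net([("f1", "m1", 1.0), ("f2", "m2", 1.0)],
                   {"f1": "D", "m1": "D", "f2": "W", "m2": "W"})
        with pytest.warns(UserWarning, match="n_perm"):
            st.permutation_test(net, "rearing_pop", n_perm=50, seed=0)

    def test_null_calibration_small(self):
        # reduced version of the acceptance calibration: 120 exchangeable
        # datasets x 300 permutations, rejection rate ~ alpha
        rng = np.random.default_rng(123)
        n_nodes, alpha = 12, 0.05
        rejections = 0
        n_data = 120
        nodes = [f"n{i}" for i in range(n_nodes)]
        for _ in range(n_data):
            cats = {x: ("D" if i < n_nodes // 2 else "W") for i, x in enumerate(nodes)}
            edges = [
                (nodes[i], nodes[j], float(rng.exponential(1.0) + 0.1))
                for i in range(n_nodes) for j in range(i + 1, n_nodes)
            ]
            net = _net(edges, cats)
            res = st.permutation_test(net, "rearing_pop", n_perm=300,
                                      seed=int(rng.integers(2**31)))
            rejections += res.p_perm < alpha
        rate = rejections / n_data
        se = np.sqrt(alpha * (1 - alpha) / n_data)
        assert abs(rate - alpha) < 3 * se


@pytest.fixture(scope="module")
def preference_run():
    """Pair-targeted attraction over a cross-fostered (orthogonal) design."""
    birds = []
    for pop in ("D1", "W1"):
        for i in range(4):
            for sex in ("M", "F"):
                # genetic pop orthogonal to rearing: half cross-fostered
                genetic = "D1" if (i % 2 == 0) == (pop == "D1") else "W1"
                birds.append(BirdRecord(
                    bird_id=f"{pop}{sex}{i}", sex=sex, genetic_pop=genetic,
                    rearing_pop=pop,
                    lineage_code=genetic[0] + pop[0],
                    rearing_aviary=f"{pop}-A1", generation=2, body_size=14.0,
                ))
    # true pairs: same-rearing but opposite-genetic monogamous matching
    pairs = [(f"{pop}F{i}", f"{pop}M{(i + 1) % 4}")
             for pop in ("D1", "W1") for i in range(4)]
    design = ExperimentDesign(groups=[("g", [b.bird_id for b in birds])],
                              days=10, day_length=0.15)
    model = PreferenceModel(a_cult=0.3, ramp_days=10)
    fixes = simulate_tracking(birds, model, pairs, design, seed=3, pair_attraction=10.0)
    daily = st.dyad_daily_distances(fixes, birds)
    return birds, daily


class TestDailySeries:
    def test_rearing_series_rises_between_sex(self, preference_run):
        birds, daily = preference_run
        series, trend = st.daily_assortment_series(daily, birds, "rearing_pop",
                                                   "between_sex")
        assert trend["slope"] > 0
        assert series["r"].iloc[-1] > series["r"].iloc[0]

    def test_same_sex_series_flat(self, preference_run):
        birds, daily = preference_run
        _, trend = st.daily_assortment_series(daily, birds, "rearing_pop", "same_sex")
        # attraction couples opposite-sex dyads only
        assert abs(trend["slope"]) < 3 * trend["slope_se"] + 0.003

    def test_genetic_series_not_positive(self, preference_run):
        birds, daily = preference_run
        _, trend = st.daily_assortment_series(daily, birds, "genetic_pop",
                                              "between_sex")
        assert trend["slope"] <= 3 * trend["slope_se"]

    def test_null_series_centred_on_zero(self):
        birds = [_bird(f"d{i}", "F" if i % 2 else "M") for i in range(4)] + [
            _bird(f"w{i}", "F" if i % 2 else "M", "W1", "WW") for i in range(4)
        ]
        design = ExperimentDesign(groups=[("g", [b.bird_id for b in birds])],
                                  days=8, day_length=0.15)
        fixes = simulate_tracking(birds, PreferenceModel(), [], design, seed=11)
        daily = st.dyad_daily_distances(fixes, birds)
        series, trend = st.daily_assortment_series(daily, birds, "rearing_pop",
                                                   "between_sex")
        se = series["r"].std(ddof=1) / np.sqrt(len(series))
        assert abs(series["r"].mean()) < 4 * se + 0.05

    def test_weight_scheme_sign_consistency(self, preference_run):
        birds, daily = preference_run
        _, t_inv = st.daily_assortment_series(daily, birds, "rearing_pop",
                                              "between_sex", weight="inverse")
        _, t_max = st.daily_assortment_series(daily, birds, "rearing_pop",
                                              "between_sex", weight="max_minus")
        assert np.sign(t_inv["slope"]) == np.sign(t_max["slope"])

    def test_single_day_rejected(self):
        birds = [_bird("f", "F"), _bird("m")]
        daily = pd.DataFrame({"bird_a": ["f"], "bird_b": ["m"], "day_index": [0],
                              "mean_distance_mm": [100.0], "ln_distance": [np.log(100)],
                              "n_simultaneous_fixes": [3], "dyad_type": ["MF"]})
        with pytest.raises(ValueError, match="2 days"):
            st.daily_assortment_series(daily, birds, "rearing_pop")


@given(w=hst.lists(hst.floats(min_value=0.1, max_value=10), min_size=4, max_size=4))
@settings(max_examples=25, deadline=None)
def test_assortativity_bounds_property(w):
    net = _net(
        [("a", "c", w[0]), ("a", "d", w[1]), ("b", "c", w[2]), ("b", "d", w[3])],
        {"a": "D", "b": "W", "c": "D", "d": "W"},
    )
    r = st.assortativity(net, "rearing_pop")
    assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
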