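"""Spatial kin structure and kin-directed building statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from weaverkin.datamodel import ChamberMap, Individual, ObservationLog
from weaverkin.kin import (
    builder_local_relatedness_contrast,
    building_location_score,
    chamber_distance_matrix,
    colony_vs_population_relatedness,
    local_relatedness,
    nearest_quartile_chambers,
    primary_chambers,
    quartile_building_test,
    relatedness_distance_slope,
)
from weaverkin.popgen import RelatednessMatrix


def line_map(n, colony="X", spacing=1.0):
    return ChamberMap(colony, {f"c{i}": (i * spacing, 0.0) for i in range(n)})


class TestChamberDistances:
    def test_pythagoras(self):
        cmap = ChamberMap("X", {"a": (0.0, 0.0), "b": (3.0, 4.0)})
        ids, d = chamber_distance_matrix(cmap)
        assert d[ids.index("a"), ids.index("b")] == pytest.approx(5.0)

    def test_self_distance_zero(self):
        ids, d = chamber_distance_matrix(line_map(4))
        assert np.allclose(np.diag(d), 0.0)

    def test_triangle_inequality(self, rng):
        pts = {f"c{i}": tuple(rng.normal(0, 5, 2)) for i in range(6)}
        ids, d = chamber_distance_matrix(ChamberMap("X", pts))
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestNearestQuartile:
    def test_line_of_five_end_focal(self):
        ids, d = chamber_distance_matrix(line_map(5))
        assert nearest_quartile_chambers(ids, d, "c0") == ["c1"]

    def test_nine_chambers_gives_two(self):
        ids, d = chamber_distance_matrix(line_map(9))
        assert nearest_quartile_chambers(ids, d, "c4") == ["c3", "c5"]

    @pytest.mark.parametrize("n", range(2, 30))
    def test_size_is_ceil_quarter(self, n, rng):
        pts = {f"c{i}": tuple(rng.normal(0, 5, 2)) for i in range(n)}
        ids, d = chamber_distance_matrix(ChamberMap("X", pts))
        q = nearest_quartile_chambers(ids, d, ids[0])
        assert len(q) == math.ceil(0.25 * (n - 1))
        assert ids[0] not in q

    def test_matches_brute_sort(self, rng):
        pts = {f"c{i}": tuple(rng.normal(0, 5, 2)) for i in range(12)}
        ids, d = chamber_distance_matrix(ChamberMap("X", pts))
        focal = ids[3]
        f = ids.index(focal)
        expected = sorted(
            (c for c in ids if c != focal),
            key=lambda c: (d[f, ids.index(c)], c),
        )[: math.ceil(0.25 * 11)]
        assert nearest_quartile_chambers(ids, d, focal) == expected

    def test_tie_break_by_chamber_id(self):
        cmap = ChamberMap("X", {"m": (0.0, 0.0), "b": (1.0, 0.0), "a": (-1.0, 0.0),
                                "z": (0.0, 1.0), "y": (0.0, -1.0)})
        ids, d = chamber_distance_matrix(cmap)
        assert nearest_quartile_chambers(ids, d, "m") == ["a"]


class TestLocalRelatedness:
    def rmat(self):
        vals = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.2], [0.1, 0.2, 1.0]])
        return RelatednessMatrix(["f", "n1", "n2"], vals)

    def test_single_neighbour(self):
        r = local_relatedness("f", self.rmat(), {"q1": ["n1"]}, ["q1"])
        assert r == 0.5

    def test_empty_neighbourhood_missing(self):
        assert np.isnan(local_relatedness("f", self.rmat(), {}, ["q1"]))

    def test_focal_excluded_and_deduplicated(self):
        occ = {"q1": ["f", "n1"], "q2": ["n1", "n2"]}
        r = local_relatedness("f", self.rmat(), occ, ["q1", "q2"])
        assert r == pytest.approx((0.5 + 0.1) / 2)

    def test_sex_filter(self):
        inds = {"f": Individual("f", "male", "X"), "n1": Individual("n1", "male", "X"),
                "n2": Individual("n2", "female", "X")}
        occ = {"q1": ["n1", "n2"]}
        r = local_relatedness("f", self.rmat(), occ, ["q1"], sex_filter="male",
                              individuals=inds)
        assert r == 0.5


class TestRelatednessDistanceSlope:
    def planted(self, rng, n=16, decay=-0.08):
        cmap = line_map(n)
        ids, d = chamber_distance_matrix(cmap)
        birds = [f"b{i}" for i in range(n)]
        assignment = {b: f"c{i}" for i, b in enumerate(birds)}
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    vals[i, j] = decay * d[i, j] + rng.normal(0, 0.02)
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        return RelatednessMatrix(birds, vals), ids, d, assignment

    def test_planted_decay_detected(self, rng):
        rmat, ids, d, assignment = self.planted(rng)
        res = relatedness_distance_slope(rmat, ids, d, assignment, n_perm=499, seed=0)
        assert res.observed < 0
        assert res.p_value <= 0.01

    def test_underdetermined_errors(self, rng):
        rmat, ids, d, assignment = self.planted(rng, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            relatedness_distance_slope(rmat, ids, d, assignment, n_perm=9, seed=0)

    def test_single_chamber_errors(self, rng):
        rmat, ids, d, _ = self.planted(rng, n=5)
        assignment = {b: "c0" for b in rmat.ids}
        with pytest.raises(ValueError, match="one chamber"):
            relatedness_distance_slope(rmat, ids, d, assignment, n_perm=9, seed=0)


class TestBuildingLocationScore:
    def test_all_building_in_own_area(self):
        score = building_location_score(
            {"c0": 4}, {"c0": 3}, {"c0": ["c1"]},
        )
        assert score == 1.0

    def test_all_building_far_away(self):
        score = building_location_score(
            {"c9": 4}, {"c0": 3}, {"c0": ["c1"]},
        )
        assert score == 0.0

    def test_visit_weighted_mean(self):
        # chambers u1 (3 visits, all events in area) and u2 (1 visit, none)
        score = building_location_score(
            {"c1": 2}, {"u1": 3, "u2": 1}, {"u1": ["c1"], "u2": ["c9"]},
        )
        assert score == pytest.approx(0.75)

    def test_visit_rescaling_invariance(self):
        a = building_location_score({"c1": 2}, {"u1": 3, "u2": 1},
                                    {"u1": ["c1"], "u2": ["c9"]})
        b = building_location_score({"c1": 2}, {"u1": 30, "u2": 10},
                                    {"u1": ["c1"], "u2": ["c9"]})
        assert a == b

    def test_no_visits_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="unweighted"):
            score = building_location_score({"c1": 1}, {}, {"u1": ["c1"], "u2": ["c9"]})
        assert score == pytest.approx(0.5)

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(20):
            chambers = [f"c{i}" for i in range(8)]
            locs = {c: int(k) for c, k in
                    zip(chambers, rng.integers(0, 4, 8)) if k > 0}
            if not locs:
                continue
            used = list(rng.choice(chambers, 3, replace=False))
            visits = {u: int(rng.integers(1, 5)) for u in used}
            qsets = {u: list(rng.choice(chambers, 2, replace=False)) for u in used}
            s = building_location_score(locs, visits, qsets)
            assert 0.0 <= s <= 1.0


class TestQuartileBuildingTest:
    def test_all_scores_at_chance_errors(self):
        with pytest.raises(ValueError):
            quartile_building_test([0.25, 0.25, 0.25])

    def test_strongly_self_directed(self, rng):
        scores = np.clip(rng.normal(0.6, 0.15, 160), 0, 1)
        v, p = quartile_building_test(scores)
        assert p < 0.001


class TestBuilderContrast:
    def test_planted_effect_detected_male_only(self, rng):
        n = 120
        sexes = np.array(["male", "female"] * (n // 2))
        colonies = np.repeat([f"C{i}" for i in range(4)], n // 4)
        local_r = rng.normal(0.0, 0.05, n)
        builders = np.zeros(n, dtype=int)
        male_idx = np.flatnonzero(sexes == "male")
        # male builders drawn from the high-local-r half
        top = male_idx[np.argsort(local_r[male_idx])[-20:]]
        builders[top] = 1
        female_idx = np.flatnonzero(sexes == "female")
        builders[rng.choice(female_idx, 10, replace=False)] = 1
        res = builder_local_relatedness_contrast(
            local_r, builders, sexes, colonies, n_perm=999, seed=0
        )
        assert res["male"].p_value < 0.01
        assert res["male"].observed > 0
        assert res["female"].p_value > 0.01

    def test_single_class_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="one builder class"):
            res = builder_local_relatedness_contrast(
                [0.1, 0.2], [1, 1], ["male", "male"], ["C1", "C1"],
                n_perm=9, seed=0,
            )
        assert res == {}


class TestColonyVsPopulation:
    def make_population(self, rng, excess=0.0, n_col=6, per=10):
        ids, sexes, colonies = [], [], []
        for c in range(n_col):
            for i in range(per):
                ids.append(f"C{c}b{i}")
                sexes.append("male" if i % 2 == 0 else "female")
                colonies.append(f"C{c}")
        n = len(ids)
        vals = rng.normal(0.0, 0.1, (n, n))
        vals = (vals + vals.T) / 2
        col = np.array(colonies)
        same = col[:, None] == col[None, :]
        vals[same] += excess
        np.fill_diagonal(vals, 1.0)
        inds = [Individual(b, s, c) for b, s, c in zip(ids, sexes, colonies)]
        return RelatednessMatrix(ids, vals), inds

    def test_single_colony_errors(self, rng):
        rmat, inds = self.make_population(rng, n_col=1)
        with pytest.raises(ValueError, match="2 colonies"):
            colony_vs_population_relatedness(rmat, inds)

    def test_planted_excess_detected(self, rng):
        rmat, inds = self.make_population(rng, excess=0.05)
        out = colony_vs_population_relatedness(rmat, inds)
        assert out["all"]["colony_mean"] > out["all"]["population_mean"]
        assert out["all"]["p_value"] < 0.01
        assert set(out) == {"all", "male", "female"}

    def test_reports_dyad_summaries(self, rng):
        rmat, inds = self.make_population(rng)
        out = colony_vs_population_relatedness(rmat, inds)
        for cls in out:
            assert out[cls]["n_dyads"] > 0
            assert out[cls]["n_colonies"] == 6
            assert np.isfinite(out[cls]["V"])


def test_primary_chambers_most_visited_tie_by_id():
    entries = pd.DataFrame(
        [("a", "X", "c2", "s1", "roost"),
         ("a", "X", "c2", "s1", "roost"),
         ("a", "X", "c1", "s1", "roost"),
         ("b", "X", "c3", "s1", "roost"),
         ("b", "X", "c1", "s1", "roost")],
        columns=ObservationLog.ENTRY_COLS,
    )
    obs = ObservationLog(entries, pd.DataFrame(columns=ObservationLog.BUILD_COLS))
    assert primary_chambers(obs, "X") == {"a": "c2", "b": "c1"}
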