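import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mesoimmunity import (
    AssayRecord,
    FormatError,
    PlateObservation,
    aggregate_replicates,
    load_scoring_rubric,
    lysogen_crs_delta,
    profile_correlation,
    reciprocal_asymmetry,
    regress_phenotype_vs_distance,
    score_observation,
    summarize_assay_counts,
)
from mesoimmunity.distances import DistanceTable


class TestScoreObservation:
    @pytest.mark.parametrize(
        "obs,expected",
        [
            (PlateObservation(False, spot_titers_with_lysis=0), 0),
            (PlateObservation(False, spot_titers_with_lysis=2), 1),
            (PlateObservation(True, eop=1e-5), 2),
            (PlateObservation(False, spot_titers_with_lysis=3), 2),
            (PlateObservation(True, eop=1e-2), 3),
            (PlateObservation(False, spot_titers_with_lysis=5), 3),
            (PlateObservation(True, eop=1.0, turbidity_vs_control="increased"), 4),
            (PlateObservation(True, eop=1.0, plaque_size_vs_control="reduced"), 4),
            (PlateObservation(True, eop=1.0), 5),
            (PlateObservation(True, eop=1.0, turbidity_vs_control="reduced"), 6),
            (PlateObservation(True, eop=1.0, plaque_size_vs_control="increased"), 6),
        ],
    )
    def test_rubric_mapping(self, obs, expected):
        assert score_observation(obs) == expected

    def test_eop_bin_edges(self):
        assert score_observation(PlateObservation(True, eop=9e-4)) == 2
        assert score_observation(PlateObservation(True, eop=1e-3)) == 3
        assert score_observation(PlateObservation(True, eop=0.3)) == 3
        assert score_observation(PlateObservation(True, eop=0.6)) == 5

    def test_plaques_without_eop_rejected(self):
        with pytest.raises(FormatError, match="efficiency of plating"):
            PlateObservation(plaques_present=True)

    def test_rubric_table_has_seven_rows(self):
        rubric = load_scoring_rubric()
        assert [r["score"] for r in rubric] == list(range(7))


def _records():
    return [
        AssayRecord("A", "A", "lysogen", [0, 0]),
        AssayRecord("A", "B", "lysogen", [4]),
        AssayRecord("B", "A", "lysogen", [0, 1]),
        AssayRecord("B", "B", "lysogen", [0]),
        AssayRecord("C", "A", "lysogen", [5, 5, 5]),
        AssayRecord("C", "B", "lysogen", [3, 5]),
        AssayRecord("A", "A_CRS", "CRS", [2, 2]),
        AssayRecord("C", "A_CRS", "CRS", [5]),
    ]


class TestAggregateReplicates:
    def test_single_replicate(self):
        m = aggregate_replicates([AssayRecord("a", "b", "lysogen", [4])])
        assert m.score("a", "b") == 4.0
        assert m.max.at["a", "b"] - m.min.at["a", "b"] == 0

    def test_mean_and_range(self):
        m = aggregate_replicates([AssayRecord("a", "b", "lysogen", [0, 1])])
        assert m.score("a", "b") == 0.5
        assert m.max.at["a", "b"] - m.min.at["a", "b"] == 1

    def test_matches_groupby_oracle(self, rng):
        records = []
        for _ in range(10):
            c = f"P{rng.integers(3)}"
            d = f"P{rng.integers(3)}"
            scores = list(rng.integers(0, 7, size=rng.integers(1, 4)))
            records.append(AssayRecord(c, d, "lysogen", [int(s) for s in scores]))
        m = aggregate_replicates(records)
        df = pd.DataFrame(
            [
                {"c": r.challenger_id, "d": r.defender_id, "s": s}
                for r in records
                for s in r.replicate_scores
            ]
        )
        oracle = df.groupby(["c", "d"])["s"].agg(["mean", "size", "min", "max"])
        for (c, d), row in oracle.iterrows():
            assert m.score(c, d) == pytest.approx(row["mean"])
            assert m.n.at[c, d] == row["size"]
            assert m.min.at[c, d] == row["min"]
            assert m.max.at[c, d] == row["max"]

    def test_mean_is_replicate_order_invariant(self):
        a = aggregate_replicates([AssayRecord("a", "b", "lysogen", [1, 3, 5])])
        b = aggregate_replicates([AssayRecord("a", "b", "lysogen", [5, 1, 3])])
        assert a.score("a", "b") == b.score("a", "b")

    def test_conflicting_defender_kind_rejected(self):
        with pytest.raises(FormatError, match="both"):
            aggregate_replicates(
                [
                    AssayRecord("a", "x", "lysogen", [1]),
                    AssayRecord("b", "x", "CRS", [1]),
                ]
            )


class TestReciprocalAsymmetry:
    def test_symmetric_matrix_all_deltas_zero(self):
        records = [
            AssayRecord(c, d, "lysogen", [2])
            for c in "AB"
            for d in "AB"
        ]
        pairs = reciprocal_asymmetry(aggregate_replicates(records))
        assert all(p.delta == 0 for p in pairs)

    def test_full_asymmetry(self):
        # A superinfects B's lysogen (5) while B is fully blocked on A's (0)
        records = [
            AssayRecord("A", "B", "lysogen", [5]),
            AssayRecord("B", "A", "lysogen", [0]),
            AssayRecord("A", "A", "lysogen", [0]),
            AssayRecord("B", "B", "lysogen", [0]),
        ]
        (pair,) = reciprocal_asymmetry(aggregate_replicates(records))
        assert pair.delta == 5.0

    def test_one_directional_pairs_excluded(self):
        records = [
            AssayRecord("A", "B", "lysogen", [5]),
            AssayRecord("B", "A", "lysogen", [1]),
            AssayRecord("A", "C", "lysogen", [4]),
            AssayRecord("C", "A", "lysogen", [2]),
            AssayRecord("B", "C", "lysogen", [3]),  # C vs B never tested
        ]
        with pytest.warns(UserWarning, match="reciprocal"):
            pairs = reciprocal_asymmetry(aggregate_replicates(records))
        assert len(pairs) == 2

    def test_delta_symmetric_and_bounded(self, small_matrix):
        for p in reciprocal_asymmetry(small_matrix):
            assert p.delta == abs(p.score_ba - p.score_ab)
            assert p.delta <= max(p.score_ab, p.score_ba)
            assert 0 <= p.delta <= 6


class TestProfileCorrelation:
    def test_identical_rows_perfectly_correlated(self):
        records = []
        for d, s in zip("WXYZ", [0, 2, 4, 5]):
            records.append(AssayRecord("A", d, "lysogen", [s]))
            records.append(AssayRecord("B", d, "lysogen", [s]))
        m = aggregate_replicates(records)
        assert profile_correlation(m, "A", "B").r == pytest.approx(1.0)

    def test_reversed_rows_anticorrelated(self):
        records = []
        for d, sa, sb in zip("WXYZ", [0, 1, 2, 3], [3, 2, 1, 0]):
            records.append(AssayRecord("A", d, "lysogen", [sa]))
            records.append(AssayRecord("B", d, "lysogen", [sb]))
        m = aggregate_replicates(records)
        assert profile_correlation(m, "A", "B").r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        defenders = [f"D{i}" for i in range(8)]
        sa = rng.integers(0, 7, 8)
        sb = rng.integers(0, 7, 8)
        records = []
        for d, x, y in zip(defenders, sa, sb):
            records.append(AssayRecord("A", d, "lysogen", [int(x)]))
            records.append(AssayRecord("B", d, "lysogen", [int(y)]))
        m = aggregate_replicates(records)
        x, y = sa.astype(float), sb.astype(float)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert profile_correlation(m, "A", "B").r == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_profile_flagged(self):
        records = []
        for d in "WXY":
            records.append(AssayRecord("A", d, "lysogen", [3]))
            records.append(AssayRecord("B", d, "lysogen", [1 + "WXY".index(d)]))
        m = aggregate_replicates(records)
        with pytest.warns(UserWarning, match="constant"):
            assert profile_correlation(m, "A", "B").r is None

    def test_defending_axis_uses_columns(self, small_matrix):
        ids = small_matrix.defenders_of_kind("lysogen")[:2]
        c = profile_correlation(small_matrix, ids[0], ids[1], axis="defending")
        assert c.axis == "defending"
        assert c.r is None or -1.0 <= c.r <= 1.0


def _distance_table(ids, values):
    n = len(ids)
    M = np.zeros((n, n))
    for (a, b), v in values.items():
        i, j = ids.index(a), ids.index(b)
        M[i, j] = M[j, i] = v
    return DistanceTable(ids=list(ids), matrices={"D": M})


class TestRegression:
    def test_exactly_linear_points_r2_one(self):
        ids = ["A", "B", "C", "D"]
        dists = {("A", b): d for b, d in zip("BCD", [0.1, 0.2, 0.3])}
        table = _distance_table(ids, dists)
        records = [AssayRecord("A", "A", "lysogen", [0])]
        for b, s in zip("BCD", [1, 2, 3]):
            records.append(AssayRecord("A", b, "lysogen", [s]))
        m = aggregate_replicates(records)
        fit = regress_phenotype_vs_distance(m, table, response="I", predictor="D")
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_least_squares(self, rng):
        ids = [f"P{i}" for i in range(6)]
        dvals = {}
        records = []
        for i, b in enumerate(ids):
            d = float(rng.uniform(0, 0.5)) if b != "P0" else 0.0
            if b != "P0":
                dvals[("P0", b)] = d
            score = int(rng.integers(0, 7))
            records.append(AssayRecord("P0", b, "lysogen", [score]))
        table = _distance_table(ids, dvals)
        m = aggregate_replicates(records)
        fit = regress_phenotype_vs_distance(m, table, response="I", predictor="D")
        xs = np.array([0.0 if b == "P0" else dvals[("P0", b)] for b in ids])
        ys = np.array([m.score("P0", b) for b in ids])
        X = np.vstack([xs, np.ones_like(xs)]).T
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_points_rejected(self):
        table = _distance_table(["A", "B"], {("A", "B"): 0.2})
        m = aggregate_replicates([AssayRecord("A", "B", "lysogen", [3])])
        with pytest.raises(ValueError, match=">= 3"):
            regress_phenotype_vs_distance(m, table, predictor="D")

    def test_infection_score_rises_with_motif_distance(
        self, small_matrix, small_distances
    ):
        # homotypic pairs are immune (low score), diverged pairs infect:
        # the infection score increases with stoperator-motif distance
        fit = regress_phenotype_vs_distance(
            small_matrix, small_distances, response="I", predictor="D_Stop_motif"
        )
        assert fit.slope > 0
        assert fit.n >= 3

    def test_clade_scope_filter_restricts_n(self, small_matrix, small_distances):
        full = regress_phenotype_vs_distance(
            small_matrix, small_distances, predictor="D_Stop_motif"
        )
        scoped = regress_phenotype_vs_distance(
            small_matrix,
            small_distances,
            predictor="D_Stop_motif",
            clade=small_distances.ids[:4],
        )
        assert scoped.n < full.n


class TestLysogenCrsDelta:
    def test_equal_scores_zero_delta(self):
        records = [
            AssayRecord("A", "A", "lysogen", [2]),
            AssayRecord("A", "A_CRS", "CRS", [2]),
        ]
        df = lysogen_crs_delta(aggregate_replicates(records))
        assert list(df["delta"]) == [0.0]

    def test_weaker_homotypic_crs_immunity_positive_delta(self):
        # repressor-only strain defends less tightly against its own phage
        records = [
            AssayRecord("A", "A", "lysogen", [0]),
            AssayRecord("A", "A_CRS", "CRS", [2]),
        ]
        df = lysogen_crs_delta(aggregate_replicates(records))
        assert list(df["delta"]) == [2.0]

    def test_join_matches_pairing_oracle(self, small_matrix):
        df = lysogen_crs_delta(small_matrix)
        assert not df.empty
        for _, row in df.iterrows():
            lys = small_matrix.score(row["challenger"], row["system"])
            crs = small_matrix.score(row["challenger"], row["system"] + "_CRS")
            assert row["delta"] == pytest.approx(crs - lys)

    def test_unpaired_system_skipped(self):
        records = [
            AssayRecord("A", "A", "lysogen", [2]),
            AssayRecord("A", "B_CRS", "CRS", [3]),
        ]
        with pytest.warns(UserWarning, match="lacks"):
            df = lysogen_crs_delta(aggregate_replicates(records))
        assert df.empty


class TestAssayCounts:
    def test_empty_input_all_zero(self):
        out = summarize_assay_counts([])
        assert out["total_assays"] == 0
        assert out["unique_comparisons"] == 0
        assert out["reciprocal_pairs"] == 0

    def test_hand_enumerated_fixture(self):
        # 12 records; reciprocal pairs {A,B} and {A,C}; one complete
        # lysogen-CRS pair (system A) challenged by A and B
        records = [
            AssayRecord("A", "A", "lysogen", [0, 0]),
            AssayRecord("A", "B", "lysogen", [3, 4]),
            AssayRecord("B", "A", "lysogen", [1]),
            AssayRecord("A", "C", "lysogen", [5]),
            AssayRecord("C", "A", "lysogen", [5, 0]),  # range 5: not "tight"
            AssayRecord("B", "C", "lysogen", [2]),
            AssayRecord("A", "A_CRS", "CRS", [2, 2]),
            AssayRecord("B", "A_CRS", "CRS", [4]),
            AssayRecord("B", "A", "lysogen", [2]),  # extra replicate, same cell
            AssayRecord("C", "C", "lysogen", [0]),
            AssayRecord("D", "A", "lysogen", [5]),
            AssayRecord("B", "B", "lysogen", [0]),
        ]
        out = summarize_assay_counts(records)
        assert out["total_assays"] == 16
        assert out["unique_comparisons"] == 11
        assert out["reciprocal_pairs"] == 2  # {A,B}, {A,C}
        # system A complete; A and B challenged both defenders -> 4
        assert out["lysogen_crs_paired_comparisons"] == 4
        # multi-replicate cells: AA, AB, BA(1+1), CA, A_CRS -> 5 of 11
        assert out["pct_multireplicate"] == pytest.approx(100 * 5 / 11)
        # of those, range < 2 fails only for CA (range 5)
        assert out["pct_multireplicate_range_lt2"] == pytest.approx(100 * 4 / 5)

    def test_simulated_dataset_counts_consistent(self, small_distances):
        from mesoimmunity import PhenotypeSimConfig, simulate_immunity

        cfg = PhenotypeSimConfig(replicates=3)
        records = simulate_immunity(small_distances, cfg, seed=5)
        out = summarize_assay_counts(records)
        n = len(small_distances.ids)
        assert out["unique_comparisons"] == n * n
        assert out["total_assays"] == n * n * 3
        assert out["reciprocal_pairs"] == n * (n - 1) // 2
        assert out["pct_multireplicate"] == 100.0
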