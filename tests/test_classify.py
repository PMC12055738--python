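"""Quartile assignment and zonal favourability scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zonalspi._rounding import round_half_away
from zonalspi.classify import (
    QuantileClassifier,
    assign_quantiles,
    favourability_all,
    favourability_score,
    quantile_occupancy,
)
from zonalspi.core import RegionRecord, ValidationError
from zonalspi.datasets import ZONAL_QUANTILE_COUNTS, counts_as_assignments


def wide(scores: dict[str, float], pillar: str = "P") -> pd.DataFrame:
    return pd.DataFrame({pillar: pd.Series(scores, dtype=float)})


def brute_force_quartiles(values: list[float]) -> dict[float, str]:
    """Independent oracle: bin against numpy percentiles with <=-lower ties."""
    c25, c50, c75 = np.percentile(values, [25, 50, 75])
    out = {}
    for v in values:
        if v <= c25:
            out[v] = "Q1"
        elif v <= c50:
            out[v] = "Q2"
        elif v <= c75:
            out[v] = "Q3"
        else:
            out[v] = "Q4"
    return out


class TestAssignQuantiles:
    def test_eight_equally_spaced_scores_two_per_quartile(self):
        scores = wide({f"u_R{i}": float(i) for i in range(1, 9)})
        out = assign_quantiles(scores).set_index("region_id")["quantile"]
        assert out["u_R1"] == out["u_R2"] == "Q1"
        assert out["u_R3"] == out["u_R4"] == "Q2"
        assert out["u_R5"] == out["u_R6"] == "Q3"
        assert out["u_R7"] == out["u_R8"] == "Q4"

    def test_all_identical_scores_all_Q1(self):
        out = assign_quantiles(wide({f"u_R{i}": 42.0 for i in range(6)}))
        assert set(out["quantile"]) == {"Q1"}

    def test_supplied_cutpoints_half_open_boundary(self):
        scores = wide({"u_A": 70.0, "u_B": 70.01, "u_C": 30.0, "u_D": 50.0})
        out = assign_quantiles(scores, cutpoints=(30, 50, 70)).set_index("region_id")
        assert out.loc["u_A", "quantile"] == "Q3"
        assert out.loc["u_B", "quantile"] == "Q4"
        assert out.loc["u_C", "quantile"] == "Q1"
        assert out.loc["u_D", "quantile"] == "Q2"

    def test_non_ascending_cutpoints_rejected(self):
        with pytest.raises(ValidationError, match="ascending"):
            assign_quantiles(wide({"u_A": 1.0, "u_B": 2.0, "u_C": 3.0, "u_D": 4.0}),
                             cutpoints=(50, 30, 70))

    def test_fewer_than_four_defined_scores_rejected(self):
        with pytest.raises(ValidationError, match=">= 4"):
            assign_quantiles(wide({"u_A": 1.0, "u_B": 2.0, "u_C": 3.0}))

    def test_undefined_scores_receive_no_assignment(self):
        scores = wide({f"u_R{i}": float(i) for i in range(5)})
        scores.loc["u_R0", "P"] = np.nan
        out = assign_quantiles(scores)
        assert "u_R0" not in set(out["region_id"])
        assert len(out) == 4

    def test_labels_fixed_mapping(self):
        out = assign_quantiles(wide({f"u_R{i}": float(i) for i in range(1, 9)}))
        mapping = dict(zip(out["quantile"], out["label"]))
        assert mapping == {"Q1": "poor", "Q2": "fair", "Q3": "good", "Q4": "excellent"}

    @given(
        st.lists(
            st.floats(0, 100, allow_nan=False, width=16), min_size=4, max_size=10,
            unique=True,
        )
    )
    def test_matches_brute_force_oracle_under_any_permutation(self, values):
        oracle = brute_force_quartiles(values)
        for perm in itertools.islice(itertools.permutations(values), 24):
            scores = wide({f"u_R{i:02d}": v for i, v in enumerate(perm)})
            out = assign_quantiles(scores).set_index("region_id")["quantile"]
            for i, v in enumerate(perm):
                assert out[f"u_R{i:02d}"] == oracle[v]

    @given(
        st.lists(st.floats(0, 100, allow_nan=False, width=16), min_size=4, max_size=40)
    )
    def test_partition_counts_sum_to_defined_scores(self, values):
        out = assign_quantiles(wide({f"u_R{i:02d}": v for i, v in enumerate(values)}))
        assert len(out) == len(values)
        assert set(out["quantile"]) <= {"Q1", "Q2", "Q3", "Q4"}

    def test_raising_a_score_weakly_increases_quartile(self):
        base = {f"u_R{i}": float(10 * i) for i in range(8)}
        out0 = assign_quantiles(wide(base)).set_index("region_id")["quantile"]
        bumped = dict(base, u_R3=base["u_R3"] + 25)
        out1 = assign_quantiles(wide(bumped)).set_index("region_id")["quantile"]
        assert out1["u_R3"] >= out0["u_R3"]


def _registry(sizes: dict[str, int]) -> list[RegionRecord]:
    recs = []
    for zone, n in sizes.items():
        for k in range(n):
            recs.append(
                RegionRecord(f"u_{zone}{k:02d}", f"{zone}{k:02d}", zone, "urban")
            )
    return recs


class TestFavourability:
    def test_published_counts_reproduce_percentages(self):
        """The published zonal Q3+Q4 counts give the published percentages,
        including the half-up cases 31.25->31.3, 56.25->56.3, 93.75->93.8."""
        assignments, registry = counts_as_assignments()
        expected = {
            ("C", "MHU"): 66.7, ("C", "WE"): 16.7, ("C", "DC"): 33.3,
            ("E", "MHU"): 50.0, ("E", "WE"): 37.5, ("E", "DC"): 50.0,
            ("N", "MHU"): 88.2, ("N", "WE"): 76.5, ("N", "DC"): 58.8,
            ("NE", "MHU"): 31.3, ("NE", "WE"): 75.0, ("NE", "DC"): 56.3,
            ("S", "MHU"): 100.0, ("S", "WE"): 93.8, ("S", "DC"): 100.0,
            ("W", "MHU"): 100.0, ("W", "WE"): 50.0, ("W", "DC"): 62.5,
        }
        for (zone, pillar), want in expected.items():
            row = favourability_score(assignments, registry, pillar, zone)
            assert row["score"] == want, (zone, pillar)

    def test_zero_favourable_gives_zero(self):
        registry = _registry({"C": 4})
        assignments = pd.DataFrame(
            {"region_id": [r.region_id for r in registry],
             "pillar_id": "MHU", "quantile": "Q1"}
        )
        assert favourability_score(assignments, registry, "MHU", "C")["score"] == 0.0

    def test_empty_zone_rejected(self):
        registry = _registry({"C": 2})
        assignments = pd.DataFrame(
            {"region_id": ["u_C00"], "pillar_id": ["MHU"], "quantile": ["Q3"]}
        )
        with pytest.raises(ValidationError, match="'S'"):
            favourability_score(assignments, registry, "MHU", "S")

    def test_unassigned_regions_count_in_denominator_only(self):
        registry = _registry({"C": 4})
        # one region has an undefined score, hence no assignment row
        assignments = pd.DataFrame(
            {"region_id": ["u_C00", "u_C01", "u_C02"],
             "pillar_id": "MHU", "quantile": ["Q4", "Q3", "Q1"]}
        )
        row = favourability_score(assignments, registry, "MHU", "C")
        assert row["n_total"] == 4 and row["n_q34"] == 2 and row["score"] == 50.0

    def test_favourability_all_row_count(self):
        assignments, registry = counts_as_assignments()
        fav = favourability_all(assignments, registry, ["MHU", "WE", "DC"])
        assert len(fav) == 18
        assert fav["score"].between(0, 100).all()

    def test_one_zone_registry(self):
        registry = _registry({"W": 3})
        assignments = pd.DataFrame(
            {"region_id": [r.region_id for r in registry],
             "pillar_id": "MHU", "quantile": ["Q4", "Q3", "Q2"]}
        )
        fav = favourability_all(assignments, registry, ["MHU"])
        assert len(fav) == 1
        assert fav["score"].iloc[0] == 66.7

    def test_score_100_iff_all_counted(self):
        registry = _registry({"N": 5})
        ids = [r.region_id for r in registry]
        all_good = pd.DataFrame(
            {"region_id": ids, "pillar_id": "MHU", "quantile": "Q3"}
        )
        assert favourability_score(all_good, registry, "MHU", "N")["score"] == 100.0
        one_bad = all_good.copy()
        one_bad.loc[0, "quantile"] = "Q2"
        assert favourability_score(one_bad, registry, "MHU", "N")["score"] < 100.0

    def test_quantile_occupancy_shares(self):
        assignments, _ = counts_as_assignments()
        occ = quantile_occupancy(assignments)
        mhu = occ[occ["pillar_id"] == "MHU"].set_index("quantile")
        # 52 of 71 regions carry Q3 in the expanded count fixture
        assert mhu.loc["Q3", "n"] == 52
        assert mhu.loc["Q3", "share"] == pytest.approx(round(100 * 52 / 71, 2), abs=0.01)
        assert occ.groupby("pillar_id")["share"].sum().round(1).eq(100.0).all()


class TestRounding:
    @pytest.mark.parametrize("tenths", range(0, 1000, 3))
    def test_half_away_on_exact_x_x5_values(self, tenths):
        """Sweep x.x5 values: every positive half rounds up (31.25 -> 31.3)."""
        s = f"{tenths / 10:.1f}5"  # e.g. "31.25"
        assert round_half_away(float(s), 1) == pytest.approx((tenths + 1) / 10)

    def test_negative_halves_round_away_from_zero(self):
        assert round_half_away(-19.415, 2) == -19.42
        assert round_half_away(-19.414999, 2) == -19.41
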