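"""Sugar-curve classification and concordance validation."""

import pandas as pd
import pytest

from oenotype.data import reference
from oenotype.exceptions import EmptyDataset
from oenotype.fermentation import (
    FermentationCurve,
    classify_strains,
    community_richness,
    concordance_table,
    favorable_groups,
    fermentation_capacity,
    read_fermentation_csv,
    read_outcomes_csv,
    region_sharing,
    residual_sugar,
    wine_type_sharing,
)


def curve(glucose_final, fructose_final, sid="S1", rep="1"):
    return FermentationCurve(sid, (0, 7, 14), (119.5, 50.0, glucose_final),
                             (120.1, 60.0, fructose_final), rep)


class TestResidualSugar:
    def test_final_day_sum(self):
        assert residual_sugar(curve(2.0, 6.0)) == pytest.approx(8.0)

    def test_initial_must_composition(self):
        must = FermentationCurve("S0", (0,), (119.5,), (120.1,))
        assert residual_sugar(must) == pytest.approx(239.6)

    def test_replicates_average(self):
        reps = [curve(4.0, 4.0, rep="1"), curve(5.0, 5.0, rep="2")]
        assert residual_sugar(reps) == pytest.approx(9.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyDataset):
            residual_sugar([])


class TestCapacity:
    @pytest.mark.parametrize("glu,fru,expected", [
        (6.0, 6.0, False),   # 12 g/L: stuck
        (4.0, 4.0, True),    # 8 g/L: dry
        (5.0, 5.0, True),    # exactly 10 g/L passes the boundary
    ])
    def test_dryness_rule(self, glu, fru, expected):
        assert fermentation_capacity(curve(glu, fru)) is expected

    def test_monotone_in_residual_sugar(self):
        residuals = [0.0, 5.0, 9.9, 10.1, 30.0]
        verdicts = [fermentation_capacity(curve(r / 2, r / 2)) for r in residuals]
        assert verdicts == sorted(verdicts, reverse=True)

    def test_classify_strains_table(self):
        curves = [curve(2, 2, "Sa"), curve(20, 20, "Sb")]
        table = classify_strains(curves)
        assert table.set_index("strain_id")["capacity"].to_dict() == {"Sa": True, "Sb": False}


class TestConcordance:
    def test_reference_table_summary(self, reference_outcomes):
        s = concordance_table(reference_outcomes)
        assert s.n_strains == 20
        assert s.capacity_count == 13
        assert s.capacity_rate == pytest.approx(0.65)
        assert s.n_sensory_wines == 13
        assert s.group_sizes == {"yellow": 5, "grey": 7, "green": 6, "pink": 2}
        assert s.validation_rate == 1.0
        assert s.favorable == {"grey", "green"}

    def test_cross_tab_row_sums_equal_group_sizes(self, reference_outcomes):
        s = concordance_table(reference_outcomes)
        for group, size in s.group_sizes.items():
            assert s.cross_tab.loc[group].sum() == size

    def test_all_capable_rate(self):
        df = pd.DataFrame({
            "strain_id": ["a", "b"], "fermentation_capacity": [True, True],
            "sensory_group": ["A", "B"], "preliminary_group": ["grey", "grey"],
            "validated": [True, True],
        })
        assert concordance_table(df).capacity_rate == 1.0

    def test_incapable_with_sensory_group_rejected(self):
        df = pd.DataFrame({
            "strain_id": ["a"], "fermentation_capacity": [False],
            "sensory_group": ["A"], "preliminary_group": ["grey"], "validated": [True],
        })
        with pytest.raises(ValueError):
            concordance_table(df)


class TestFavorable:
    def test_no_capable_strains_empty(self):
        df = pd.DataFrame({
            "strain_id": ["a"], "fermentation_capacity": [False],
            "sensory_group": ["none"], "preliminary_group": ["grey"], "validated": [True],
        })
        assert favorable_groups(df) == set()

    def test_single_all_desirable_group(self):
        df = pd.DataFrame({
            "strain_id": ["a", "b"], "fermentation_capacity": [True, True],
            "sensory_group": ["A", "B"], "preliminary_group": ["green", "green"],
            "validated": [True, True],
        })
        assert favorable_groups(df) == {"green"}


class TestSharing:
    def test_reference_region_facts(self):
        inc = reference.reference_region_incidence()
        out = region_sharing(inc)
        assert out["in_all_regions"] == {"S10"}
        assert out["exclusive"]["Santorini"] == {"S15", "S17", "S18"}
        assert out["exclusive"]["Nemea"] == {"S11", "S12", "S13"}
        assert out["exclusive"]["Pelion"] == {"S1", "S2"}

    def test_exclusive_and_shared_partition_each_region(self):
        inc = reference.reference_region_incidence()
        out = region_sharing(inc)
        for region in inc.columns:
            present = set(inc.index[inc[region]])
            assert out["exclusive"][region] | out["shared"][region] == present
            assert out["exclusive"][region] & out["shared"][region] == set()

    def test_single_region_all_exclusive(self):
        inc = pd.DataFrame({"R": [True, True]}, index=["x", "y"])
        assert region_sharing(inc)["exclusive"]["R"] == {"x", "y"}

    def test_reference_wine_type_sets(self):
        out = wine_type_sharing(reference.reference_wine_type_incidence())
        assert out["both"] == {"S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10", "S20"}
        assert out["red_only"] == {"S1", "S11", "S12", "S13", "S14", "S19"}
        assert out["white_only"] == {"S15", "S16", "S17", "S18"}


class TestRichness:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (8, 3)])
    def test_type_boundaries(self, n, expected):
        assert community_richness({"s": n})["s"] == expected


def test_fermentation_csv_roundtrip(tmp_path):
    rows = [
        {"strain_id": "S1", "day": d, "glucose": g, "fructose": f, "replicate": "1"}
        for d, g, f in [(0, 119.5, 120.1), (7, 10.0, 12.0), (14, 1.0, 2.0)]
    ]
    path = tmp_path / "ferm.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    curves = read_fermentation_csv(path)
    assert len(curves) == 1
    assert residual_sugar(curves[0]) == pytest.approx(3.0)


def test_outcomes_csv_parses_booleans(tmp_path):
    path = tmp_path / "outcomes.csv"
    reference.load_strain_outcomes()  # bundled copy parses
    import importlib.resources as res
    raw = res.files("oenotype.data").joinpath("strain_outcomes.csv").read_text()
    path.write_text(raw)
    df = read_outcomes_csv(path)
    assert df["fermentation_capacity"].sum() == 13
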