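"""Ordinal coding of the five screening assays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oenotype.assays import (
    DIGIT_RANGES,
    AssayPanel,
    PhenotypeCode,
    PhenotypeEncoder,
    distinct_phenotypes,
    encode_acetic,
    encode_bglu,
    encode_h2s,
    encode_killer,
    encode_phenotype,
    encode_so2,
    decode_acetic,
    decode_bglu,
    read_assay_csv,
    write_assay_csv,
)
from oenotype.exceptions import (
    EmptyDataset,
    IncompleteAssay,
    NonMonotoneProfile,
    UnsupportedPhenotype,
)


def so2(top):
    """Growth series up to and including dose ``top``."""
    return {c: c <= top for c in (0, 100, 200, 300, 400, 500)}


class TestDigitEncoders:
    @pytest.mark.parametrize("state,digit", [("neutral", 1), ("sensitive", 2)])
    def test_killer_coding(self, state, digit):
        assert encode_killer(state) == digit

    def test_killer_positive_has_no_code(self):
        with pytest.raises(UnsupportedPhenotype):
            encode_killer("killer_positive")
        assert encode_killer("killer_positive", allow_killer_positive=True) == 3

    @pytest.mark.parametrize("scores,policy,digit", [
        ({2: 0, 5: 0, 8: 0}, "day8", 0),
        ({2: 0, 5: 0, 8: 0}, "max", 0),
        ({2: 0, 5: 0, 8: 0}, "mean", 0),
        ({2: 1, 5: 2, 8: 3}, "day8", 3),
        ({2: 1, 5: 2, 8: 3}, "max", 3),
        ({2: 3, 5: 1, 8: 0}, "max", 3),
        ({2: 1, 5: 2, 8: 2}, "mean", 2),
    ])
    def test_h2s_policies(self, scores, policy, digit):
        assert encode_h2s(scores, policy) == digit

    def test_h2s_missing_day(self):
        with pytest.raises(IncompleteAssay):
            encode_h2s({2: 1, 8: 2})

    def test_acetic_polarity_and_roundtrip(self):
        # 0 marks production: the undesirable state carries the zero code
        assert encode_acetic("producer") == 0
        assert encode_acetic("non_producer") == 1
        for state in ("producer", "non_producer"):
            assert decode_acetic(encode_acetic(state)) == state

    @pytest.mark.parametrize("top,digit", [(0, 0), (100, 1), (300, 1), (400, 2), (500, 2)])
    def test_so2_thresholds(self, top, digit):
        assert encode_so2(so2(top)) == digit

    def test_so2_non_monotone_warns_and_codes_from_top(self):
        series = so2(300)
        series[100] = False
        with pytest.warns(NonMonotoneProfile):
            assert encode_so2(series) == 1

    def test_bglu_roundtrip(self):
        assert encode_bglu("positive") == 0
        assert encode_bglu("negative") == 1
        for state in ("positive", "negative"):
            assert decode_bglu(encode_bglu(state)) == state


class TestFullCode:
    def test_reference_combination(self, panel_neutral_dry):
        assert encode_phenotype(panel_neutral_dry).digits == (1, 1, 0, 2, 1)

    def test_sensitive_low_activity_combination(self):
        panel = AssayPanel(
            killer="sensitive",
            h2s_scores={2: 0, 5: 0, 8: 0},
            acetic="non_producer",
            so2_growth=so2(0),
            bglu="positive",
        )
        assert encode_phenotype(panel).digits == (2, 0, 1, 0, 0)

    def test_encoding_is_deterministic(self, panel_neutral_dry):
        assert encode_phenotype(panel_neutral_dry) == encode_phenotype(panel_neutral_dry)

    @settings(derandomize=True, max_examples=60)
    @given(
        killer=st.sampled_from(["neutral", "sensitive"]),
        h2s=st.lists(st.integers(0, 3), min_size=3, max_size=3),
        acetic=st.sampled_from(["producer", "non_producer"]),
        top=st.sampled_from([0, 100, 200, 300, 400, 500]),
        bglu=st.sampled_from(["positive", "negative"]),
        policy=st.sampled_from(["day8", "max", "mean"]),
    )
    def test_every_panel_encodes_within_digit_ranges(self, killer, h2s, acetic, top, bglu, policy):
        panel = AssayPanel(killer, dict(zip((2, 5, 8), h2s)), acetic, so2(top), bglu)
        code = encode_phenotype(panel, policy)
        for d, (lo, hi) in zip(code.digits, DIGIT_RANGES):
            assert lo <= d <= hi


class TestDistinctPhenotypes:
    def test_counting(self):
        codes = [PhenotypeCode((1, 0, 0, 2, 1)), PhenotypeCode((1, 0, 0, 2, 1)),
                 PhenotypeCode((2, 0, 0, 2, 1))]
        out = distinct_phenotypes(codes)
        assert [(c.digits, n) for c, n in out] == [((1, 0, 0, 2, 1), 2), ((2, 0, 0, 2, 1), 1)]

    def test_multiplicities_sum_to_input_size(self, rng):
        from conftest import random_code_matrix
        codes = [PhenotypeCode(tuple(int(x) for x in row))
                 for row in random_code_matrix(rng, 40)]
        out = distinct_phenotypes(codes)
        assert sum(n for _, n in out) == 40
        assert [c.digits for c, _ in out] == sorted(c.digits for c, _ in out)

    def test_all_identical_and_empty(self):
        assert len(distinct_phenotypes([PhenotypeCode((1, 1, 0, 2, 1))] * 5)) == 1
        with pytest.raises(EmptyDataset):
            distinct_phenotypes([])


class TestEncoderEstimator:
    def test_transform_matrix(self, panel_neutral_dry):
        X = PhenotypeEncoder().fit_transform([panel_neutral_dry] * 3)
        assert X.shape == (3, 5)
        assert (X == np.array([1, 1, 0, 2, 1])).all()

    def test_get_params_roundtrip(self):
        enc = PhenotypeEncoder(h2s_policy="max")
        assert PhenotypeEncoder(**enc.get_params()).h2s_policy == "max"

    def test_bad_policy_rejected(self, panel_neutral_dry):
        with pytest.raises(ValueError):
            PhenotypeEncoder(h2s_policy="median").fit_transform([panel_neutral_dry])


def test_assay_csv_roundtrip(tmp_path):
    from oenotype.simulate import SimulationConfig, gen_isolate_panel

    records, _ = gen_isolate_panel(SimulationConfig(seed=7, n_isolates=15))
    path = tmp_path / "assays.csv"
    write_assay_csv(records, path)
    back = read_assay_csv(path)
    assert [r.isolate_id for r in back] == [r.isolate_id for r in records]
    assert all(
        encode_phenotype(a.assays) == encode_phenotype(b.assays)
        for a, b in zip(records, back)
    )
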