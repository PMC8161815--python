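"""Localized mismatch index: delta algebra, the product table, transition
classification and rate summaries.

The frozen 6x6 product table below is the canonical 3-stage LMI table
(rows = PSG delta for W-L, W-D, L-D, L-W, D-L, D-W; columns = device delta
in the same order): symmetric, with diagonal {1, 4, 9}.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnoval import (
    AlignedPair,
    Hypnogram,
    StageEncoding,
    UndefinedRateError,
    classify_lmi,
    lmi_sequence,
    summarize_rates,
    transition_deltas,
)

ENC3 = StageEncoding.default()
DELTAS_IN_PAPER_ORDER = (1, 3, 2, -1, -2, -3)  # W-L, W-D, L-D, L-W, D-L, D-W

LMI_TABLE = np.array(
    [
        [1, 3, 2, -1, -2, -3],
        [3, 9, 6, -3, -6, -9],
        [2, 6, 4, -2, -4, -6],
        [-1, -3, -2, 1, 2, 3],
        [-2, -6, -4, 2, 4, 6],
        [-3, -9, -6, 3, 6, 9],
    ]
)

CLASS_OF_PRODUCT = {
    1: "correct_wake",
    9: "correct_wake",
    4: "correct_sleep",
    3: "incorrect_sleep",
    -4: "incorrect_sleep",
}


def _pair(psg_stages, dev_stages, alphabet="DEV3"):
    return AlignedPair(
        psg=Hypnogram(stages=tuple(psg_stages), alphabet=alphabet, source="PSG"),
        device=Hypnogram(stages=tuple(dev_stages), alphabet=alphabet, source="device"),
    )


TRANSITIONS_3 = [  # (from, to, delta) in the canonical order
    ("Wake", "Light", 1),
    ("Wake", "Deep", 3),
    ("Light", "Deep", 2),
    ("Light", "Wake", -1),
    ("Deep", "Light", -2),
    ("Deep", "Wake", -3),
]


class TestDeltas:
    def test_deep_to_wake_is_minus_three(self):
        h = Hypnogram(stages=("Deep", "Wake"), alphabet="DEV3")
        from hypnoval import encode

        assert transition_deltas(encode(h, ENC3)).tolist() == [-3]

    def test_six_legal_transitions_in_paper_order(self):
        from hypnoval import encode

        for (a, b, expected) in TRANSITIONS_3:
            h = Hypnogram(stages=(a, b), alphabet="DEV3")
            assert transition_deltas(encode(h, ENC3))[0] == expected

    def test_constant_sequence_all_zero(self):
        assert transition_deltas(np.array([2, 2, 2, 2])).tolist() == [0, 0, 0]

    def test_hand_difference(self):
        assert transition_deltas(np.array([1, 2, 4, 2, 1])).tolist() == [1, 2, -2, -1]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            transition_deltas(np.array([1]))


class TestProductTable:
    def test_exhaustive_36_cell_reproduction(self):
        """Every ordered pair of legal transitions reproduces the product table,
        its diagonal {1,4,9}, symmetry, and the four-class grouping."""
        for r, (pa, pb, dp) in enumerate(TRANSITIONS_3):
            for c, (da, db, dw) in enumerate(TRANSITIONS_3):
                pair = _pair([pa, pb], [da, db])
                res = lmi_sequence(pair, ENC3)
                assert res.transition_set.tolist() == [0]
                value = int(res.lmi_values[0])
                assert value == LMI_TABLE[r, c] == dp * dw
                expected_class = CLASS_OF_PRODUCT.get(value, "incorrect_wake")
                if r == c:
                    assert value in (1, 4, 9)
                    assert res.classes[0].startswith("correct")
                assert res.classes[0] == expected_class
        assert (LMI_TABLE == LMI_TABLE.T).all()

    def test_same_epoch_wake_deep_agreement_scores_nine(self):
        res = lmi_sequence(_pair(["Wake", "Deep"], ["Wake", "Deep"]), ENC3)
        assert res.lmi_values.tolist() == [9]
        assert res.classes == ("correct_wake",)

    def test_one_sided_wake_deep_vs_light_deep_scores_six(self):
        res = lmi_sequence(_pair(["Wake", "Deep"], ["Light", "Deep"]), ENC3)
        assert res.lmi_values.tolist() == [6]
        assert res.classes == ("incorrect_wake",)

    def test_identical_hypnograms_give_perfect_squares(self, default_scenario):
        from hypnoval import DeviceType, categorize_psg, simulate_psg

        h = categorize_psg(simulate_psg(default_scenario), DeviceType.TYPE_II)
        res = lmi_sequence(AlignedPair(psg=h, device=h), ENC3)
        assert res.n_transitions > 0
        assert set(res.lmi_values.tolist()) <= {1, 4, 9}
        assert res.rates["overall_correct"] == 100.0


class TestClassification:
    @pytest.mark.parametrize(
        "dp, dw, expected",
        [
            (3, 3, "correct_wake"),  # product 9
            (1, 1, "correct_wake"),
            (2, 2, "correct_sleep"),  # product 4
            (2, -2, "incorrect_sleep"),  # product -4
            (1, 3, "incorrect_sleep"),  # product 3: wake direction agrees
            (-3, -1, "incorrect_sleep"),
            (1, 2, "incorrect_wake"),  # product 2
            (3, -3, "incorrect_wake"),  # product -9
            (2, 0, "incorrect_sleep"),  # one-sided sleep transition missed
            (0, 2, "incorrect_sleep"),
            (1, 0, "incorrect_wake"),  # one-sided wake transition missed
            (0, -3, "incorrect_wake"),
        ],
    )
    def test_delta_pair_classes(self, dp, dw, expected):
        assert classify_lmi(dp, dw, ENC3, "DEV3") == expected

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            classify_lmi(0, 0, ENC3, "DEV3")

    def test_symmetry_under_role_swap(self):
        deltas = [0, *DELTAS_IN_PAPER_ORDER]
        for dp in deltas:
            for dw in deltas:
                if dp == 0 and dw == 0:
                    continue
                assert classify_lmi(dp, dw, ENC3, "DEV3") == classify_lmi(
                    dw, dp, ENC3, "DEV3"
                )

    def test_product_is_square_of_legal_delta_iff_deltas_equal(self):
        """Brute force over all 7x7 delta pairs including zero."""
        squares = {d * d for d in DELTAS_IN_PAPER_ORDER}
        deltas = [0, *DELTAS_IN_PAPER_ORDER]
        for dp in deltas:
            for dw in deltas:
                if dp == 0 and dw == 0:
                    continue
                is_square = dp * dw in squares
                assert is_square == (dp == dw and dp != 0)
                if dp == dw:
                    assert classify_lmi(dp, dw, ENC3, "DEV3").startswith("correct")

    @pytest.mark.parametrize("rem_code", [8, 16, 9])
    def test_four_stage_classes_do_not_depend_on_rem_code(self, rem_code):
        """4-stage classification is pair-based: correct iff equal deltas,
        wake/sleep split by the wake-crossing component, for any REM code."""
        enc = StageEncoding.default(rem_code=rem_code)
        stages = ("Wake", "Light", "Deep", "REM")
        ref = StageEncoding.default(rem_code=8)
        for a in stages:
            for b in stages:
                if a == b:
                    continue
                for c in stages:
                    for d in stages:
                        if c == d:
                            continue
                        dp = enc.codes[b] - enc.codes[a]
                        dw = enc.codes[d] - enc.codes[c]
                        got = classify_lmi(dp, dw, enc, "DEV4")
                        want = classify_lmi(
                            ref.codes[b] - ref.codes[a],
                            ref.codes[d] - ref.codes[c],
                            ref,
                            "DEV4",
                        )
                        assert got == want
                        if (a, b) == (c, d):
                            assert got.startswith("correct")
                        else:
                            assert got.startswith("incorrect")


class TestRates:
    def test_rates_sum_to_hundred_and_split_consistently(self, noisy_scenario):
        from hypnoval import AlignedPair, categorize_psg, generate_night

        psg, dev, _ = generate_night(noisy_scenario)
        pair = AlignedPair(
            psg=categorize_psg(psg, noisy_scenario.device_type), device=dev
        )
        res = lmi_sequence(pair, ENC3)
        r = res.rates
        assert sum(r[c] for c in ("correct_wake", "correct_sleep", "incorrect_wake", "incorrect_sleep")) == pytest.approx(100.0)
        assert r["overall_correct"] + r["overall_incorrect"] == pytest.approx(100.0)

    def test_constant_device_misses_every_psg_transition(self):
        psg = ["Wake", "Light", "Light", "Deep", "Light", "Wake"]
        dev = ["Light"] * 6
        res = lmi_sequence(_pair(psg, dev), ENC3)
        assert res.n_transitions == 4
        assert res.rates["overall_correct"] == 0.0
        assert (res.lmi_values == 0).all()

    def test_empty_transition_set_rates_undefined(self):
        res = lmi_sequence(_pair(["Light"] * 5, ["Light"] * 5), ENC3)
        assert res.n_transitions == 0 and res.rates is None
        with pytest.raises(UndefinedRateError):
            summarize_rates(res)

    def test_planted_agreement_rate_recovered(self, rng):
        """Each PSG transition is either copied exactly (prob 0.3) or delayed
        by two epochs; bookkeeping gives the exact expected correct rate:
        kept boundaries contribute one correct epoch, delayed ones two
        one-sided incorrect epochs (runs are long enough not to collide)."""
        cycle = ["Light", "Deep", "Wake"]
        kept_total = 0
        trans_total = 0
        correct = 0
        a_total = 0
        for _ in range(30):
            # PSG: runs of 6 epochs cycling Light -> Deep -> Wake
            runs = [cycle[j % 3] for j in range(40)]
            stages = [s for s in runs for _ in range(6)]
            dev = list(stages)
            n = len(stages)
            kept = 0
            delayed = 0
            for b in range(6, n, 6):  # run boundaries
                trans_total += 1
                if rng.random() < 0.3:
                    kept += 1
                else:
                    delayed += 1
                    dev[b : b + 2] = [stages[b - 1]] * 2
            kept_total += kept
            res = lmi_sequence(_pair(stages, dev), ENC3)
            correct += sum(c.startswith("correct") for c in res.classes)
            a_total += res.n_transitions
            assert res.n_transitions == kept + 2 * delayed
        assert correct == kept_total  # exact bookkeeping oracle
        sigma = np.sqrt(0.3 * 0.7 / trans_total)
        assert kept_total / trans_total == pytest.approx(0.3, abs=3 * sigma)
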