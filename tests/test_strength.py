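"""Strength model: proximity weights, per-base scoring, calibration."""

import numpy as np
import pytest

from conftest import make_design
from minsyn.pool import C_CRE_NON_TGA, C_CRE_TGA, GENERIC
from minsyn.strength import (
    StrengthModel,
    calibrate,
    predict_strength,
    proximity_weight,
    raw_score,
    score_library,
)

MODEL = StrengthModel()


class TestProximityWeight:
    @pytest.mark.parametrize(
        "distance,cls,expected",
        [
            (0, C_CRE_TGA, 1.0),
            (60, C_CRE_TGA, 1.0),  # end of the TGA plateau
            (95, C_CRE_TGA, 0.5),  # halfway down the 70 bp decay
            (130, C_CRE_TGA, 0.0),  # 60 + 70: fully decayed
            (200, C_CRE_TGA, 0.0),
            (100, C_CRE_NON_TGA, 1.0),  # inside the 130 bp plateau
            (130, C_CRE_NON_TGA, 1.0),
            (200, C_CRE_NON_TGA, 0.0),
        ],
    )
    def test_piecewise_linear_form(self, distance, cls, expected):
        assert proximity_weight(distance, cls, MODEL) == pytest.approx(expected)

    def test_generic_class_rejected(self):
        with pytest.raises(ValueError, match="C-CRE classes only"):
            proximity_weight(10, GENERIC, MODEL)

    def test_weight_nonincreasing_in_distance(self):
        for cls in (C_CRE_TGA, C_CRE_NON_TGA):
            weights = [proximity_weight(d, cls, MODEL) for d in range(0, 301)]
            assert all(a >= b for a, b in zip(weights, weights[1:]))
            assert weights[0] == 1.0 and weights[-1] == 0.0


def one_cre_design(cre_class=GENERIC, gap=0, cre_len=10, spacer_len=21, prefix_len=19):
    """prefix + spacer + CRE + (gap bases) + TATA + core; CRE 3' edge sits
    ``gap`` bases from the TATA box."""
    parts = [
        ("prefix", "A" * prefix_len),
        ("spacer", "C" * spacer_len),
        ("cre", "G" * cre_len, "X", cre_class),
    ]
    if gap:
        parts.append(("spacer", "A" * gap))
    return make_design("d", parts)


class TestRawScore:
    def test_no_cres_scores_zero(self):
        design = make_design("MinSyn000", [("prefix", "A" * 19), ("spacer", "C" * 10)])
        assert raw_score(design, MODEL) == 0.0

    def test_hand_computed_generic_example(self):
        # 100 bp total, one 10 bp generic CRE abutting the TATA box
        design = one_cre_design(GENERIC, gap=0)
        assert len(design.sequence) == 100
        assert raw_score(design, MODEL) == pytest.approx(10 / 100)

    def test_tga_ccre_weight_drops_past_plateau(self):
        near = raw_score(one_cre_design(C_CRE_TGA, gap=30), MODEL)
        far = raw_score(one_cre_design(C_CRE_TGA, gap=90), MODEL)
        assert near > far

    def test_gap_penalty_kicks_in_past_fifty(self):
        """The summed (length-corrected) score is flat up to a 50 bp gap and
        lower beyond."""
        def summed(gap):
            design = one_cre_design(GENERIC, gap=gap)
            return raw_score(design, MODEL) * len(design.sequence)

        assert summed(0) == summed(50) == pytest.approx(10.0)
        assert summed(51) < summed(50)
        assert summed(50 + 70) == pytest.approx(0.0)

    def test_between_two_ccres_bonus(self):
        """Bases strictly between the outermost C-CRE pair pick up the
        midpoint-weighted bonus."""
        parts = [
            ("prefix", "A" * 19),
            ("spacer", "C" * 5),
            ("cre", "G" * 10, "cc1", C_CRE_TGA),
            ("spacer", "C" * 20),
            ("cre", "G" * 10, "cc2", C_CRE_TGA),
        ]
        design = make_design("d", parts)
        tata = design.tata_start
        # both C-CREs on the TGA plateau; between-region = the 20 bp spacer
        d1 = tata - (19 + 5 + 10)  # distal C-CRE 3' edge: 30 bases from TATA
        assert d1 == 30
        expected_sum = (
            2.0 * 1.0 * 10  # proximal C-CRE, distance 0
            + 2.0 * 1.0 * 10  # distal C-CRE, distance 30 (on plateau)
            + 0.5 * 1.0 * 20  # between-region, midpoint 20 bp from TATA
        )
        assert raw_score(design, MODEL) == pytest.approx(
            expected_sum / len(design.sequence)
        )

    def test_single_ccre_gets_no_between_bonus(self):
        design = one_cre_design(C_CRE_TGA, gap=0)
        assert raw_score(design, MODEL) == pytest.approx(2.0 * 10 / 100)

    def test_decreasing_tga_distance_never_decreases_score(self):
        scores = [
            raw_score(one_cre_design(C_CRE_TGA, gap=g), MODEL)
            for g in range(0, 200, 10)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_adding_above_mean_generic_cre_raises_score(self):
        base = one_cre_design(GENERIC, gap=0)
        base_raw = raw_score(base, MODEL)
        assert base_raw < MODEL.s_generic
        richer = make_design(
            "d+",
            [
                ("prefix", "A" * 19),
                ("spacer", "C" * 21),
                ("cre", "G" * 10, "X", GENERIC),
                ("spacer", "C" * 5),
                ("cre", "T" * 10, "Y", GENERIC),
            ],
        )
        assert raw_score(richer, MODEL) > base_raw

    def test_cre_downstream_of_tata_rejected(self):
        from minsyn.design import DEFAULT_CORE, DEFAULT_TATA, MinSynDesign, Segment

        design = MinSynDesign(
            "bad",
            (
                Segment("prefix", "A" * 19),
                Segment("tata", DEFAULT_TATA),
                Segment("cre", "G" * 10, cre_id="X", cre_class=GENERIC),
                Segment("core", DEFAULT_CORE),
            ),
        )
        with pytest.raises(ValueError, match="upstream"):
            raw_score(design, MODEL)


class TestCalibration:
    def test_exact_fit_recovers_slope_and_unit_r2(self):
        fitted, diag = calibrate(MODEL, [(1, 3), (2, 6), (4, 12)])
        assert diag.calibration_k == pytest.approx(3.0)
        assert diag.r_squared == pytest.approx(1.0)
        assert fitted.calibration_k == diag.calibration_k

    def test_closed_form_numerator(self):
        _, diag = calibrate(MODEL, [(1, 2), (2, 4), (3, 7)])
        assert diag.calibration_k == pytest.approx(31 / 14)

    def test_matches_statsmodels_through_origin(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 1.0, 40)
        y = 2.2 * x + rng.normal(0, 0.1, 40)
        _, diag = calibrate(MODEL, list(zip(x, y)))
        reference = sm.OLS(y, x).fit()
        assert diag.calibration_k == pytest.approx(reference.params[0])

    def test_recovery_within_two_se(self):
        rng = np.random.default_rng(17)
        k_true, sigma, n = 2.5, 0.12, 50
        x = rng.uniform(0.05, 0.8, n)
        y = k_true * x + rng.normal(0, sigma, n)
        _, diag = calibrate(MODEL, list(zip(x, y)))
        se = sigma / np.sqrt(np.sum(x**2))
        assert abs(diag.calibration_k - k_true) < 2 * se

    def test_all_zero_scores_cannot_calibrate(self):
        with pytest.raises(ValueError, match="all raw scores are zero"):
            calibrate(MODEL, [(0, 1), (0, 2)])

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            calibrate(MODEL, [(1, 2)])


class TestPredict:
    def test_uncalibrated_model_refuses(self):
        with pytest.raises(ValueError, match="not calibrated"):
            predict_strength(one_cre_design(), MODEL)

    def test_zero_raw_score_predicts_zero(self):
        model = StrengthModel(calibration_k=3.0)
        design = make_design("MinSyn000", [("prefix", "A" * 19), ("spacer", "C" * 10)])
        assert predict_strength(design, model) == 0.0

    def test_prediction_linear_in_k(self):
        design = one_cre_design(C_CRE_TGA)
        one = predict_strength(design, StrengthModel(calibration_k=1.5))
        two = predict_strength(design, StrengthModel(calibration_k=3.0))
        assert two == pytest.approx(2 * one)

    def test_prediction_order_equals_raw_order(self, pool):
        from minsyn.design import GeneratorConfig, generate_library

        library = generate_library(pool, GeneratorConfig(library_size=30, rng_seed=2))
        scored = score_library(library, StrengthModel(calibration_k=2.0))
        assert (
            scored.sort_values("raw_score").design_id.tolist()
            == scored.sort_values("predicted_strength").design_id.tolist()
        )
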