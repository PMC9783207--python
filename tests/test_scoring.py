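"""Normalization, Kiviat area, SD propagation and rendering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdqa.scoring import (
    AXIS_ORDER,
    KiviatResult,
    NormalizedScores,
    kiviat_area,
    normalize_parameters,
    render_kiviat,
)


def scores_from(radii, sds=None):
    sds = sds or [0.0] * 5
    kw = {k: (float(r), float(s)) for k, r, s in zip(AXIS_ORDER, radii, sds)}
    return NormalizedScores(**kw)


def shoelace_area(radii):
    """Independent oracle: explicit polygon vertices + shoelace formula."""
    angles = [math.radians(90 - 72 * i) for i in range(5)]
    pts = [(r * math.cos(a), r * math.sin(a)) for r, a in zip(radii, angles)]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


GOLD_AREA = shoelace_area([1.0] * 5)


class TestNormalization:
    def test_survey_row_phased_1A(self):
        s = normalize_parameters(
            BA=(2.0, 1.1), RE=(20.0, 5.0), AMVS=(0.50, 0.26), VeMeA=(0.42, 0.03), TR=(0.08, 0.01)
        )
        assert s.BA[0] == pytest.approx(0.96, abs=0.005)
        assert s.RE[0] == pytest.approx(0.80)
        assert s.AMVS[0] == pytest.approx(0.50)
        assert s.VeMeA[0] == pytest.approx(0.58)
        assert s.TR[0] == pytest.approx(0.40)

    def test_endpoint_cases(self):
        s = normalize_parameters((45.0, 0), (0.0, 0), (1.0, 0), (0.0, 0), (0.5, 0))
        assert s.BA[0] == 0.0
        assert s.RE[0] == 1.0
        assert s.AMVS[0] == 1.0
        assert s.VeMeA[0] == 1.0
        assert s.TR[0] == 1.0

    def test_amvs_above_one_folds(self):
        s = normalize_parameters((0, 0), (0, 0), (1.3, 0), (0, 0), (0.5, 0))
        assert s.AMVS[0] == pytest.approx(0.7)

    def test_clipping_recorded(self):
        s = normalize_parameters((50.0, 0), (0, 0), (1.0, 0), (1.4, 0), (0.5, 0))
        assert s.BA[0] == 0.0 and s.VeMeA[0] == 0.0
        assert set(s.clipped) == {"BA", "VeMeA"}

    def test_sd_propagation(self):
        s = normalize_parameters((10.0, 4.5), (30.0, 7.0), (0.8, 0.2), (0.3, 0.05), (0.18, 0.02))
        assert s.BA[1] == pytest.approx(4.5 / 45)
        assert s.RE[1] == pytest.approx(0.07)
        assert s.AMVS[1] == pytest.approx(0.2)
        assert s.VeMeA[1] == pytest.approx(0.05)
        assert s.TR[1] == pytest.approx(0.02 / (2 * math.sqrt(0.18 * 0.5)))


class TestKiviatArea:
    def test_gold_standard_is_one(self):
        assert kiviat_area(scores_from([1.0] * 5)).S_star == pytest.approx(1.0)

    def test_survey_area_phased_1A(self):
        res = kiviat_area(scores_from([0.96, 0.80, 0.50, 0.58, 0.40]))
        assert res.S_star == pytest.approx(0.41, abs=0.005)

    @settings(max_examples=50, deadline=None)
    @given(radii=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5))
    def test_matches_shoelace_oracle(self, radii):
        closed_form = kiviat_area(scores_from(radii)).S_star
        assert closed_form == pytest.approx(shoelace_area(radii) / GOLD_AREA, abs=1e-12)

    def test_monotone_in_each_score(self):
        base = [0.5, 0.6, 0.4, 0.7, 0.3]
        s0 = kiviat_area(scores_from(base)).S_star
        for i in range(5):
            bumped = list(base)
            bumped[i] += 0.2
            assert kiviat_area(scores_from(bumped)).S_star > s0

    def test_cyclic_and_reflection_invariance(self):
        radii = [0.9, 0.3, 0.7, 0.5, 0.2]
        ref = kiviat_area(scores_from(radii)).S_star
        for k in range(1, 5):
            rotated = radii[k:] + radii[:k]
            assert kiviat_area(scores_from(rotated)).S_star == pytest.approx(ref)
        assert kiviat_area(scores_from(radii[::-1])).S_star == pytest.approx(ref)

    def test_not_invariant_under_arbitrary_permutation(self):
        radii = [0.9, 0.3, 0.7, 0.5, 0.2]
        ref = kiviat_area(scores_from(radii)).S_star
        areas = {
            round(kiviat_area(scores_from(list(p))).S_star, 9)
            for p in itertools.permutations(radii)
        }
        assert len(areas) > 1  # the axis order is part of the contract

    def test_sigma_propagation_survey_row(self):
        # printed scores and SDs of the best phased system, configuration A
        res = kiviat_area(
            scores_from([0.96, 0.80, 0.50, 0.58, 0.40], [0.02, 0.05, 0.26, 0.03, 0.02])
        )
        assert res.sigma_S_star == pytest.approx(0.07, abs=0.005)

    def test_sigma_matches_finite_differences(self):
        radii = [0.6, 0.8, 0.3, 0.9, 0.5]
        sds = [0.01, 0.02, 0.03, 0.01, 0.02]
        res = kiviat_area(scores_from(radii, sds))
        grad_sq = 0.0
        eps = 1e-6
        for i in range(5):
            hi = list(radii)
            hi[i] += eps
            lo = list(radii)
            lo[i] -= eps
            g = (kiviat_area(scores_from(hi)).S_star - kiviat_area(scores_from(lo)).S_star) / (
                2 * eps
            )
            grad_sq += (g * sds[i]) ** 2
        assert res.sigma_S_star == pytest.approx(math.sqrt(grad_sq), rel=1e-4)


class TestRenderKiviat:
    def test_file_created_nonempty(self, tmp_path):
        res = kiviat_area(scores_from([0.9, 0.8, 0.5, 0.6, 0.4]))
        out = tmp_path / "kiviat.png"
        render_kiviat(res, str(out))
        assert out.exists() and out.stat().st_size > 0

    def test_svg_rerender_byte_identical(self, tmp_path):
        res = kiviat_area(scores_from([0.9, 0.8, 0.5, 0.6, 0.4]))
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        render_kiviat(res, str(p1))
        render_kiviat(res, str(p2))
        assert p1.read_bytes() == p2.read_bytes()
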