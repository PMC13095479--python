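"""Model curves, their closed-form derived parameters, and the numeric peak."""

import math

import numpy as np
import pytest

from rlcfit import light_models as lm
from rlcfit.light_models import (
    EilersPeetersParams,
    InvalidParamsError,
    PlattParams,
    VollenweiderParams,
    WalsbyParams,
    NoInteriorMaximumError,
    derive,
    numeric_curve_max,
    predict,
)

from conftest import grid_search_max, random_valid_params

EXAMPLES = {
    "eilers_peeters": EilersPeetersParams(a=1e-5, b=1e-3, c=2.0),
    "platt": PlattParams(ps=100.0, alpha=0.4, beta=0.02),
    "walsby": WalsbyParams(etr_max=100.0, alpha=0.5, beta=-0.02),
    "vollenweider": VollenweiderParams(pmax=100.0, a=0.01, alpha=0.002, n=1.0),
}


@pytest.mark.parametrize("model", lm.MODEL_ORDER)
def test_curves_vanish_at_zero_light(model):
    assert predict(model, EXAMPLES[model], 0.0) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "model,par,expected",
    [
        ("eilers_peeters", 447.214, 100.56),  # the curve maximum
        ("platt", 0.0, 0.0),
        ("walsby", 643.78, 83.12),  # value at the stationary point
    ],
)
def test_point_evaluations(model, par, expected):
    assert predict(model, EXAMPLES[model], par) == pytest.approx(expected, abs=0.005)


def test_predict_is_vectorized_and_nonnegative():
    for model, params in EXAMPLES.items():
        d = derive(model, params)
        im = d.im_with_photoinhibition or d.ik_with_photoinhibition
        grid = np.linspace(0.0, 2.0 * im, 500)
        vals = predict(model, params, grid)
        assert vals.shape == grid.shape
        assert np.all(vals >= 0)


@pytest.mark.parametrize(
    "model,bad",
    [
        ("eilers_peeters", EilersPeetersParams(a=-1e-5, b=1e-3, c=2.0)),
        ("eilers_peeters", EilersPeetersParams(a=1e-5, b=-1.0, c=2.0)),
        ("platt", PlattParams(ps=100.0, alpha=0.4, beta=-0.01)),
        ("platt", PlattParams(ps=-5.0, alpha=0.4, beta=0.02)),
        ("walsby", WalsbyParams(etr_max=100.0, alpha=0.1, beta=-0.2)),
        ("vollenweider", VollenweiderParams(pmax=100.0, a=0.0, alpha=0.002, n=1.0)),
    ],
)
def test_invalid_params_rejected(model, bad):
    with pytest.raises(InvalidParamsError):
        predict(model, bad, 100.0)


def test_wrong_param_type_rejected():
    with pytest.raises(TypeError):
        predict("platt", EXAMPLES["eilers_peeters"], 100.0)


class TestDerivedClosedForms:
    def test_eilers_peeters_example(self):
        d = derive("eilers_peeters", EXAMPLES["eilers_peeters"])
        assert d.alpha == pytest.approx(0.5)
        assert d.etrmax_with_photoinhibition == pytest.approx(100.56, abs=0.005)
        assert d.ik_with_photoinhibition == pytest.approx(201.12, abs=0.01)
        assert d.im_with_photoinhibition == pytest.approx(447.21, abs=0.01)
        assert d.w == pytest.approx(0.2236, abs=1e-4)
        for na in ("beta", "etrmax_without_photoinhibition",
                   "ik_without_photoinhibition", "ib", "etrmax_without_with_ratio"):
            assert getattr(d, na) is None

    def test_eilers_peeters_maximum_identity(self):
        p = EXAMPLES["eilers_peeters"]
        d = derive("eilers_peeters", p)
        assert predict("eilers_peeters", p, d.im_with_photoinhibition) == \
            pytest.approx(d.etrmax_with_photoinhibition, rel=1e-12)
        assert d.ik_with_photoinhibition == \
            pytest.approx(d.etrmax_with_photoinhibition / d.alpha, rel=1e-12)

    def test_platt_example(self):
        d = derive("platt", EXAMPLES["platt"])
        assert d.etrmax_with_photoinhibition == pytest.approx(81.79, abs=0.005)
        assert d.ik_with_photoinhibition == pytest.approx(204.5, abs=0.05)
        assert d.ik_without_photoinhibition == pytest.approx(250.0)
        assert d.im_with_photoinhibition == pytest.approx(761.1, abs=0.05)
        assert d.ib == pytest.approx(5000.0)
        assert d.etrmax_without_with_ratio == pytest.approx(1.2226, abs=1e-4)
        assert d.w is None

    def test_platt_no_photoinhibition_limit(self):
        d = derive("platt", PlattParams(ps=100.0, alpha=0.4, beta=0.0))
        assert d.etrmax_with_photoinhibition == 100.0
        assert d.etrmax_without_with_ratio == 1.0
        assert d.im_with_photoinhibition is None
        assert d.ib is None

    def test_walsby_example(self):
        d = derive("walsby", EXAMPLES["walsby"])
        assert d.im_with_photoinhibition == pytest.approx(643.78, abs=0.01)
        assert d.etrmax_with_photoinhibition == pytest.approx(83.12, abs=0.005)
        assert d.alpha == pytest.approx(0.48)

    def test_walsby_no_inhibition_limit(self):
        d = derive("walsby", WalsbyParams(etr_max=100.0, alpha=0.5, beta=0.0))
        assert d.etrmax_with_photoinhibition == 100.0
        assert d.im_with_photoinhibition is None
        assert d.etrmax_without_with_ratio == 1.0

    def test_vollenweider_example(self):
        d = derive("vollenweider", EXAMPLES["vollenweider"])
        assert d.alpha == pytest.approx(1.0)
        assert d.ik_without_photoinhibition == pytest.approx(100.0)
        assert d.etrmax_with_photoinhibition == pytest.approx(83.33, abs=0.05)
        assert d.im_with_photoinhibition == pytest.approx(223.6, rel=0.01)
        assert d.etrmax_without_with_ratio == pytest.approx(1.20, abs=0.005)

    def test_vollenweider_no_inhibition(self):
        d = derive("vollenweider",
                   VollenweiderParams(pmax=50.0, a=0.02, alpha=0.0, n=1.0))
        assert d.etrmax_with_photoinhibition == 50.0
        assert d.im_with_photoinhibition is None

    @pytest.mark.parametrize("model", ["platt", "walsby", "vollenweider"])
    def test_ratio_equals_ik_ratio(self, model):
        d = derive(model, EXAMPLES[model])
        assert d.etrmax_without_with_ratio == pytest.approx(
            d.etrmax_without_photoinhibition / d.etrmax_with_photoinhibition,
            abs=1e-9)
        assert d.etrmax_without_with_ratio == pytest.approx(
            d.ik_without_photoinhibition / d.ik_with_photoinhibition, abs=1e-9)


class TestNumericCurveMax:
    def test_quadratic(self):
        im, mx = numeric_curve_max(lambda x: -(np.asarray(x) - 500.0) ** 2 + 100.0,
                                   upper_hint=300.0)
        assert im == pytest.approx(500.0, abs=0.01)
        assert mx == pytest.approx(100.0, abs=1e-6)

    def test_matches_eilers_closed_form(self):
        p = EXAMPLES["eilers_peeters"]
        im, mx = numeric_curve_max(lambda x: predict("eilers_peeters", p, x), 100.0)
        assert im == pytest.approx(447.21, abs=0.1)
        assert mx == pytest.approx(100.56, abs=0.005)

    def test_monotone_curve_flagged(self):
        with pytest.raises(NoInteriorMaximumError):
            numeric_curve_max(lambda x: np.asarray(x, dtype=float), 100.0)


@pytest.mark.parametrize("model", lm.MODEL_ORDER)
def test_derived_match_grid_oracle(model):
    """Derived peak location/height agree with a dense-grid search, and the
    derived initial slope with a numeric derivative near zero light."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        params = random_valid_params(model, rng)
        d = derive(model, params)
        im_g, mx_g = grid_search_max(model, params, n_grid=200_001)
        assert d.etrmax_with_photoinhibition == pytest.approx(mx_g, rel=1e-3)
        assert d.im_with_photoinhibition == pytest.approx(im_g, rel=1e-3)
        h = 1e-4 * d.ik_with_photoinhibition
        slope = (predict(model, params, 2 * h) - predict(model, params, 0.0)) / (2 * h)
        assert d.alpha == pytest.approx(slope, rel=5e-3)
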