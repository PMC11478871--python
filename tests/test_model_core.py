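"""Four-group mixture model: types, density evaluation, Lfdr formula."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stareg import (FourGroupModel, MixtureParams, MonotoneDensity,
                    PairedPValues, compute_lfdr, evaluate_density,
                    mixture_log_likelihood)
from stareg.model_core import UNIFORM_DENSITY

from .conftest import paired, random_mixture_params, random_monotone_density


class TestTypes:
    def test_paired_pvalues_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            PairedPValues(np.array(["a"]), [0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="unique"):
            PairedPValues(np.array(["a", "a"]), [0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="outside"):
            paired([0.1, 1.5], [0.3, 0.4])

    def test_boundary_pvalues_are_clipped_inside_open_interval(self):
        d = paired([0.0, 1.0], [0.5, 0.5])
        assert d.p1[0] > 0.0 and d.p1[1] < 1.0
        # clipping preserves ordering
        assert d.p1[0] < d.p1[1]

    def test_mixture_params_must_be_simplex(self):
        with pytest.raises(ValueError):
            MixtureParams(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(ValueError):
            MixtureParams(0.5, 0.2, 0.2, 0.2)

    def test_monotone_density_rejects_increasing_heights(self):
        with pytest.raises(ValueError, match="non-increasing"):
            MonotoneDensity(knots=[0.0, 0.5, 1.0], heights=[0.4, 1.6])
        with pytest.raises(ValueError, match="integrate"):
            MonotoneDensity(knots=[0.0, 0.5, 1.0], heights=[2.0, 0.4])


class TestEvaluateDensity:
    def test_uniform_density_is_one_everywhere(self):
        assert evaluate_density(UNIFORM_DENSITY, 0.3) == 1.0

    def test_step_density_lookup(self):
        # least-concave-majorant of the ECDF of {0.1, 0.2, 0.9}
        d = MonotoneDensity(knots=[0.0, 0.2, 0.9, 1.0],
                            heights=[10 / 3, 10 / 21, 0.0])
        assert evaluate_density(d, 0.5) == pytest.approx(10 / 21)
        # left-continuity: an interior breakpoint takes the value of the
        # interval ending there (the LCM left derivative)
        assert evaluate_density(d, 0.2) == pytest.approx(10 / 3)
        assert evaluate_density(d, 0.9) == pytest.approx(10 / 21)
        assert evaluate_density(d, 0.0) == pytest.approx(10 / 3)
        assert evaluate_density(d, 1.0) == 0.0

    def test_normalization_arithmetic(self):
        d = MonotoneDensity(knots=[0.0, 0.5, 1.0], heights=[1.6, 0.4])
        assert np.sum(np.asarray(d.heights) * np.diff(d.knots)) == pytest.approx(1.0)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            evaluate_density(UNIFORM_DENSITY, 1.2)


def _triangular():
    """Fine step approximation of f(x) = 2(1-x) exact at interval midpoints."""
    knots = np.linspace(0.0, 1.0, 2001)
    mids = (knots[:-1] + knots[1:]) / 2
    return MonotoneDensity(knots=knots, heights=2 * (1 - mids))


class TestComputeLfdr:
    def test_pure_replicable_mixture_gives_zero_lfdr(self):
        model = FourGroupModel(MixtureParams(0, 0, 0, 1),
                               _triangular(), _triangular())
        res = compute_lfdr(model, paired([0.1, 0.9], [0.2, 0.4]))
        assert np.allclose(res.lfdr, 0.0)

    def test_zero_replicable_weight_gives_unit_lfdr(self):
        model = FourGroupModel(MixtureParams(0.5, 0.25, 0.25, 0),
                               _triangular(), _triangular())
        res = compute_lfdr(model, paired([0.1, 0.9], [0.2, 0.4]))
        assert np.allclose(res.lfdr, 1.0)

    def test_direct_substitution_at_density_value_one(self):
        # f1 = f2 = 2(1-x) equals 1 at x = 0.5, so all four terms weigh 0.25
        model = FourGroupModel(MixtureParams(0.25, 0.25, 0.25, 0.25),
                               lambda x: 2 * (1 - x), lambda x: 2 * (1 - x))
        res = compute_lfdr(model, paired([0.5], [0.5]))
        assert res.lfdr[0] == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_lfdr_componentwise_monotone(self, seed):
        """Under non-increasing non-null densities, Lfdr never decreases
        when both p-values increase."""
        rng = np.random.default_rng(seed)
        model = FourGroupModel(random_mixture_params(rng),
                               random_monotone_density(rng),
                               random_monotone_density(rng))
        a = rng.uniform(size=(20, 2))
        b = np.minimum(a + rng.uniform(size=(20, 2)), 1.0)
        lo = compute_lfdr(model, paired(a[:, 0], a[:, 1])).lfdr
        hi = compute_lfdr(model, paired(b[:, 0], b[:, 1])).lfdr
        assert np.all(lo <= hi + 1e-12)

    def test_mixture_density_integrates_to_one(self, rng):
        model = FourGroupModel(random_mixture_params(rng),
                               random_monotone_density(rng),
                               random_monotone_density(rng))
        # composite midpoint rule on the product step grid is exact here
        k1, k2 = np.asarray(model.f1.knots), np.asarray(model.f2.knots)
        m1 = (k1[:-1] + k1[1:]) / 2
        m2 = (k2[:-1] + k2[1:]) / 2
        f1v = model.f1.evaluate(m1)[:, None]
        f2v = model.f2.evaluate(m2)[None, :]
        xi = model.params
        cell = (xi.xi00 + xi.xi01 * f2v + xi.xi10 * f1v + xi.xi11 * f1v * f2v)
        integral = np.sum(cell * np.diff(k1)[:, None] * np.diff(k2)[None, :])
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestLogLikelihood:
    def test_null_only_model_has_zero_loglik(self):
        model = FourGroupModel(MixtureParams(1, 0, 0, 0),
                               _triangular(), _triangular())
        assert mixture_log_likelihood(model, paired([0.3], [0.7])) == pytest.approx(0.0)

    def test_flat_nonnull_densities_have_zero_loglik(self):
        model = FourGroupModel(MixtureParams(0.25, 0.25, 0.25, 0.25),
                               UNIFORM_DENSITY, UNIFORM_DENSITY)
        assert mixture_log_likelihood(model, paired([0.2], [0.9])) == pytest.approx(0.0)

    def test_matches_hand_evaluated_four_term_sum(self):
        f1 = MonotoneDensity(knots=[0.0, 0.5, 1.0], heights=[1.6, 0.4])
        f2 = MonotoneDensity(knots=[0.0, 0.2, 1.0], heights=[3.0, 0.5])
        xi = MixtureParams(0.4, 0.3, 0.2, 0.1)
        data = paired([0.1, 0.6, 0.45], [0.15, 0.25, 0.8])
        expected = 0.0
        for p1, p2 in zip(data.p1, data.p2):
            a = 1.6 if p1 < 0.5 else 0.4
            b = 3.0 if p2 < 0.2 else 0.5
            expected += math.log(0.4 + 0.3 * b + 0.2 * a + 0.1 * a * b)
        model = FourGroupModel(xi, f1, f2)
        assert mixture_log_likelihood(model, data) == pytest.approx(expected)
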