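import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinekit.cline_models import (
    ClineFit,
    ClineParams,
    FitOptions,
    aicc,
    binomial_loglik,
    cline_value,
    compare_models,
    fit_locus,
    fit_model,
    fit_rse,
    gaussian_loglik,
    polarize,
)

MODEL_I = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.0, pmax=1.0)


def _grid_eval(k, n, x, ends, cs, ws):
    from scipy.special import expit, gammaln
    cc, ww = np.meshgrid(cs, ws, indexing="ij")
    g = expit(4.0 * (x[None, None, :] - cc[..., None]) / ww[..., None])
    p = np.clip(ends[0] + (ends[1] - ends[0]) * g, 1e-6, 1 - 1e-6)
    const = np.sum(gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1))
    ll = const + np.sum(k * np.log(p) + (np.asarray(n) - k) * np.log1p(-p), axis=-1)
    i = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[i]), float(cc[i]), float(ww[i])


def grid_search_loglik(k, n, x, ends, n_grid=101, refine=0):
    """Independent (c, w) grid-search oracle for model I, vectorized.

    ``refine`` adds local re-gridding passes around the coarse optimum so
    the located (c, w) can be compared at fine resolution.
    """
    x = np.asarray(x, dtype=float)
    length = x.max() - x.min()
    cs = np.linspace(x.min() - 0.5 * length, x.min() + 1.5 * length, n_grid)
    ws = np.linspace(1.0, 10.0 * length, n_grid)
    ll, c_star, w_star = _grid_eval(k, n, x, ends, cs, ws)
    dc, dw = cs[1] - cs[0], ws[1] - ws[0]
    for _ in range(refine):
        cs = np.linspace(c_star - dc, c_star + dc, n_grid)
        ws = np.linspace(max(w_star - dw, 1.0), w_star + dw, n_grid)
        ll, c_star, w_star = _grid_eval(k, n, x, ends, cs, ws)
        dc, dw = cs[1] - cs[0], ws[1] - ws[0]
    return ll, c_star, w_star


class TestClineValue:
    def test_centre_is_midpoint(self):
        assert float(cline_value(MODEL_I, np.array([650.0]))[0]) == pytest.approx(0.5)

    def test_quarter_width_south(self):
        v = float(cline_value(MODEL_I, np.array([725.0]))[0])
        assert v == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), rel=1e-12)

    def test_general_midpoint(self):
        p = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        assert float(cline_value(p, np.array([650.0]))[0]) == pytest.approx(0.5)

    def test_stepped_junction_continuity(self):
        p = ClineParams(
            model_id="III", c=650.0, w=300.0, pmin=0.0, pmax=1.0,
            delta_l=100.0, tau_l=0.5, delta_r=120.0, tau_r=0.7,
        )
        for xj in (650.0 - 100.0, 650.0 + 120.0):
            core = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.0, pmax=1.0)
            assert float(cline_value(p, np.array([xj]))[0]) == pytest.approx(
                float(cline_value(core, np.array([xj]))[0]), abs=1e-12
            )
        # the quoted closed form at the left junction
        assert float(cline_value(p, np.array([550.0]))[0]) == pytest.approx(
            1.0 / (1.0 + math.exp(4.0 / 3.0)), rel=1e-12
        )

    def test_null_model_uniform(self):
        p = ClineParams(model_id="NULL", p0=0.42)
        np.testing.assert_allclose(cline_value(p, np.linspace(0, 1400, 5)), 0.42)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            cline_value(ClineParams(model_id="I", c=0, w=0.0, pmin=0, pmax=1), np.array([1.0]))

    @settings(max_examples=40, deadline=None)
    @given(d=st.floats(0.0, 2000.0))
    def test_model_i_symmetry_about_centre(self, d):
        lo = float(cline_value(MODEL_I, np.array([650.0 - d]))[0])
        hi = float(cline_value(MODEL_I, np.array([650.0 + d]))[0])
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        w=st.floats(50, 2000), c=st.floats(0, 1400),
        dl=st.floats(0, 500), tl=st.floats(0.01, 1.0),
        dr=st.floats(0, 500), tr=st.floats(0.01, 1.0),
    )
    def test_monotone_in_x(self, w, c, dl, tl, dr, tr):
        p = ClineParams(
            model_id="IV", c=c, w=w, pmin=0.05, pmax=0.95,
            delta_l=dl, tau_l=tl, delta_r=dr, tau_r=tr,
        )
        vals = np.asarray(cline_value(p, np.linspace(-700, 2100, 200)))
        assert np.all(np.diff(vals) >= -1e-9)

    def test_width_is_inverse_max_slope(self):
        # numerical max slope of the sigmoid equals (pmax - pmin) / w
        p = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        xs = np.linspace(649.0, 651.0, 2001)
        slope = np.max(np.diff(np.asarray(cline_value(p, xs))) / np.diff(xs))
        assert slope == pytest.approx((0.9 - 0.1) / 300.0, rel=1e-6)


class TestLikelihoods:
    def test_binomial_closed_form(self):
        p = ClineParams(model_id="NULL", p0=0.5)
        ll = binomial_loglik(p, [5], [10], [0.0])
        assert ll == pytest.approx(math.log(math.comb(10, 5)) - 10 * math.log(2), rel=1e-12)

    def test_clamp_keeps_loglik_finite(self):
        p = ClineParams(model_id="NULL", p0=1.0)
        assert np.isfinite(binomial_loglik(p, [3], [10], [0.0]))

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            binomial_loglik(ClineParams(model_id="NULL", p0=0.5), [11], [10], [0.0])

    def test_gaussian_perfect_fit_matches_sigma_grid_oracle(self, transect_x):
        p = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        y = np.asarray(cline_value(p, transect_x))
        ll = gaussian_loglik(p, y, transect_x, sigma_floor=1e-4)
        # 1-D grid over sigma: the profiled value must top the grid
        grid = [
            float(np.sum(-0.5 * np.log(2 * np.pi * s**2) - 0.5 * (y - y) ** 2 / s**2))
            for s in np.geomspace(1e-4, 1.0, 400)
        ]
        assert ll >= max(grid) - 1e-9


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-10.0, 2, 12) == pytest.approx(25.333333333, rel=1e-9)

    def test_guards(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 0, 12)
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_always_exceeds_aic(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 8))
            n = int(rng.integers(k + 2, 40))
            ll = float(rng.normal(-20, 5))
            assert aicc(ll, k, n) > -2 * ll + 2 * k


def _fit(model_id, aicc_val, k=2, converged=True):
    return ClineFit(
        params=ClineParams(model_id=model_id, c=650, w=300, pmin=0, pmax=1, p0=0.5),
        loglik=0.0, k=k, aicc=aicc_val, rse=None, converged=converged,
    )


class TestCompareModels:
    def test_evidence_ratio_closed_form(self):
        fits = {"NULL": _fit("NULL", 30.0, k=1), "I": _fit("I", 20.0)}
        comp = compare_models(fits)
        assert comp.evidence_ratio_vs_null == pytest.approx(math.exp(5.0), rel=1e-12)
        assert comp.best_model == "I"

    def test_tie_prefers_fewer_parameters(self):
        fits = {"NULL": _fit("NULL", 30.0, k=1), "I": _fit("I", 20.0, k=2), "II": _fit("II", 20.0, k=4)}
        assert compare_models(fits).best_model == "I"

    def test_null_best_gives_ratio_below_one(self):
        fits = {"NULL": _fit("NULL", 10.0, k=1), "I": _fit("I", 20.0)}
        comp = compare_models(fits)
        assert comp.evidence_ratio_vs_null < 1.0
        assert comp.best_model == "I"

    def test_no_converged_fit_gives_zero_ratio(self):
        fits = {"NULL": _fit("NULL", 10.0, k=1), "I": _fit("I", 20.0, converged=False)}
        comp = compare_models(fits)
        assert comp.best_model is None
        assert comp.evidence_ratio_vs_null == 0.0

    def test_akaike_weights_sum_to_one(self):
        fits = {
            "NULL": _fit("NULL", 25.0, k=1), "I": _fit("I", 20.0),
            "II": _fit("II", 22.0, k=4), "III": _fit("III", 28.0, k=6),
        }
        comp = compare_models(fits)
        assert sum(comp.akaike_weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= w <= 1 for w in comp.akaike_weights.values())


class TestRse:
    def test_perfect_fit_zero(self, transect_x):
        p = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        f = np.asarray(cline_value(p, transect_x))
        assert fit_rse(p, f, transect_x, k_struct=2) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self, transect_x):
        p = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        f = np.asarray(cline_value(p, transect_x)) + 0.1
        assert fit_rse(p, f, transect_x, k_struct=2) == pytest.approx(0.1 * math.sqrt(12 / 10), rel=1e-9)

    def test_matches_direct_residual_computation(self, transect_x, rng):
        p = ClineParams(model_id="II", c=700.0, w=250.0, pmin=0.2, pmax=0.8)
        f = np.asarray(cline_value(p, transect_x)) + rng.normal(0, 0.05, len(transect_x))
        expected = math.sqrt(sum((f - np.asarray(cline_value(p, transect_x))) ** 2) / (12 - 4))
        assert fit_rse(p, f, transect_x, k_struct=4) == pytest.approx(expected, rel=1e-12)

    def test_undefined_without_residual_dof(self, transect_x):
        p = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        assert fit_rse(p, np.zeros(2), transect_x[:2], k_struct=2) is None


class TestFitting:
    def test_noiseless_recovery_matches_grid_oracle(self, transect_x):
        truth = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        n = np.full(12, 30.0)
        k = np.asarray(cline_value(truth, transect_x)) * n  # expected counts
        fit = fit_model(k=k, n=n, x=transect_x, model_id="I", options=FitOptions(seed=1))
        ends = (k[0] / n[0], k[-1] / n[-1])
        _, c_star, w_star = grid_search_loglik(k, n, transect_x, ends, refine=3)
        assert fit.params.c == pytest.approx(c_star, abs=5.0)
        assert fit.params.w == pytest.approx(w_star, rel=0.05)
        assert fit.converged

    def test_optimizer_never_below_grid_oracle(self, transect_x):
        rng = np.random.default_rng(9)
        n = np.full(12, 30)
        for _ in range(5):
            truth = ClineParams(
                model_id="I", c=rng.uniform(400, 900), w=rng.uniform(100, 600),
                pmin=0.05, pmax=0.95,
            )
            k = rng.binomial(30, np.asarray(cline_value(truth, transect_x)))
            fit = fit_model(k=k, n=n, x=transect_x, model_id="I", options=FitOptions(seed=2))
            ends = (k[0] / 30, k[-1] / 30)
            ll_grid, _, _ = grid_search_loglik(k, n, transect_x, ends)
            assert fit.loglik >= ll_grid - 1e-3

    def test_strictly_linear_gradient_always_flagged(self, transect_x):
        # exact linear frequency profile: no cline model can beat the line
        n = np.full(12, 30.0)
        p = np.clip(0.1 + 0.8 * transect_x / 1400.0, 0.02, 0.98)
        comp = fit_locus(k=p * n, n=n, x=transect_x, options=FitOptions(seed=3))
        assert comp.linear_gradient

    def test_sampled_linear_gradient_mostly_flagged(self, transect_x):
        # with binomial noise the exclusion is statistical, not exact
        n = np.full(12, 30)
        p = np.clip(0.1 + 0.8 * transect_x / 1400.0, 0.02, 0.98)
        rng = np.random.default_rng(3)
        flagged = 0
        for _ in range(10):
            comp = fit_locus(k=rng.binomial(30, p), n=n, x=transect_x, options=FitOptions(seed=3))
            best = comp.best_fit
            if comp.linear_gradient or best is None or not best.converged:
                flagged += 1
        assert flagged >= 8

    def test_polarity_flip_detected_and_recorded(self, transect_x):
        truth = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.9, pmax=0.1)  # north-high
        n = np.full(12, 40)
        rng = np.random.default_rng(8)
        k = rng.binomial(40, np.asarray(cline_value(truth, transect_x)))
        k_flip, flipped = polarize(k, n, transect_x)
        assert flipped
        np.testing.assert_array_equal(k_flip, n - k)
        comp = fit_locus(k=k, n=n, x=transect_x, options=FitOptions(seed=4), models=("I", "II"))
        assert comp.polarity == "flipped"
        assert comp.best_model in ("I", "II")

    def test_too_few_populations_rejected(self):
        x = np.linspace(0, 100, 3)
        with pytest.raises(ValueError):
            fit_model(k=[1, 2, 3], n=[10, 10, 10], x=x, model_id="II", options=FitOptions(seed=0))

    def test_binomial_recovery_under_sampling_noise(self, transect_x):
        # 20 diploids/population, free-end sigmoid: medians over 100 loci near truth
        truth = ClineParams(model_id="I", c=650.0, w=300.0, pmin=0.1, pmax=0.9)
        p = np.asarray(cline_value(truth, transect_x))
        n = np.full(12, 40)
        rng = np.random.default_rng(6)
        cs, ws = [], []
        for _ in range(100):
            fit = fit_model(
                k=rng.binomial(40, p), n=n, x=transect_x, model_id="II", options=FitOptions(seed=6)
            )
            cs.append(fit.params.c)
            ws.append(fit.params.w)
        assert abs(np.median(cs) - 650) <= 50
        assert np.median(np.abs(np.array(ws) - 300) / 300) <= 0.25
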