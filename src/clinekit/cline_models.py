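"""Szymura–Barton geographic cline models and maximum-likelihood fitting.

The cline describes allele frequency along a one-dimensional transect
coordinate x (km from the northern reference point) as

    P(x) = pmin + (pmax - pmin) * g(x)

with the sigmoid core g(x) = 1 / (1 + exp(-4 (x - c) / w)); c is the
cline centre (position of steepest change) and w the width, defined as
the inverse of the maximum slope of g, so the maximum slope of P is
(pmax - pmin) / w. Stepped variants replace the core with exponential
tails beyond distances deltaL/deltaR from the centre, with slope ratios
tauL/tauR in [0, 1]; tails join the core continuously.

Model ladder (free parameters under the binomial likelihood):

    NULL   p0 only (uniform frequency; the no-cline reference)   k = 1
    LINEAR a + b*x, clipped to [eps, 1-eps] (diagnostic model)   k = 2
    I      c, w; pmin/pmax fixed (observed transect ends or 0/1) k = 2
    II     c, w, pmin, pmax                                      k = 4
    III    model I core + deltaL, tauL, deltaR, tauR             k = 6
    IV     model II + tails                                      k = 8

Counts are modelled as k_i ~ Binomial(n_i, P(x_i)) per population; a
Gaussian likelihood with profiled noise variance (one extra parameter)
serves continuous responses such as normalized environmental variables.
Fitting is bounded multistart maximum likelihood: a seeded space-filling
(Latin hypercube) design of candidate starts, augmented with moment-based
and warm starts, is screened by likelihood and the best few are polished
with L-BFGS-B. Model choice uses AICc with n = number of populations, and
support against the uniform null is summarized by the evidence ratio
exp((AICc_null - AICc_best) / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import qmc

CLINE_MODELS = ("I", "II", "III", "IV")
ALL_MODELS = ("NULL", "LINEAR") + CLINE_MODELS

#: structural (shape) parameter count per model; Gaussian likelihood adds 1 for sigma
MODEL_K = {"NULL": 1, "LINEAR": 2, "I": 2, "II": 4, "III": 6, "IV": 8}


@dataclass
class ClineParams:
    """Parameter bundle for one cline model (unused fields stay None)."""

    model_id: str
    c: float | None = None
    w: float | None = None
    pmin: float | None = None
    pmax: float | None = None
    delta_l: float | None = None
    tau_l: float | None = None
    delta_r: float | None = None
    tau_r: float | None = None
    p0: float | None = None       # NULL model
    slope: float | None = None    # LINEAR model: P(x) = p0 + slope * x


@dataclass
class FitOptions:
    """Tunable knobs of the fitting procedure (all deterministic given seed)."""

    likelihood: str = "binomial"        # "binomial" | "gaussian"
    model1_ends: str = "observed"       # "observed" | "unit": how model I/III fix pmin/pmax
    n_starts: int = 20                  # space-filling starts screened per model
    n_polish: int = 2                   # best starts refined with L-BFGS-B
    seed: int = 0
    eps: float = 1e-6                   # frequency clamp
    sigma_floor: float = 1e-4           # Gaussian likelihood noise floor
    w_min: float = 1.0                  # km
    w_max_factor: float = 10.0          # w upper bound = factor * transect length
    opt_tol: float = 1e-8
    linear_aicc_margin: float = 2.0     # cline must beat LINEAR by this much AICc


@dataclass
class ClineFit:
    """One fitted model at one locus."""

    params: ClineParams
    loglik: float
    k: int
    aicc: float
    rse: float | None
    converged: bool
    polarity: str = "as-is"             # "as-is" | "flipped"


@dataclass
class ModelComparison:
    """AICc comparison of the cline models against the uniform null."""

    fits: dict[str, ClineFit]
    best_model: str | None
    akaike_weights: dict[str, float]
    evidence_ratio_vs_null: float
    linear_gradient: bool = False
    polarity: str = "as-is"

    @property
    def best_fit(self) -> ClineFit | None:
        return self.fits.get(self.best_model) if self.best_model else None


# ---------------------------------------------------------------------------
# model evaluation

def cline_value(params: ClineParams, x) -> np.ndarray:
    """Predicted frequency (or normalized response) at transect position x (km)."""
    x = np.asarray(x, dtype=float)
    m = params.model_id
    if m == "NULL":
        return np.full_like(x, float(params.p0))
    if m == "LINEAR":
        return params.p0 + params.slope * x
    c, w = params.c, params.w
    if w is None or w <= 0:
        raise ValueError("cline width w must be positive")
    g = expit(4.0 * (x - c) / w)
    if m in ("III", "IV"):
        dl, tl = params.delta_l, params.tau_l
        dr, tr = params.delta_r, params.tau_r
        left = x <= c - dl
        right = x >= c + dr
        if np.any(left):
            xl = x[left]
            amp = expit(-4.0 * dl / w)
            rate = 4.0 * tl / w * expit(4.0 * dl / w)
            g[left] = amp * np.exp(rate * (xl - c + dl))
        if np.any(right):
            xr = x[right]
            amp = expit(-4.0 * dr / w)
            rate = 4.0 * tr / w * expit(4.0 * dr / w)
            g[right] = 1.0 - amp * np.exp(-rate * (xr - c - dr))
    return params.pmin + (params.pmax - params.pmin) * g


def binomial_loglik(params: ClineParams, k, n, x, eps: float = 1e-6) -> float:
    """Binomial log-likelihood of per-population counts under the cline.

    Includes the log binomial coefficient, so values are absolute (the
    constant cancels in every likelihood-ratio or AICc comparison).
    Predicted frequencies are clamped to [eps, 1 - eps].
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k > n):
        raise ValueError("counts k cannot exceed totals n")
    p = np.clip(cline_value(params, x), eps, 1.0 - eps)
    return float(
        np.sum(
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(p) + (n - k) * np.log1p(-p)
        )
    )


def gaussian_loglik(params: ClineParams, y, x, sigma_floor: float = 1e-4) -> float:
    """Gaussian log-likelihood with the noise s.d. profiled out by MLE.

    sigma-hat^2 = mean squared residual, floored at ``sigma_floor**2`` so a
    perfect fit stays finite. Used for continuous responses (environmental
    variables) in place of the binomial count model.
    """
    y = np.asarray(y, dtype=float)
    r = y - cline_value(params, x)
    m = len(y)
    s2 = max(float(np.mean(r**2)), sigma_floor**2)
    return float(-0.5 * m * math.log(2.0 * math.pi * s2) - 0.5 * np.sum(r**2) / s2)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 ll + 2k + 2k(k+1)/(n-k-1).

    ``n`` is the number of response units (populations on the transect).
    """
    if k < 1:
        raise ValueError("parameter count k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_rse(params: ClineParams, freqs, x, k_struct: int) -> float | None:
    """Residual standard error between observed and fitted frequencies.

    sqrt(sum (f_i - P(x_i))^2 / (n_pops - k)); None when there are no
    residual degrees of freedom.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_pops = len(freqs)
    if n_pops <= k_struct:
        return None
    resid = freqs - cline_value(params, x)
    return float(np.sqrt(np.sum(resid**2) / (n_pops - k_struct)))


# ---------------------------------------------------------------------------
# fitting

def _free_param_spec(model_id: str, x: np.ndarray):
    """(names, lower bounds, upper bounds) of the free parameters."""
    x0, x1 = float(np.min(x)), float(np.max(x))
    length = x1 - x0
    c_lo, c_hi = x0 - 0.5 * length, x0 + 1.5 * length
    spec = {
        "LINEAR": (["p0", "slope"], [0.0, -2.0 / max(length, 1.0)], [1.0, 2.0 / max(length, 1.0)]),
        "I": (["c", "w"], [c_lo, None], [c_hi, None]),
        "II": (["c", "w", "pmin", "pmax"], [c_lo, None, 0.0, 0.0], [c_hi, None, 1.0, 1.0]),
        "III": (
            ["c", "w", "delta_l", "tau_l", "delta_r", "tau_r"],
            [c_lo, None, 0.0, 0.0, 0.0, 0.0],
            [c_hi, None, length, 1.0, length, 1.0],
        ),
        "IV": (
            ["c", "w", "pmin", "pmax", "delta_l", "tau_l", "delta_r", "tau_r"],
            [c_lo, None, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [c_hi, None, 1.0, 1.0, length, 1.0, length, 1.0],
        ),
    }
    return spec[model_id]


def _vector_to_params(model_id: str, vec, fixed_ends: tuple[float, float] | None) -> ClineParams:
    names, _, _ = _free_param_spec(model_id, np.array([0.0, 1.0]))
    kw = dict(zip(names, (float(v) for v in vec)))
    p = ClineParams(model_id=model_id, **kw)
    if model_id in ("I", "III"):
        p.pmin, p.pmax = fixed_ends
    return p


def _fast_predict(model_id: str, vec: np.ndarray, x: np.ndarray, fixed_ends) -> np.ndarray:
    """Vector-parameter model evaluation used in the optimizer hot loop.

    Mirrors :func:`cline_value` exactly, bypassing ClineParams construction.
    """
    if model_id == "LINEAR":
        return vec[0] + vec[1] * x
    c, w = vec[0], vec[1]
    if model_id == "II":
        pmin, pmax = vec[2], vec[3]
    elif model_id == "IV":
        pmin, pmax = vec[2], vec[3]
    else:
        pmin, pmax = fixed_ends
    g = expit(4.0 * (x - c) / w)
    if model_id in ("III", "IV"):
        off = 2 if model_id == "III" else 4
        dl, tl, dr, tr = vec[off], vec[off + 1], vec[off + 2], vec[off + 3]
        left = x <= c - dl
        right = x >= c + dr
        if left.any():
            amp = expit(-4.0 * dl / w)
            rate = 4.0 * tl / w * expit(4.0 * dl / w)
            g[left] = amp * np.exp(rate * (x[left] - c + dl))
        if right.any():
            amp = expit(-4.0 * dr / w)
            rate = 4.0 * tr / w * expit(4.0 * dr / w)
            g[right] = 1.0 - amp * np.exp(-rate * (x[right] - c - dr))
    return pmin + (pmax - pmin) * g


def _moment_start(x: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Heuristic (c, w) from the steepest observed frequency change."""
    order = np.argsort(x)
    xs, fs = x[order], f[order]
    df = np.diff(fs)
    dx = np.diff(xs)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(dx > 0, df / dx, 0.0)
    i = int(np.argmax(np.abs(slopes)))
    c0 = 0.5 * (xs[i] + xs[i + 1])
    span = abs(fs[-1] - fs[0])
    smax = abs(slopes[i])
    w0 = span / smax if smax > 0 else (xs[-1] - xs[0])
    return c0, float(np.clip(w0, 1.0, 10 * (xs[-1] - xs[0])))


def fit_model(
    k=None,
    n=None,
    x=None,
    model_id: str = "I",
    options: FitOptions | None = None,
    y=None,
    warm_starts: list[ClineParams] | None = None,
) -> ClineFit:
    """Fit one cline model by bounded multistart maximum likelihood.

    For the binomial likelihood pass per-population counts ``k``/``n``;
    for the Gaussian likelihood pass the continuous response ``y``.
    ``warm_starts`` seeds the start list with parameter vectors from
    simpler already-fitted models.

    The fit is flagged ``converged=False`` when the optimizer fails or the
    width lands on its upper bound (the signature of a gradient with no
    sharp transition); such fits are retained but never win classification.
    """
    opt = options or FitOptions()
    x = np.asarray(x, dtype=float)
    n_pops = len(x)
    if opt.likelihood == "binomial":
        k = np.asarray(k, dtype=float)
        n = np.asarray(n, dtype=float)
        freqs = k / n
        log_binom = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
        eps = opt.eps
        def ll(params):
            return binomial_loglik(params, k, n, x, eps=eps)
        def fast_ll(model_id, vec, fixed_ends):
            p = np.clip(_fast_predict(model_id, vec, x, fixed_ends), eps, 1.0 - eps)
            return log_binom + float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    elif opt.likelihood == "gaussian":
        freqs = np.asarray(y, dtype=float)
        sf2 = opt.sigma_floor**2
        m_obs = len(freqs)
        def ll(params):
            return gaussian_loglik(params, freqs, x, sigma_floor=opt.sigma_floor)
        def fast_ll(model_id, vec, fixed_ends):
            r = freqs - _fast_predict(model_id, vec, x, fixed_ends)
            ssr = float(np.sum(r * r))
            s2 = max(ssr / m_obs, sf2)
            return -0.5 * m_obs * math.log(2.0 * math.pi * s2) - 0.5 * ssr / s2
    else:
        raise ValueError(f"unknown likelihood {opt.likelihood!r}")

    k_struct = MODEL_K[model_id]
    k_free = k_struct + (1 if opt.likelihood == "gaussian" else 0)
    if n_pops < k_struct + 1:
        raise ValueError(f"model {model_id} needs at least {k_struct + 1} populations, got {n_pops}")

    length = float(np.max(x) - np.min(x))
    w_hi = opt.w_max_factor * length

    if model_id == "NULL":
        # closed-form MLE of the uniform model
        if opt.likelihood == "binomial":
            p0 = float(np.clip(k.sum() / n.sum(), opt.eps, 1 - opt.eps))
        else:
            p0 = float(np.mean(freqs))
        params = ClineParams(model_id="NULL", p0=p0)
        lval = ll(params)
        return ClineFit(
            params=params, loglik=lval, k=k_free,
            aicc=aicc(lval, k_free, n_pops),
            rse=fit_rse(params, freqs, x, k_struct), converged=True,
        )

    fixed_ends = None
    if model_id in ("I", "III"):
        if opt.model1_ends == "observed":
            fixed_ends = (float(freqs[np.argmin(x)]), float(freqs[np.argmax(x)]))
        else:
            fixed_ends = (0.0, 1.0)

    names, lo, hi = _free_param_spec(model_id, x)
    lo = [w_hi * 0 + opt.w_min if b is None else b for b in lo]
    hi = [w_hi if b is None else b for b in hi]
    lo, hi = np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)
    dim = len(names)

    # space-filling screening design (seeded), plus heuristic/warm starts
    sampler = qmc.LatinHypercube(d=dim, seed=opt.seed)
    starts = qmc.scale(sampler.random(max(opt.n_starts, 4)), lo, hi)
    extras = []
    c0, w0 = _moment_start(x, freqs)
    base = {"c": c0, "w": w0, "pmin": float(np.min(freqs)), "pmax": float(np.max(freqs)),
            "delta_l": length / 4, "tau_l": 0.5, "delta_r": length / 4, "tau_r": 0.5,
            "p0": float(np.mean(freqs)),
            "slope": float(np.polyfit(x, freqs, 1)[0]) if model_id == "LINEAR" else 0.0}
    extras.append([base[nm] for nm in names])
    for wp in warm_starts or []:
        vec = []
        for nm in names:
            v = getattr(wp, nm, None)
            vec.append(base[nm] if v is None else v)
        extras.append(vec)
    starts = np.vstack([starts, np.clip(np.asarray(extras, dtype=float), lo, hi)])

    def neg(vec):
        return -fast_ll(model_id, vec, fixed_ends)

    screened = np.array([neg(s) for s in starts])
    order = np.argsort(screened)
    best_val = np.inf
    best_vec = starts[order[0]]
    any_success = False
    for idx in order[: max(opt.n_polish, 1)]:
        res = minimize(
            neg, starts[idx], method="L-BFGS-B",
            bounds=list(zip(lo, hi)), options={"ftol": opt.opt_tol, "maxiter": 200},
        )
        if res.fun < best_val:
            best_val, best_vec = res.fun, res.x
            any_success = res.success or any_success
        elif res.success:
            any_success = True

    params = _vector_to_params(model_id, best_vec, fixed_ends)
    lval = -float(best_val)
    w_at_bound = params.w is not None and params.w >= 0.999 * w_hi
    converged = bool(any_success) and not w_at_bound
    try:
        a = aicc(lval, k_free, n_pops)
    except ValueError:
        a = math.inf
        converged = False
    return ClineFit(
        params=params, loglik=lval, k=k_free, aicc=a,
        rse=fit_rse(params, freqs, x, k_struct), converged=converged,
    )


def compare_models(
    fits: dict[str, ClineFit],
    linear_aicc_margin: float = 2.0,
) -> ModelComparison:
    """Select the best cline model by AICc and weigh it against the null.

    The best model is the converged cline fit (I-IV) with the lowest AICc;
    exact ties go to the model with fewer parameters. Akaike weights are
    computed over the null plus all converged cline fits. The evidence
    ratio against the uniform null is exp((AICc_null - AICc_best)/2) — the
    pairwise weight ratio — and is 0 by convention when no cline model
    converged. If a LINEAR diagnostic fit is present and the best cline
    model fails to beat it by more than ``linear_aicc_margin`` AICc units,
    the locus is flagged as a linear gradient (no sharp transition) and is
    excluded from clinal classification.
    """
    if "NULL" not in fits:
        raise ValueError("comparison requires a NULL fit")
    null_fit = fits["NULL"]
    candidates = {
        m: f for m, f in fits.items()
        if m in CLINE_MODELS and f.converged and math.isfinite(f.aicc)
    }
    if not candidates:
        weights = {"NULL": 1.0}
        return ModelComparison(
            fits=fits, best_model=None, akaike_weights=weights,
            evidence_ratio_vs_null=0.0,
            linear_gradient="LINEAR" in fits,
            polarity=null_fit.polarity,
        )
    best_model = min(candidates, key=lambda m: (candidates[m].aicc, MODEL_K[m]))
    best = candidates[best_model]

    compared = {"NULL": null_fit, **candidates}
    a_min = min(f.aicc for f in compared.values())
    raw = {m: math.exp(-(f.aicc - a_min) / 2.0) for m, f in compared.items()}
    tot = sum(raw.values())
    weights = {m: v / tot for m, v in raw.items()}

    evidence = math.exp((null_fit.aicc - best.aicc) / 2.0)
    linear = False
    if "LINEAR" in fits and math.isfinite(fits["LINEAR"].aicc):
        linear = fits["LINEAR"].aicc <= best.aicc + linear_aicc_margin
    return ModelComparison(
        fits=fits, best_model=best_model, akaike_weights=weights,
        evidence_ratio_vs_null=evidence, linear_gradient=linear,
        polarity=best.polarity,
    )


def polarize(k: np.ndarray, n: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip the focal allele so the southern transect half has the higher mean frequency.

    Returns (possibly flipped) counts and whether a flip occurred; the flip
    is recorded on fits and undone in reports.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(k, dtype=float) / np.asarray(n, dtype=float)
    mid = np.median(x)
    north = f[x <= mid].mean()
    south = f[x > mid].mean()
    if north > south:
        return np.asarray(n) - np.asarray(k), True
    return np.asarray(k), False


def fit_locus(
    k=None,
    n=None,
    x=None,
    y=None,
    options: FitOptions | None = None,
    models: tuple[str, ...] = CLINE_MODELS,
) -> ModelComparison:
    """Fit NULL, LINEAR and the requested cline models at one locus and compare.

    Binomial path: pass ``k``/``n`` counts; the locus is first re-polarized
    so frequency increases southward. Gaussian path (environmental
    responses): pass ``y``.
    """
    opt = options or FitOptions()
    flipped = False
    if opt.likelihood == "binomial":
        k, flipped = polarize(k, n, x)
    fits: dict[str, ClineFit] = {}
    warm: list[ClineParams] = []
    for m in ("NULL", "LINEAR") + tuple(models):
        try:
            f = fit_model(k=k, n=n, x=x, y=y, model_id=m, options=opt, warm_starts=warm)
        except ValueError:
            continue
        f.polarity = "flipped" if flipped else "as-is"
        fits[m] = f
        if m in CLINE_MODELS and f.converged:
            warm.append(f.params)
    comp = compare_models(fits, linear_aicc_margin=opt.linear_aicc_margin)
    comp.polarity = "flipped" if flipped else "as-is"
    return comp
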