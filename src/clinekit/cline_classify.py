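"""Clinal-allele classification, candidate enrichment, environmental clines
and selection-coefficient estimation.

A locus is *clinal* when its evidence ratio (best cline model vs the
uniform null, exp(dAICc/2)) strictly exceeds the 99th percentile of the
evidence-ratio distribution over all successfully fitted loci — an
outlier rule rather than a fixed threshold, so roughly 1% of loci
qualify by construction. Externally derived selection candidates (genome
scans, genotype-environment associations) are tested for enrichment of
clinal alleles with an upper-tail hypergeometric test against a
background matched on the fitted end-frequency difference. For clinal
candidates, cline width w and neighbourhood size N_S combine into the
migration-selection-balance selection intensity s = N_S / w**2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from clinekit.cline_models import FitOptions, ModelComparison, fit_locus

logger = logging.getLogger(__name__)


@dataclass
class ClinalCall:
    """Per-locus classification result."""

    locus_id: str
    evidence_ratio: float
    is_clinal: bool
    threshold_used: float
    delta_p: float | None       # |fitted pmax - pmin| of the best model
    best_model: str | None
    converged: bool
    linear_gradient: bool


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one candidate set for clinal alleles."""

    candidate_set_id: str
    n_background: int
    n_background_clinal: int
    n_candidates: int
    n_candidates_clinal: int
    p_value: float
    p_adjusted: float


def classify_clinal(
    comparisons: dict[str, ModelComparison],
    percentile: float = 99.0,
) -> list[ClinalCall]:
    """Label loci clinal by the empirical evidence-ratio percentile rule.

    The threshold is the ``percentile`` (default 99th, linear
    interpolation) of evidence ratios over loci with a converged,
    non-linear-gradient best fit; only such loci can be clinal, and only
    with evidence ratio strictly above the threshold.
    """
    fitted = {lid: c for lid, c in comparisons.items() if c.best_model is not None}
    if not fitted:
        warnings.warn("no converged cline fits; clinal set is empty")
        threshold = np.inf
    else:
        if len(fitted) < 100:
            warnings.warn(
                f"only {len(fitted)} fitted loci; the {percentile}th-percentile "
                "evidence-ratio threshold is unreliable"
            )
        ratios = np.array([c.evidence_ratio_vs_null for c in fitted.values()])
        threshold = float(np.percentile(ratios, percentile))

    calls = []
    for lid, c in comparisons.items():
        best = c.best_fit
        delta_p = None
        if best is not None and best.params.pmin is not None:
            delta_p = abs(best.params.pmax - best.params.pmin)
        is_clinal = (
            lid in fitted
            and not c.linear_gradient
            and c.evidence_ratio_vs_null > threshold
        )
        calls.append(
            ClinalCall(
                locus_id=lid,
                evidence_ratio=c.evidence_ratio_vs_null,
                is_clinal=bool(is_clinal),
                threshold_used=threshold,
                delta_p=delta_p,
                best_model=c.best_model,
                converged=c.best_model is not None,
                linear_gradient=c.linear_gradient,
            )
        )
    return calls


def calls_from_frame(df: pd.DataFrame) -> list[ClinalCall]:
    """Rebuild per-locus calls from a clinal-calls TSV (stage rerun support)."""
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            ClinalCall(
                locus_id=str(row.locus_id),
                evidence_ratio=float(row.evidence_ratio),
                is_clinal=bool(row.is_clinal),
                threshold_used=float(row.threshold_used),
                delta_p=None if pd.isna(row.delta_p) else float(row.delta_p),
                best_model=None if pd.isna(row.best_model) else str(row.best_model),
                converged=bool(row.converged),
                linear_gradient=bool(row.linear_gradient),
            )
        )
    return calls


def classify_frame(clines: pd.DataFrame, percentile: float = 99.0) -> pd.DataFrame:
    """Evidence-ratio classification straight from a clines TSV.

    Mirrors :func:`classify_clinal` on the flat-file representation:
    threshold over rows with a converged best model, strict exceedance,
    linear-gradient rows never clinal.
    """
    fitted = clines["best_model"].isin(("I", "II", "III", "IV"))
    if fitted.sum() == 0:
        warnings.warn("no converged cline fits; clinal set is empty")
        threshold = np.inf
    else:
        if fitted.sum() < 100:
            warnings.warn("fewer than 100 fitted loci; percentile threshold unreliable")
        threshold = float(np.percentile(clines.loc[fitted, "evidence_ratio"], percentile))
    out = pd.DataFrame({
        "locus_id": clines["locus_id"],
        "evidence_ratio": clines["evidence_ratio"],
        "is_clinal": fitted & ~clines["linear_gradient"] & (clines["evidence_ratio"] > threshold),
        "threshold_used": threshold,
        "delta_p": (clines["pmax"] - clines["pmin"]).abs(),
        "best_model": clines["best_model"].where(fitted, None),
        "converged": fitted,
        "linear_gradient": clines["linear_gradient"],
    })
    return out


def matched_background(
    candidates: set[str],
    calls: list[ClinalCall],
    bin_width: float = 0.05,
) -> set[str]:
    """Loci with end-frequency differences similar to the candidates'.

    Each candidate contributes every fitted locus whose ``delta_p`` falls
    in the same ``bin_width``-wide bin (bins [0, bw), [bw, 2bw), ...); the
    background is the union over candidates, so overlapping bins are never
    double-counted. Candidates without a fitted ``delta_p`` are dropped
    with a warning.
    """
    by_id = {c.locus_id: c for c in calls}
    bins_needed = set()
    for cand in candidates:
        call = by_id.get(cand)
        if call is None or call.delta_p is None:
            warnings.warn(f"candidate {cand} has no fitted cline; dropped from matching")
            continue
        bins_needed.add(int(call.delta_p / bin_width))
    return {
        c.locus_id
        for c in calls
        if c.delta_p is not None and int(c.delta_p / bin_width) in bins_needed
    }


def enrichment_test(
    candidates: set[str],
    clinal: set[str],
    background: set[str],
    n_tests: int = 1,
    candidate_set_id: str = "candidates",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test for clinal-allele enrichment.

    With N = |background|, K clinal loci in the background and n
    candidates (a subset of the background), the p-value is
    P(X >= observed) for X ~ Hypergeom(N, K, n). Bonferroni adjustment
    multiplies by ``n_tests`` (the number of candidate sets tested
    together), capped at 1.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the matched background")
    N = len(background)
    K = len(clinal & background)
    n = len(candidates)
    obs = len(clinal & candidates)
    p = float(hypergeom.sf(obs - 1, N, K, n))
    # sf underflows to 0 for extreme enrichment at large N; keep p in (0, 1]
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentResult(
        candidate_set_id=candidate_set_id,
        n_background=N,
        n_background_clinal=K,
        n_candidates=n,
        n_candidates_clinal=obs,
        p_value=p,
        p_adjusted=min(1.0, n_tests * p),
    )


def run_enrichment(
    candidate_sets: dict[str, set[str]],
    calls: list[ClinalCall],
    bin_width: float = 0.05,
) -> list[EnrichmentResult]:
    """Frequency-matched enrichment for several candidate sets at once.

    The Bonferroni family is the set of tests run in this invocation.
    """
    clinal = {c.locus_id for c in calls if c.is_clinal}
    fitted = {c.locus_id for c in calls if c.delta_p is not None}
    m = len(candidate_sets)
    results = []
    for set_id, cand in candidate_sets.items():
        usable = cand & fitted
        if not usable:
            warnings.warn(f"candidate set {set_id}: no fitted candidates; skipped")
            continue
        bg = matched_background(usable, calls, bin_width=bin_width) | usable
        results.append(
            enrichment_test(usable, clinal, bg, n_tests=m, candidate_set_id=set_id)
        )
    return results


def fit_env_clines(
    env,
    geometry,
    options: FitOptions | None = None,
) -> dict[str, ModelComparison]:
    """Fit the cline-model ladder to each normalized environmental variable.

    Uses the Gaussian likelihood (profiled noise s.d.) on the [0, 1]
    normalized values with the same transect predictor as the allele
    clines. Constant variables were already excluded at read time.
    """
    opt = options or FitOptions()
    if opt.likelihood != "gaussian":
        opt = FitOptions(**{**opt.__dict__, "likelihood": "gaussian"})
    x = np.asarray(geometry["distance_km"], dtype=float)
    pops = list(geometry["population_id"])
    out = {}
    for var in env.normalized.columns:
        y = env.normalized.loc[pops, var].to_numpy(dtype=float)
        out[var] = fit_locus(y=y, x=x, options=opt)
    return out


def selection_coefficient(n_s: float, w: float) -> float:
    """Selection intensity from migration-selection balance, s = N_S / w**2.

    Follows from cline width scaling as w ~ sigma / sqrt(s) with
    neighbourhood size standing in for sigma**2; ``w`` in km, ``n_s``
    unitless, so s is a per-generation intensity.
    """
    if n_s is None or not np.isfinite(n_s) or n_s <= 0:
        raise ValueError("selection coefficient needs a positive neighbourhood size")
    if w is None or w <= 0:
        raise ValueError("selection coefficient needs a positive cline width")
    return n_s / w**2


def selection_table(
    calls: list[ClinalCall],
    comparisons: dict[str, ModelComparison],
    n_s: float | None,
    candidates: set[str] | None = None,
) -> pd.DataFrame:
    """Per-locus selection coefficients for clinal (and optionally candidate) loci.

    When the IBD slope was non-positive, N_S is undefined and every s is
    missing with an explanatory status column.
    """
    rows = []
    for call in calls:
        if not call.is_clinal:
            continue
        if candidates is not None and call.locus_id not in candidates:
            continue
        best = comparisons[call.locus_id].best_fit
        w = best.params.w
        if n_s is None or not np.isfinite(n_s) or n_s <= 0:
            rows.append((call.locus_id, call.best_model, w, np.nan, np.nan, "N_S undefined (non-positive IBD slope)"))
        else:
            rows.append((call.locus_id, call.best_model, w, n_s, selection_coefficient(n_s, w), "ok"))
    return pd.DataFrame(
        rows, columns=["locus_id", "best_model", "w_km", "n_s", "s", "status"]
    )
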