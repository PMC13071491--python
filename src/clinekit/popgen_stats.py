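"""Weir–Cockerham F_ST from per-population allele counts.

The estimator is the moments (ANOVA) theta of Weir & Cockerham (1984) in
its allele-count form: because the count matrix retains allele copies but
not genotypes, alleles within populations are treated as independently
sampled (random union of gametes), which collapses the three-level
genotype ANOVA to two levels. Writing, for locus l with r populations,

    MSP = sum_i n_i (p_i - pbar)^2 / (r - 1)          (among populations)
    MSG = sum_i n_i p_i q_i / sum_i (n_i - 1)         (within populations)
    n_c = (N - sum_i n_i^2 / N) / (r - 1),  N = sum_i n_i

the variance components are a = (MSP - MSG) / n_c among populations and
c = MSG within, and theta = a / (a + c). Multilocus and pairwise values
combine loci as a ratio of summed components (ratio of averages), the
standard Weir–Cockerham combination. Negative estimates are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class LocusFst:
    """Per-locus Weir–Cockerham variance components and theta.

    ``b`` (the among-individual-within-population component of the full
    genotype-level estimator) is identically zero in this allele-count
    form and kept for interface compatibility. ``theta`` is None when the
    locus is monomorphic across all populations considered.
    """

    locus_id: str
    a: float
    b: float
    c: float
    theta: float | None


def _components(k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (a, c) components for loci x populations count arrays."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    r = k.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    big_n = n.sum(axis=1)
    pbar = k.sum(axis=1) / big_n
    p = k / n
    msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (n * p * (1 - p)).sum(axis=1) / (n - 1).sum(axis=1)
    n_c = (big_n - (n**2).sum(axis=1) / big_n) / (r - 1)
    a = (msp - msg) / n_c
    return a, msg


def wc_fst_locus(k, n, locus_id: str = "") -> LocusFst:
    """Weir–Cockerham theta for one locus over >= 2 populations.

    ``k``/``n`` are focal-allele and total copy counts per population;
    every population must contribute at least 2 copies. A locus that is
    monomorphic across all populations has no defined theta (recorded as
    ``None``).
    """
    k = np.atleast_2d(np.asarray(k, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if np.any(n < 2):
        raise ValueError("wc_fst_locus requires n_i >= 2 in every population")
    a, c = _components(k, n)
    a, c = float(a[0]), float(c[0])
    denom = a + c
    theta = a / denom if denom > 0 else None
    return LocusFst(locus_id=locus_id, a=a, b=0.0, c=c, theta=theta)


def pairwise_fst_matrix(counts, geometry=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Multilocus pairwise F_ST between all population pairs.

    For each pair, loci where either population has fewer than 2 sampled
    copies are skipped, and per-locus components are summed over the
    remaining loci: theta_pair = sum(a) / sum(a + c). Monomorphic loci
    contribute zero to both sums and therefore never change the estimate.
    Pairs with no informative locus get NaN.

    Returns the symmetric matrix (ordered like ``counts.populations``) and
    a long-format table (pop_i, pop_j, theta, n_loci_used).
    """
    pops = counts.populations
    if geometry is not None:
        order = list(geometry["population_id"])
        if set(order) != set(pops):
            raise ValueError("geometry and counts disagree on populations")
        idx = [pops.index(p) for p in order]
        k_all = counts.k[:, idx]
        n_all = counts.n[:, idx]
        pops = order
    else:
        k_all, n_all = counts.k, counts.n
    p = len(pops)
    mat = np.full((p, p), np.nan)
    np.fill_diagonal(mat, 0.0)
    records = []
    for i in range(p):
        for j in range(i + 1, p):
            k = np.stack([k_all[:, i], k_all[:, j]], axis=1).astype(float)
            n = np.stack([n_all[:, i], n_all[:, j]], axis=1).astype(float)
            ok = (n >= 2).all(axis=1)
            n_skipped = int((~ok).sum())
            if n_skipped:
                logger.debug("pair (%s, %s): %d locus/loci skipped (n_i < 2)", pops[i], pops[j], n_skipped)
            k, n = k[ok], n[ok]
            # drop loci monomorphic across the pair: components are 0/0-free but theta undefined alone
            poly = (k.sum(axis=1) > 0) & (k.sum(axis=1) < n.sum(axis=1))
            theta = np.nan
            n_used = int(poly.sum())
            if n_used > 0:
                a, c = _components(k[poly], n[poly])
                denom = (a + c).sum()
                if denom > 0:
                    theta = float(a.sum() / denom)
            if not np.isfinite(theta):
                logger.warning("pair (%s, %s) has no informative loci; F_ST undefined", pops[i], pops[j])
            mat[i, j] = mat[j, i] = theta
            records.append((pops[i], pops[j], theta, n_used))
    table = pd.DataFrame(records, columns=["pop_i", "pop_j", "theta", "n_loci_used"])
    return mat, table
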