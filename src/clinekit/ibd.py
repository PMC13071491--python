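"""Isolation by distance: geodesic distances, linearized-F_ST regression,
Mantel permutation tests, and neighbourhood-size estimation.

Under a one-dimensional stepping-stone model, linearized genetic distance
F_ST / (1 - F_ST) between population pairs increases linearly with the
logarithm of geographic distance (Rousset 1997), and the inverse of the
regression slope is proportional to Wright's neighbourhood size N_S.
Here N_S is taken as exactly 1/slope and is used downstream only as a
dispersal-rate proxy in the selection-coefficient formula s = N_S / w**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def geodesic_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle (haversine) distance in km between two points.

    Coordinates are in decimal degrees; latitudes must lie in [-90, 90]
    and longitudes in [-180, 180].
    """
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def distance_matrix(geometry) -> np.ndarray:
    """Symmetric matrix of pairwise geodesic distances (km) between populations.

    ``geometry`` is a DataFrame with ``latitude`` and ``longitude`` columns
    (one row per population), as produced by :func:`clinekit.genotype_io.read_geometry`.
    """
    lat = np.asarray(geometry["latitude"], dtype=float)
    lon = np.asarray(geometry["longitude"], dtype=float)
    p = len(lat)
    d = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            d[i, j] = d[j, i] = geodesic_km(lat[i], lon[i], lat[j], lon[j])
    return d


@dataclass
class IBDResult:
    """Isolation-by-distance regression summary.

    slope/intercept/r_squared are for the OLS fit of F_ST/(1-F_ST) on
    ln(distance in km); ``n_s`` is the neighbourhood size 1/slope, defined
    only for positive slopes (``None`` otherwise).
    """

    slope: float
    intercept: float
    r_squared: float
    mantel_rho: float | None
    mantel_p: float | None
    n_s: float | None
    n_pairs: int


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel permutation test between two symmetric distance matrices.

    The statistic is the Pearson correlation of the upper-triangular
    entries; the null distribution is generated by simultaneous row/column
    permutations of ``m2``. The p-value is two-sided on ``|rho|`` with the
    add-one rule ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)``.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(m1, m1.T) and np.allclose(m2, m2.T)):
        raise ValueError("Mantel test requires symmetric matrices")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    p = m1.shape[0]
    iu = np.triu_indices(p, k=1)
    v1 = m1[iu]
    v1c = v1 - v1.mean()
    denom1 = np.sqrt((v1c**2).sum())

    def corr(v2: np.ndarray) -> float:
        v2c = v2 - v2.mean()
        denom = denom1 * np.sqrt((v2c**2).sum())
        if denom == 0:
            return 0.0
        return float((v1c * v2c).sum() / denom)

    rho = corr(m2[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(p)
        mp = m2[np.ix_(perm, perm)]
        if abs(corr(mp[iu])) >= abs(rho):
            hits += 1
    pval = (1 + hits) / (1 + n_perm)
    return rho, pval


def ibd_regression(
    fst: np.ndarray,
    geometry,
    populations: list[str] | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
    run_mantel: bool = True,
) -> IBDResult:
    """Regress linearized F_ST on log geographic distance; estimate N_S.

    Parameters
    ----------
    fst
        Symmetric pairwise F_ST matrix (NaN for undefined cells), ordered
        like ``geometry``.
    geometry
        Population table with latitude/longitude (one row per population).
    populations
        Optional subset of ``population_id`` values to restrict the
        regression to (e.g. northern-transect pairs only).
    """
    fst = np.asarray(fst, dtype=float)
    geom = geometry
    if populations is not None:
        idx = [list(geom["population_id"]).index(p) for p in populations]
        geom = geom.iloc[idx].reset_index(drop=True)
        fst = fst[np.ix_(idx, idx)]
    d = distance_matrix(geom)
    p = d.shape[0]
    iu = np.triu_indices(p, k=1)
    dv, fv = d[iu], fst[iu]

    zero_d = (dv <= 0) & np.isfinite(fv)
    if zero_d.any():
        warnings.warn(f"{zero_d.sum()} population pair(s) at zero distance dropped from IBD")
    keep = np.isfinite(fv) & (dv > 0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 population pairs with defined F_ST and positive distance")
    x = np.log(dv[keep])
    y = fv[keep] / (1.0 - fv[keep])
    res = stats.linregress(x, y)
    slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    n_s = 1.0 / slope if slope > 0 else None

    rho = pval = None
    if run_mantel:
        # masked cells break the permutation scheme; Mantel runs on the full matrices
        lin = np.zeros_like(fst)
        lin[iu] = np.where(np.isfinite(fv), fv / (1.0 - fv), 0.0)
        lin += lin.T
        rho, pval = mantel_test(d, lin, n_perm=n_perm, seed=seed)
    return IBDResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mantel_rho=rho,
        mantel_p=pval,
        n_s=n_s,
        n_pairs=int(keep.sum()),
    )
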