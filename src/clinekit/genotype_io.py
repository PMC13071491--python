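"""Readers and writers for the pipeline's flat-file formats.

Formats handled:

* population map — two-column TSV (``sample_id``, ``population_id``);
* transect geometry — TSV with ``population_id``, ``latitude``,
  ``longitude``, ``n_diploid``; transect positions (km) are computed here
  as geodesic distance from a stored reference point (default: the
  northernmost site, 69.06N 22.55E), which is the cline predictor;
* VCF v4.2 (plain or gzipped, via cyvcf2) — reduced to per-population
  ALT-allele counts; only biallelic records are used, missing genotypes
  shrink the allele-copy total (no imputation);
* per-population environmental table — TSV with bioclimatic variables,
  min-max normalized to [0, 1] per variable;
* allele-count matrix TSV — lossless round-trip of the internal counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from clinekit.ibd import geodesic_km

logger = logging.getLogger(__name__)

#: northernmost site of the Swedish transect; cline distances are measured from here
DEFAULT_REFERENCE_POINT = (69.06, 22.55)


@dataclass
class PopulationMap:
    """Assignment of samples to populations (each sample to exactly one)."""

    sample_to_pop: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_pop.values():
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def samples_of(self, population_id: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == population_id]


@dataclass
class AlleleCountMatrix:
    """Per-locus, per-population focal-allele counts.

    ``k[l, j]`` is the number of focal-allele copies observed at locus
    ``l`` in population ``j``; ``n[l, j]`` the total allele copies sampled
    (2 x diploids genotyped there). ``k/n`` realizes the observed
    population allele frequency used as the cline response.
    """

    loci: pd.DataFrame  # columns: locus_id, chrom, pos (1-based)
    populations: list[str]
    k: np.ndarray  # (n_loci, n_pops) int
    n: np.ndarray  # (n_loci, n_pops) int

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(self.k > self.n) or np.any(self.k < 0):
            raise ValueError("allele counts must satisfy 0 <= k <= n")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def frequencies(self) -> np.ndarray:
        """Observed per-population frequencies (NaN where n == 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.k / np.maximum(self.n, 1), np.nan)


@dataclass
class EnvTable:
    """Per-population environmental variables, raw and min-max normalized."""

    populations: list[str]
    raw: pd.DataFrame        # index: population_id, columns: variable ids
    normalized: pd.DataFrame  # same shape; constant variables excluded
    constant_variables: list[str] = field(default_factory=list)


def read_population_map(path) -> PopulationMap:
    """Read a two-column (sample_id, population_id) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2 or len(df) == 0:
        raise ValueError(f"population map {path} is empty or malformed")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "population_id"]
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in population map: {dup.iloc[0]}")
    mapping = dict(zip(df["sample_id"], df["population_id"]))
    pm = PopulationMap(mapping)
    if pm.n_populations < 2:
        raise ValueError("population map must contain at least 2 populations")
    logger.info("population map: %d samples in %d populations", len(mapping), pm.n_populations)
    return pm


def read_geometry(path, reference_point: tuple[float, float] = DEFAULT_REFERENCE_POINT) -> pd.DataFrame:
    """Read the transect geometry TSV and attach ``distance_km``.

    Distances are geodesic (haversine) kilometres from ``reference_point``,
    so the transect coordinate is always consistent with the IBD module's
    distance computations.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"population_id", "latitude", "longitude", "n_diploid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"geometry table missing columns: {sorted(missing)}")
    if (df["n_diploid"] < 1).any():
        raise ValueError("n_diploid must be >= 1 for every population")
    ref_lat, ref_lon = reference_point
    df = df.copy()
    df["distance_km"] = [
        geodesic_km(ref_lat, ref_lon, lat, lon)
        for lat, lon in zip(df["latitude"], df["longitude"])
    ]
    df.attrs["reference_point"] = (ref_lat, ref_lon)
    return df


def read_vcf_to_counts(
    vcf_path,
    popmap: PopulationMap,
    max_missing: float = 0.5,
) -> AlleleCountMatrix:
    """Collapse a diploid VCF into per-population ALT-allele counts.

    Non-biallelic records are skipped (with a logged total). Missing
    genotypes reduce the allele-copy total ``n`` of their population and
    are never imputed. Loci whose overall missing fraction exceeds
    ``max_missing``, or where any population retains zero sampled copies,
    are dropped (the cline likelihood is undefined there); both exclusions
    are logged.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in popmap.sample_to_pop]
    if unknown:
        raise ValueError(f"VCF sample(s) not in population map: {unknown[:5]}")
    pops = popmap.populations
    pop_idx = {p: i for i, p in enumerate(pops)}
    sample_pop = np.array([pop_idx[popmap.sample_to_pop[s]] for s in samples])
    n_pops = len(pops)

    rows, ks, ns = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        k = np.zeros(n_pops, dtype=int)
        n = np.zeros(n_pops, dtype=int)
        called = gt != 2
        np.add.at(n, sample_pop[called], 2)
        np.add.at(k, sample_pop[gt == 1], 1)
        np.add.at(k, sample_pop[gt == 3], 2)
        rows.append((f"{var.CHROM}:{var.POS}", var.CHROM, var.POS))
        ks.append(k)
        ns.append(n)
    if n_skipped:
        logger.info("skipped %d non-biallelic record(s)", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic records in {vcf_path}")

    loci = pd.DataFrame(rows, columns=["locus_id", "chrom", "pos"])
    k_mat = np.vstack(ks)
    n_mat = np.vstack(ns)
    total_copies = 2 * len(samples)
    miss_frac = 1.0 - n_mat.sum(axis=1) / total_copies
    keep = (miss_frac <= max_missing) & (n_mat > 0).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d locus/loci (missingness > %.0f%% or a population with zero copies)",
            n_dropped, 100 * max_missing,
        )
    acm = AlleleCountMatrix(
        loci=loci.loc[keep].reset_index(drop=True),
        populations=pops,
        k=k_mat[keep],
        n=n_mat[keep],
    )
    if acm.n_loci == 0:
        raise ValueError("all records were filtered out")
    acm.loci.attrs["n_skipped_non_biallelic"] = n_skipped
    acm.loci.attrs["n_dropped_missingness"] = n_dropped
    return acm


def read_env_table(path, geometry: pd.DataFrame | None = None) -> EnvTable:
    """Read a populations x variables TSV and min-max normalize each variable.

    Constant variables cannot be normalized; they are flagged and excluded
    from downstream cline fitting.
    """
    raw = pd.read_csv(path, sep="\t")
    if "population_id" not in raw.columns:
        raise ValueError("environmental table needs a population_id column")
    raw = raw.set_index("population_id")
    if geometry is not None:
        geo_pops = set(geometry["population_id"])
        extra = set(raw.index) - geo_pops
        if extra:
            raise ValueError(f"environmental table population(s) absent from geometry: {sorted(extra)}")
    constant = [c for c in raw.columns if np.isclose(raw[c].max(), raw[c].min())]
    norm_cols = {}
    for c in raw.columns:
        if c in constant:
            continue
        lo, hi = raw[c].min(), raw[c].max()
        norm_cols[c] = (raw[c] - lo) / (hi - lo)
    normalized = pd.DataFrame(norm_cols, index=raw.index)
    if constant:
        logger.info("constant environmental variable(s) flagged: %s", constant)
    return EnvTable(
        populations=list(raw.index),
        raw=raw,
        normalized=normalized,
        constant_variables=constant,
    )


def write_counts_tsv(acm: AlleleCountMatrix, path) -> None:
    """Write the count matrix as TSV (locus_id, chrom, pos, k_<pop>/n_<pop> pairs)."""
    out = acm.loci.copy()
    for j, pop in enumerate(acm.populations):
        out[f"k_{pop}"] = acm.k[:, j]
        out[f"n_{pop}"] = acm.n[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> AlleleCountMatrix:
    """Inverse of :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t")
    pops = [c[2:] for c in df.columns if c.startswith("k_")]
    k = df[[f"k_{p}" for p in pops]].to_numpy(dtype=int)
    n = df[[f"n_{p}" for p in pops]].to_numpy(dtype=int)
    return AlleleCountMatrix(
        loci=df[["locus_id", "chrom", "pos"]].copy(),
        populations=pops,
        k=k,
        n=n,
    )
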