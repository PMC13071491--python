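"""Synthetic transect datasets with known truth, for end-to-end testing.

The generator emulates a boreal contact-zone resequencing design: 12
populations spaced along a ~1,400 km southward latitudinal transect from
a northern reference site (69.06N, 22.55E), 15 diploids per population,
and biallelic SNPs in four classes:

* ``clinal`` — frequencies follow a sigmoid/stepped cline across the
  contact zone (defaults: centre drawn around 650 km, width 150-450 km,
  ends near 0.1/0.9), binomially sampled;
* ``linear`` — a straight frequency gradient (no sharp transition), the
  pattern the cline pipeline must exclude;
* ``flat`` — uniform frequency, the null class;
* ``ibd_neutral`` — smooth isolation-by-distance structure: a Gaussian
  process on the logit scale with covariance exp(-d/rho) scaled so mean
  pairwise F_ST hits a target (default 0.01), which gives a positive IBD
  slope and hence a neighbourhood-size estimate from synthetic data alone.

Diploid genotypes are drawn under Hardy-Weinberg within populations and
written as plain-text VCF v4.2 alongside geometry/population-map/
environmental TSVs and a truth table. Everything is bit-reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clinekit.cline_models import ClineParams, cline_value
from clinekit.ibd import geodesic_km, distance_matrix

REFERENCE_POINT = (69.06, 22.55)
KM_PER_DEG_LAT = 111.19492664455873  # pi * R_earth / 180


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic transect."""

    n_pops: int = 12
    transect_length_km: float = 1400.0
    n_diploid: int = 15
    n_clinal: int = 10
    n_linear: int = 30
    n_flat: int = 460
    n_ibd_neutral: int = 500
    # clinal parameter ranges (uniform draws)
    c_range: tuple[float, float] = (550.0, 750.0)
    w_range: tuple[float, float] = (150.0, 450.0)
    pmin_range: tuple[float, float] = (0.0, 0.15)
    pmax_range: tuple[float, float] = (0.85, 1.0)
    clinal_model: str = "I"
    # neutral spatial structure
    rho_km: float = 300.0
    target_fst: float = 0.01
    # environmental table
    n_env_clinal: int = 6
    env_noise_sd: float = 0.02
    seed: int = 0
    position_jitter: float = 0.02  # fraction of inter-population spacing

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_diploid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def simulate_transect(config: SimConfig) -> pd.DataFrame:
    """Population geometry along a southward meridian from the reference point.

    Populations are evenly spaced over [0, L] with seeded jitter at
    interior sites; latitude is derived from the target distance and the
    stored ``distance_km`` is then *recomputed* with the haversine
    formula, so transect coordinates are exactly consistent with the IBD
    module's distances.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    ref_lat, ref_lon = REFERENCE_POINT
    target = np.linspace(0.0, config.transect_length_km, config.n_pops)
    if config.n_pops > 2:
        spacing = config.transect_length_km / (config.n_pops - 1)
        jitter = rng.uniform(-1, 1, config.n_pops - 2) * config.position_jitter * spacing
        target[1:-1] += jitter
    lat = ref_lat - target / KM_PER_DEG_LAT
    geom = pd.DataFrame(
        {
            "population_id": [f"P{i + 1:02d}" for i in range(config.n_pops)],
            "latitude": lat,
            "longitude": np.full(config.n_pops, ref_lon),
            "n_diploid": np.full(config.n_pops, config.n_diploid),
        }
    )
    geom["distance_km"] = [
        geodesic_km(ref_lat, ref_lon, la, lo) for la, lo in zip(geom["latitude"], geom["longitude"])
    ]
    geom.attrs["reference_point"] = REFERENCE_POINT
    return geom


def _true_frequencies(locus_class: str, params: dict, geometry: pd.DataFrame, rng) -> np.ndarray:
    x = np.asarray(geometry["distance_km"], dtype=float)
    if locus_class == "clinal":
        cp = ClineParams(
            model_id=params.get("model", "I"),
            c=params["c"], w=params["w"],
            pmin=params["pmin"], pmax=params["pmax"],
            delta_l=params.get("delta_l"), tau_l=params.get("tau_l"),
            delta_r=params.get("delta_r"), tau_r=params.get("tau_r"),
        )
        return np.asarray(cline_value(cp, x), dtype=float)
    if locus_class == "linear":
        p0, slope = params["p0"], params["slope"]
        if not 0.0 <= p0 <= 1.0:
            raise ValueError("linear intercept outside [0, 1]")
        return np.clip(p0 + slope * x, 0.02, 0.98)
    if locus_class == "flat":
        p = params["p"]
        if not 0.0 <= p <= 1.0:
            raise ValueError("flat frequency outside [0, 1]")
        return np.full(len(x), p)
    if locus_class == "ibd_neutral":
        p0 = params.get("p0", 0.5)
        d = distance_matrix(geometry)
        corr = np.exp(-d / params.get("rho_km", 300.0))
        off = corr[np.triu_indices(len(x), k=1)]
        # scale the logit-GP so expected mean pairwise theta ~ target_fst
        target = params.get("target_fst", 0.01)
        pq = p0 * (1 - p0)
        sigma2 = target / (pq * np.mean(1.0 - off))
        cov = sigma2 * corr
        z = rng.multivariate_normal(np.full(len(x), _logit(p0)), cov, method="cholesky")
        return _expit(z)
    raise ValueError(f"unknown locus class {locus_class!r}")


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_locus_counts(
    locus_class: str,
    params: dict,
    geometry: pd.DataFrame,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population (k, n, true frequency) for one locus.

    ``k_i ~ Binomial(n_i, P(x_i))`` with ``n_i = 2 * n_diploid`` — the
    sampling noise model of the whole pipeline.
    """
    rng = np.random.default_rng(seed)
    p = _true_frequencies(locus_class, params, geometry, rng)
    n = 2 * np.asarray(geometry["n_diploid"], dtype=int)
    k = rng.binomial(n, p)
    return k, n, p


def _draw_locus_params(locus_class: str, config: SimConfig, rng) -> dict:
    if locus_class == "clinal":
        return {
            "model": config.clinal_model,
            "c": rng.uniform(*config.c_range),
            "w": rng.uniform(*config.w_range),
            "pmin": rng.uniform(*config.pmin_range),
            "pmax": rng.uniform(*config.pmax_range),
            "delta_l": rng.uniform(50, 300) if config.clinal_model in ("III", "IV") else None,
            "tau_l": rng.uniform(0.2, 0.8) if config.clinal_model in ("III", "IV") else None,
            "delta_r": rng.uniform(50, 300) if config.clinal_model in ("III", "IV") else None,
            "tau_r": rng.uniform(0.2, 0.8) if config.clinal_model in ("III", "IV") else None,
        }
    if locus_class == "linear":
        lo = rng.uniform(0.05, 0.3)
        hi = rng.uniform(0.7, 0.95)
        return {"p0": lo, "slope": (hi - lo) / config.transect_length_km}
    if locus_class == "flat":
        return {"p": rng.uniform(0.05, 0.95)}
    if locus_class == "ibd_neutral":
        return {
            "p0": rng.uniform(0.2, 0.8),
            "rho_km": config.rho_km,
            "target_fst": config.target_fst,
        }
    raise ValueError(locus_class)


def simulate_dataset(config: SimConfig, outdir) -> dict:
    """Generate a full dataset: VCF, geometry/popmap/env TSVs, truth table.

    Genotypes are drawn per individual as Binomial(2, p_i) (Hardy-Weinberg
    within populations), so re-reading the VCF reproduces the truth
    frequencies up to binomial sampling error. Returns a dict of paths
    plus the in-memory geometry and truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = simulate_transect(config)
    n_pops = config.n_pops

    samples = []
    sample_pop = []
    for i, pop in enumerate(geometry["population_id"]):
        for j in range(config.n_diploid):
            samples.append(f"{pop}_s{j + 1:02d}")
            sample_pop.append(i)
    sample_pop = np.asarray(sample_pop)

    classes = (
        ["clinal"] * config.n_clinal
        + ["linear"] * config.n_linear
        + ["flat"] * config.n_flat
        + ["ibd_neutral"] * config.n_ibd_neutral
    )
    param_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    locus_seeds = np.random.SeedSequence([config.seed, 2]).generate_state(len(classes))

    truth_rows = []
    vcf_path = outdir / "transect.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clinekit-synthetic\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for li, cls in enumerate(classes):
            params = _draw_locus_params(cls, config, param_rng)
            rng = np.random.default_rng(int(locus_seeds[li]))
            p = _true_frequencies(cls, params, geometry, rng)
            # HW genotype draw per individual
            geno = rng.binomial(2, p[sample_pop])
            pos = 1000 * (li + 1)
            locus_id = f"chr1:{pos}"
            gt_str = ["0/0", "0/1", "1/1"]
            row = [
                "chr1", str(pos), locus_id, "A", "C", ".", "PASS", ".", "GT",
            ] + [gt_str[g] for g in geno]
            fh.write("\t".join(row) + "\n")
            truth_rows.append(
                {
                    "locus_id": locus_id,
                    "class": cls,
                    "model": params.get("model", ""),
                    "c": params.get("c", np.nan),
                    "w": params.get("w", np.nan),
                    "pmin": params.get("pmin", np.nan),
                    "pmax": params.get("pmax", np.nan),
                    **{f"freq_{pop}": p[i] for i, pop in enumerate(geometry["population_id"])},
                }
            )

    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")

    popmap_path = outdir / "popmap.tsv"
    pd.DataFrame(
        {"sample_id": samples, "population_id": [geometry["population_id"].iloc[i] for i in sample_pop]}
    ).to_csv(popmap_path, sep="\t", index=False)

    geometry_path = outdir / "geometry.tsv"
    geometry.drop(columns=["distance_km"]).to_csv(
        geometry_path, sep="\t", index=False, float_format="%.10g"
    )

    env_path = outdir / "environment.tsv"
    simulate_env_table(config, geometry).to_csv(env_path, sep="\t", index=False, float_format="%.10g")

    return {
        "vcf": vcf_path,
        "popmap": popmap_path,
        "geometry": geometry_path,
        "env": env_path,
        "truth": truth_path,
        "geometry_df": geometry,
        "truth_df": truth,
        "reference_point": REFERENCE_POINT,
    }


def simulate_env_table(config: SimConfig, geometry: pd.DataFrame) -> pd.DataFrame:
    """19 bioclimatic-style variables; a configurable subset follows clines.

    The first ``n_env_clinal`` variables transition sigmoidally at the
    contact zone (centres drawn from the clinal centre range); the rest
    split between latitudinal linear trends and flat noise. Raw values get
    per-variable offsets/scales so min-max normalization is exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    x = np.asarray(geometry["distance_km"], dtype=float)
    cols = {"population_id": list(geometry["population_id"])}
    n_linear_env = (19 - config.n_env_clinal) // 2
    for v in range(1, 20):
        name = f"bio{v}"
        if v <= config.n_env_clinal:
            cp = ClineParams(
                model_id="I",
                c=rng.uniform(*config.c_range),
                w=rng.uniform(*config.w_range),
                pmin=0.0, pmax=1.0,
            )
            base = np.asarray(cline_value(cp, x), dtype=float)
        elif v <= config.n_env_clinal + n_linear_env:
            base = x / x.max()
        else:
            base = np.full(len(x), 0.5)
        noisy = base + rng.normal(0.0, config.env_noise_sd, len(x))
        offset, scale = rng.uniform(-20, 20), rng.uniform(0.5, 50)
        cols[name] = offset + scale * noisy
    return pd.DataFrame(cols)
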