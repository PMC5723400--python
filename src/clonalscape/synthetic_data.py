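"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, each seeded and fully deterministic, each returning its
ground truth alongside the data:

* clonal populations — ~50 ramet samples in a 50-m-diameter site with
  >= 2 m spacing, drawn from a small number of genets whose multilocus
  genotypes follow Hardy-Weinberg equilibrium at independent loci;
* storm histories — Poisson storm arrivals, linear tracks past each site,
  a radially decaying parametric vortex (an explicit stand-in for
  operational cyclone wind models: only the hourly-winds-at-a-site
  interface matters), i.i.d. synoptic background winds;
* driver scenarios — site covariates over an ~8-degree latitude span with
  SST tied to latitude (to exercise the collinearity prefilter) and a
  stored response function, by default hump-shaped in sqrt cyclone
  probability, plus Gaussian noise, clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

#: Allele counts of the seven-locus microsatellite panel used for
#: Halophila ovalis (loci with 12, 2, 12, 7, 5, 7, and 3 alleles).
MICROSAT_PANEL = (12, 2, 12, 7, 5, 7, 3)


class PackingError(RuntimeError):
    """Requested sample count cannot be packed at the minimum spacing."""


@dataclass
class ClonalPopulationTruth:
    site_id: str
    genet_centers: np.ndarray          # (G_true, 2) metres
    genet_genotypes: list              # per genet: tuple of per-locus calls
    sample_points: np.ndarray          # (N, 2) metres
    sample_to_genet: dict              # sample_id -> genet index
    seed: int

    @property
    def n_sampled_genets(self) -> int:
        return len(set(self.sample_to_genet.values()))


def _dirichlet_frequencies(rng, n_alleles: int, concentration: float = 1.0):
    p = rng.dirichlet(np.full(n_alleles, concentration))
    # avoid degenerate zero frequencies from extreme draws
    p = np.clip(p, 1e-6, None)
    return p / p.sum()


def _hwe_genotype(rng, freqs) -> tuple:
    a, b = rng.choice(len(freqs), size=2, p=freqs)
    a, b = f"{a + 1:03d}", f"{b + 1:03d}"
    return (a, b) if a <= b else (b, a)


def _pack_points(rng, n: int, radius: float, min_spacing: float,
                 max_tries: int = 20000) -> np.ndarray:
    """Dart-throwing placement of n points in a disc at min spacing."""
    pts = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} points at {min_spacing} m spacing in a "
                f"{2 * radius:g}-m-diameter disc after {max_tries} tries"
            )
        tries += 1
        r = radius * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        p = np.array([r * math.cos(theta), r * math.sin(theta)])
        if all(np.hypot(*(p - q)) >= min_spacing for q in pts):
            pts.append(p)
    return np.array(pts)


def simulate_clonal_population(
    g_true: int,
    allele_counts=MICROSAT_PANEL,
    missing_rate: float = 0.0,
    n_samples: int = 50,
    min_spacing: float = 2.0,
    site_diameter: float = 50.0,
    ramet_radius: float = 25.0,
    site_id: str = "site1",
    species: str = "synthetic",
    seed: int = 0,
    allele_frequencies=None,
):
    """Simulate ramet sampling from a clonal meadow.

    Genet centers are uniform in the disc; each of the ``n_samples``
    sample points (>= ``min_spacing`` apart) is assigned to the nearest
    genet center within ``ramet_radius`` (points covered by no genet are
    re-drawn). Each genet carries one multilocus genotype drawn once under
    HWE from per-locus allele frequencies (Dirichlet-uniform unless given
    explicitly as a list of per-locus frequency vectors). Missing calls
    are injected independently per sample x locus at ``missing_rate``.

    Returns (GenotypeMatrix, ClonalPopulationTruth).
    """
    if g_true < 1:
        raise ValueError("need at least one genet")
    rng = np.random.default_rng(seed)
    radius = site_diameter / 2.0

    if allele_frequencies is None:
        allele_frequencies = [
            _dirichlet_frequencies(rng, k) for k in allele_counts
        ]
    n_loci = len(allele_frequencies)
    locus_ids = [f"L{j + 1}" for j in range(n_loci)]

    centers = _pack_points(rng, g_true, radius, 0.0)
    genotypes = [
        tuple(_hwe_genotype(rng, np.asarray(f, dtype=float))
              for f in allele_frequencies)
        for _ in range(g_true)
    ]

    # sample points: spaced, and each must fall within some genet's reach
    pts, tries = [], 0
    max_tries = 40000
    while len(pts) < n_samples:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n_samples} samples at {min_spacing} m "
                f"spacing within ramet reach after {max_tries} tries"
            )
        tries += 1
        r = radius * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        p = np.array([r * math.cos(theta), r * math.sin(theta)])
        if any(np.hypot(*(p - q)) < min_spacing for q in pts):
            continue
        d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
        if d.min() > ramet_radius:  # unoccupied ground: re-draw the point
            continue
        pts.append(p)
    pts = np.array(pts)

    sample_ids = [f"{site_id}_s{i + 1:02d}" for i in range(n_samples)]
    sample_to_genet = {}
    calls = []
    for sid, p in zip(sample_ids, pts):
        d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
        gi = int(np.argmin(d))
        sample_to_genet[sid] = gi
        row = []
        for call in genotypes[gi]:
            row.append(None if rng.random() < missing_rate else call)
        calls.append(row)

    matrix = GenotypeMatrix(site_id=site_id, species=species,
                            sample_ids=sample_ids, locus_ids=locus_ids,
                            calls=calls)
    truth = ClonalPopulationTruth(
        site_id=site_id, genet_centers=centers, genet_genotypes=genotypes,
        sample_points=pts, sample_to_genet=sample_to_genet, seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# storms


@dataclass
class StormScenario:
    """Parametric storm climate for one stretch of coast.

    The vortex is a simple radially decaying profile — linear ramp to the
    peak wind at the radius of maximum winds, power-law decay outside —
    standing in for operational cyclone wind-field models; only the hourly
    wind it yields at a site matters downstream.
    """

    storms_per_year: float = 2.0
    max_wind: float = 45.0            # m/s at the radius of maximum winds
    eye_radius_km: float = 30.0       # radius of maximum winds
    decay_exponent: float = 0.6
    track_speed_kmh: float = 20.0
    track_offset_scale_km: float = 150.0  # Rayleigh scale of closest approach
    storm_hours: int = 48
    synoptic_mean: float = 6.0        # lognormal median of background wind, m/s
    synoptic_sigma: float = 0.25
    synoptic_cap: float = 16.0        # background winds stay below gale force;
                                      # sustained gale seas belong to storms
    seed: int = 0


def vortex_wind(distance_km, max_wind: float, eye_radius_km: float,
                decay_exponent: float = 0.6):
    """Hourly vortex wind at a radial distance from the cyclone center."""
    d = np.asarray(distance_km, dtype=float)
    inner = max_wind * d / eye_radius_km
    outer = max_wind * (eye_radius_km / np.maximum(d, eye_radius_km)) ** decay_exponent
    return np.where(d < eye_radius_km, inner, outer)


def simulate_storm_history(
    scenario: StormScenario,
    years: int,
    sites: pd.DataFrame,
    start_year: int = 1985,
) -> dict:
    """Hourly wind series per site from a Poisson storm process.

    ``sites`` needs columns site_id, x_km, y_km (planar coordinates;
    tracks run parallel to the x axis at a Rayleigh-distributed closest
    approach in y, so a site farther from the storm corridor sees weaker
    vortex winds). Returns {site_id: DataFrame of WindSample columns}.
    """
    if years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(scenario.seed)
    n_hours = years * 8760
    t0 = pd.Timestamp(f"{start_year}-01-01")
    timestamps = pd.date_range(t0, periods=n_hours, freq="h")

    out = {}
    site_rows = list(sites.itertuples(index=False))
    syn = {
        s.site_id: np.minimum(
            rng.lognormal(np.log(scenario.synoptic_mean),
                          scenario.synoptic_sigma, n_hours),
            scenario.synoptic_cap)
        for s in site_rows
    }
    cyc = {s.site_id: np.zeros(n_hours) for s in site_rows}
    dist = {s.site_id: np.full(n_hours, 1e6) for s in site_rows}

    n_storms = rng.poisson(scenario.storms_per_year * years)
    for _ in range(n_storms):
        start = rng.integers(0, n_hours)
        # track: moves in +x at track_speed; passes each site at an offset
        y_track = rng.rayleigh(scenario.track_offset_scale_km) * rng.choice([-1, 1])
        x_start = -scenario.track_speed_kmh * scenario.storm_hours / 2
        hours = np.arange(scenario.storm_hours)
        idx = start + hours
        idx = idx[idx < n_hours]
        x_track = x_start + scenario.track_speed_kmh * hours[: len(idx)]
        for s in site_rows:
            d = np.hypot(x_track - s.x_km, y_track - s.y_km)
            w = vortex_wind(d, scenario.max_wind, scenario.eye_radius_km,
                            scenario.decay_exponent)
            stronger = w > cyc[s.site_id][idx]
            cyc[s.site_id][idx] = np.where(stronger, w, cyc[s.site_id][idx])
            dist[s.site_id][idx] = np.where(stronger, d, dist[s.site_id][idx])

    for s in site_rows:
        out[s.site_id] = pd.DataFrame({
            "timestamp": timestamps,
            "site_id": s.site_id,
            "cyclone_wind": cyc[s.site_id],
            "synoptic_wind": syn[s.site_id],
            "distance_to_center": dist[s.site_id],
            "eye_radius": scenario.eye_radius_km,
        })
    return out


def simulate_exposure_counts(lam_true: float, years: int, seed: int = 0,
                             site_id: str = "site1"):
    """Yearly exposure counts drawn directly from Poisson(lam_true).

    The minimal generator for checking the 1 - e^(-lambda) arithmetic
    against long-run event frequencies.
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam_true, size=years)
    return {y: int(c) for y, c in enumerate(counts)}


# ---------------------------------------------------------------------------
# driver scenarios


@dataclass
class DriverScenario:
    """Covariate-and-response generator for the driver analysis.

    The default response is hump-shaped in sqrt cyclone probability
    (interior maximum at ``hump_peak`` on the sqrt scale), with an
    additive dugong-presence effect and a linear SST slope, plus Gaussian
    noise, clipped to [0, 1].
    """

    n_sites: int = 16
    species: str = "synthetic"
    lat_range: tuple = (-22.0, -14.0)
    sst_range: tuple = (26.0, 29.5)
    sst_lat_noise: float = 0.1        # keeps corr(SST, latitude) >= 0.95
    kd490_range: tuple = (0.03, 0.12)
    dist_shore_range: tuple = (5.0, 75.0)
    dugong_prob: float = 0.5
    dist_cyclone_corr: float = 0.0    # Gaussian-copula link, e.g. 0.86
    hump_amplitude: float = 0.8
    hump_peak: float = 0.55           # on the sqrt(cyclone_pr) scale
    dugong_effect: float = 0.0
    sst_slope: float = 0.0
    baseline: float = 0.1
    noise_sd: float = 0.05
    seed: int = 0


def _response(scn: DriverScenario, cyclone_pr, dugong01, sst):
    s = np.sqrt(cyclone_pr)
    hump = scn.hump_amplitude * (1.0 - ((s - scn.hump_peak) / scn.hump_peak) ** 2)
    sst_c = (sst - np.mean(scn.sst_range)) / (scn.sst_range[1] - scn.sst_range[0])
    return (scn.baseline + np.clip(hump, 0.0, None)
            + scn.dugong_effect * dugong01 + scn.sst_slope * sst_c)


def simulate_driver_dataset(scenario: DriverScenario):
    """Site covariates plus richness response for one species.

    Returns (DataFrame with site_id, species, latitude, cyclone_pr,
    dugong, sst, kd490, dist_shore, R; truth dict holding the scenario and
    the noise-free response).
    """
    scn = scenario
    if scn.n_sites < 6:
        raise ValueError("need at least six sites")
    rng = np.random.default_rng(scn.seed)
    n = scn.n_sites

    latitude = np.sort(rng.uniform(*scn.lat_range, n))
    lat01 = (latitude - scn.lat_range[0]) / (scn.lat_range[1] - scn.lat_range[0])
    sst = (scn.sst_range[0] + lat01 * (scn.sst_range[1] - scn.sst_range[0])
           + rng.normal(0.0, scn.sst_lat_noise, n))

    z_cyc = rng.normal(size=n)
    cyclone_pr = stats_norm_cdf(z_cyc) * 0.9 + 0.02
    if scn.dist_cyclone_corr != 0.0:
        rho = scn.dist_cyclone_corr
        z_d = rho * z_cyc + math.sqrt(1 - rho ** 2) * rng.normal(size=n)
    else:
        z_d = rng.normal(size=n)
    d01 = stats_norm_cdf(z_d)
    dist_shore = scn.dist_shore_range[0] + d01 * (
        scn.dist_shore_range[1] - scn.dist_shore_range[0])

    kd490 = rng.uniform(*scn.kd490_range, n)
    dugong01 = (rng.random(n) < scn.dugong_prob).astype(float)
    # guard against a constant factor in tiny designs
    if dugong01.sum() in (0, n):
        dugong01[rng.integers(0, n)] = 1.0 - dugong01[0]

    mu = _response(scn, cyclone_pr, dugong01, sst)
    r_obs = np.clip(mu + rng.normal(0.0, scn.noise_sd, n), 0.0, 1.0)

    df = pd.DataFrame({
        "site_id": [f"site{i + 1:02d}" for i in range(n)],
        "species": scn.species,
        "latitude": latitude,
        "cyclone_pr": cyclone_pr,
        "dugong": np.where(dugong01 > 0, "present", "absent"),
        "sst": sst,
        "kd490": kd490,
        "dist_shore": dist_shore,
        "R": r_obs,
    })
    truth = {"scenario": scn, "mu": mu, "dugong01": dugong01}
    return df, truth


def stats_norm_cdf(z):
    from scipy.stats import norm

    return norm.cdf(np.asarray(z, dtype=float))
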