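"""Synthetic landscapes, occurrences, genotypes and clustering-run summaries.

Every generator is a pure function of its configuration and seed, and plants
a known truth that the downstream estimators must recover:

* :func:`generate_landscape` builds co-registered present and glacial
  predictor stacks on an idealised meridional coastline. The glacial stack
  is the present stack plus additive offsets (e.g. a −2 °C temperature
  anomaly), with the shoreline displaced to the −120 m isobath.
* :func:`generate_occurrences` draws presence points from a known
  environmental niche.
* :func:`generate_genotypes` draws diploid microsatellite genotypes with a
  planted two-level cluster hierarchy (Dirichlet-divergent allele
  frequencies), refugial sites carrying private alleles, and a founder
  effect that truncates the allele pool with distance to the nearest
  refugium.
* :func:`generate_structure_runs` fabricates Bayesian-clustering
  log-probability tables with a rate-of-change break at the true K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .geo import min_distance_to_points_km
from .io_formats import MISSING, GenotypeMatrix, MembershipMatrix, validate_site_table
from .stack import EnvStack

PREDICTORS = (
    "max_temperature",
    "min_temperature",
    "phosphate",
    "nitrate",
    "salinity",
    "ice_thickness",
)


class ConfigurationError(ValueError):
    pass


class EmptyNicheError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# Landscape
# --------------------------------------------------------------------------- #
@dataclass
class LandscapeConfig:
    """Geometry, niche truth and glacial anomalies of the synthetic seascape.

    The default landscape is a north–south coastline spanning 14–55° N with
    a linear thermal gradient and oligotrophic warm waters. The true niche
    is the interval per predictor inside which the species can occur; the
    defaults make temperature the binding constraint (max temperature
    ≤ 24 °C at the warm edge, min temperature ≥ 3 °C at the cold edge).
    """

    lon_min: float = 0.0
    lon_max: float = 8.0
    lat_min: float = 14.0
    lat_max: float = 55.0
    resolution: float = 0.25
    niche: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "max_temperature": (-np.inf, 24.0),
            "min_temperature": (3.0, np.inf),
            "phosphate": (0.01, np.inf),
            "nitrate": (0.01, np.inf),
            "salinity": (20.0, 45.0),
            "ice_thickness": (-np.inf, 0.16),
        }
    )
    # glacial anomalies: a -2 °C shift of maxima (low-latitude anomaly) and a
    # stronger -6 °C shift of minima, reflecting the steeper glacial
    # meridional gradient that pushed the cold range edge equatorward
    lgm_offsets: Dict[str, float] = field(
        default_factory=lambda: {
            "max_temperature": -2.0,
            "min_temperature": -6.0,
            "ice_thickness": 0.05,
        }
    )
    sea_level_drop: float = 120.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ConfigurationError("degenerate extent")
        for name, (lo, hi) in self.niche.items():
            if not lo < hi:
                raise ConfigurationError(f"niche for {name!r}: lower bound must be below upper bound")


def _base_fields(cfg: LandscapeConfig) -> Tuple[Dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic predictor surfaces plus seeded measurement noise."""
    lon = np.arange(cfg.lon_min + cfg.resolution / 2, cfg.lon_max, cfg.resolution)
    lat = np.arange(cfg.lat_max - cfg.resolution / 2, cfg.lat_min, -cfg.resolution)
    nrow, ncol = lat.size, lon.size
    latg = np.repeat(lat[:, None], ncol, axis=1)
    colg = np.repeat(np.arange(ncol)[None, :], nrow, axis=0)

    rng = np.random.default_rng(cfg.seed)
    # two-terrace shelf profile (terraces at the interglacial and glacial
    # lowstand levels): a western land strip, a gentle present-day shelf
    # (0 to -30 m over ~2°), a scarp to -120 m, a second terrace from -120
    # to -150 m (the glacial 30 m habitat band), then the deep ocean
    x = colg * cfg.resolution  # degrees offshore of the western edge
    ramp = np.select(
        [x < 0.5, x < 2.5, x < 3.0, x < 5.0],
        [
            20.0 - 44.0 * x,
            -2.0 - 14.0 * (x - 0.5),
            -30.0 - 180.0 * (x - 2.5),
            -120.0 - 15.0 * (x - 3.0),
        ],
        default=-150.0 - 200.0 * (x - 5.0),
    )
    bathy = ramp + rng.normal(0.0, 1.0, size=(nrow, ncol))
    tmax = 34.0 - 0.5 * latg
    layers = {
        "max_temperature": tmax,
        "min_temperature": tmax - 8.0,
        "phosphate": 0.006 + 0.0008 * (latg - cfg.lat_min),
        "nitrate": 0.002 + 0.0006 * latg,
        "salinity": 34.0 + 0.01 * (latg - 40.0),
        "ice_thickness": np.maximum(0.0, 0.05 * (latg - 58.0)),
    }
    if cfg.noise_sd > 0:
        for name in layers:
            scale = cfg.noise_sd if "temperature" in name else cfg.noise_sd * 0.01
            layers[name] = layers[name] + rng.normal(0.0, scale, size=(nrow, ncol))
    return layers, bathy, lon, lat


def _masks(bathy: np.ndarray, sea_level: float) -> Tuple[np.ndarray, np.ndarray]:
    """Ocean and ≤30 m habitat masks for a sea level ``sea_level`` m below present."""
    ocean = bathy < -sea_level
    habitat = ocean & (bathy >= -sea_level - 30.0)
    return ocean, habitat


def generate_landscape(cfg: LandscapeConfig) -> Tuple[EnvStack, EnvStack]:
    """Return co-registered (present, LGM) stacks.

    The LGM stack equals the present stack plus the configured additive
    offsets; its shoreline is displaced to the configured isobath below the
    present sea level, so the ocean and 30 m habitat masks shift offshore.
    """
    layers, bathy, lon, lat = _base_fields(cfg)
    ocean_p, hab_p = _masks(bathy, 0.0)
    present = EnvStack(
        layers={k: v.copy() for k, v in layers.items()},
        bathymetry=bathy,
        ocean_mask=ocean_p,
        habitat_mask=hab_p,
        lon=lon,
        lat=lat,
        period="present",
    )
    lgm_layers = {k: v + cfg.lgm_offsets.get(k, 0.0) for k, v in layers.items()}
    ocean_l, hab_l = _masks(bathy, cfg.sea_level_drop)
    lgm = EnvStack(
        layers=lgm_layers,
        bathymetry=bathy.copy(),
        ocean_mask=ocean_l,
        habitat_mask=hab_l,
        lon=lon,
        lat=lat,
        period="LGM",
    )
    return present, lgm


# --------------------------------------------------------------------------- #
# Occurrences
# --------------------------------------------------------------------------- #
@dataclass
class OccurrenceSet:
    """Presence / pseudo-absence points with coordinates."""

    data: pd.DataFrame  # columns: lon, lat, label, source

    @property
    def presences(self) -> pd.DataFrame:
        return self.data[self.data["label"] == "presence"]

    @property
    def absences(self) -> pd.DataFrame:
        return self.data[self.data["label"] == "pseudo_absence"]


def niche_suitability(stack: EnvStack, niche: Dict[str, Tuple[float, float]]) -> np.ndarray:
    """Boolean truth map: habitat cells where every predictor is in tolerance."""
    ok = stack.habitat_mask.copy()
    for name, (lo, hi) in niche.items():
        if name not in stack.layers:
            raise ValueError(f"stack lacks predictor {name!r}")
        ok &= (stack.layers[name] >= lo) & (stack.layers[name] <= hi)
    return ok


def generate_occurrences(
    stack: EnvStack, cfg: LandscapeConfig, n: int, seed: int, jitter: bool = True
) -> OccurrenceSet:
    """Draw ``n`` presence points uniformly over niche-suitable habitat cells."""
    suitable = niche_suitability(stack, cfg.niche)
    rows, cols = np.nonzero(suitable)
    if rows.size == 0:
        raise EmptyNicheError("no habitat cell satisfies the configured niche")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    lon = stack.lon[cols[idx]].astype(float)
    lat = stack.lat[rows[idx]].astype(float)
    if jitter:
        half = stack.resolution * 0.49
        lon = lon + rng.uniform(-half, half, size=n)
        lat = lat + rng.uniform(-half, half, size=n)
    df = pd.DataFrame({"lon": lon, "lat": lat, "label": "presence", "source": "synthetic"})
    return OccurrenceSet(df)


# --------------------------------------------------------------------------- #
# Sites
# --------------------------------------------------------------------------- #
def generate_sites(
    present: EnvStack,
    lgm: EnvStack,
    cfg: LandscapeConfig,
    n_sites: int = 40,
    n_level1: int = 2,
    n_level2_per_group: int = 3,
    refugium_radius_km: float = 150.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sampling sites along the present coastline with planted truth labels.

    Sites sit on the innermost habitat cell of evenly spaced latitudes
    within the present suitable range (a 1-D coastline embedded in the 2-D
    grid). A site is flagged refugial when it lies within
    ``refugium_radius_km`` of a cell that was niche-suitable at the LGM.
    Level-1 clusters are contiguous latitude blocks; level-2 clusters nest
    inside them.
    """
    suitable_now = niche_suitability(present, cfg.niche)
    rows = np.nonzero(suitable_now.any(axis=1))[0]
    if rows.size < n_sites:
        raise ConfigurationError("not enough suitable coastline rows for the requested sites")
    pick = np.linspace(0, rows.size - 1, n_sites).round().astype(int)
    site_rows = rows[pick]
    site_cols = np.array([np.nonzero(suitable_now[r])[0][0] for r in site_rows])

    lgm_ok = niche_suitability(lgm, cfg.niche)
    ref_rows, ref_cols = np.nonzero(lgm_ok)
    lons = present.lon[site_cols]
    lats = present.lat[site_rows]
    if ref_rows.size:
        dist = min_distance_to_points_km(lons, lats, lgm.lon[ref_cols], lgm.lat[ref_rows])
        # refugial = the site's latitude band stayed suitable at the LGM
        # (the glacial shoreline sits offshore, so cross-shore displacement
        # alone must not disqualify a persistent latitude)
        ref_lats = np.unique(lgm.lat[ref_rows])
        lat_gap = np.min(np.abs(lats[:, None] - ref_lats[None, :]), axis=1)
        refug = (lat_gap <= present.resolution) | (dist <= refugium_radius_km)
    else:
        dist = np.full(n_sites, np.inf)
        refug = np.zeros(n_sites, dtype=bool)

    order = np.argsort(-lats)  # north to south
    level1 = np.empty(n_sites, dtype=int)
    level2 = np.empty(n_sites, dtype=int)
    blocks = np.array_split(order, n_level1)
    for i, block in enumerate(blocks):
        level1[block] = i
        for j, sub in enumerate(np.array_split(block, n_level2_per_group)):
            level2[sub] = i * n_level2_per_group + j

    df = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:03d}" for i in range(n_sites)],
            "lon": lons,
            "lat": lats,
            "region": [f"G{l2 + 1}" for l2 in level2],
            "refugium": refug,
            "level1": level1,
            "level2": level2,
            "dist_refugium_km": dist,
        }
    )
    return validate_site_table(df)


# --------------------------------------------------------------------------- #
# Genotypes
# --------------------------------------------------------------------------- #
@dataclass
class GenotypeSimConfig:
    """Planted-truth microsatellite simulation.

    Allele frequencies follow a hierarchical Dirichlet model: each level-1
    cluster diverges from the ancestral frequency vector with concentration
    ``level1_concentration``, and each level-2 cluster diverges from its
    parent with the (larger) ``level2_concentration`` — so level-1
    divergence exceeds level-2 divergence. Refugial sites carry
    ``n_private_alleles`` site-restricted alleles; non-refugial sites lose
    alleles with distance d to the nearest refugium by truncating the
    ranked allele list to ``max(2, round(A * exp(-decay_rate * d)))``.
    """

    n_sites: int = 40
    individuals_per_site: int = 30
    n_loci: int = 6
    alleles_per_locus: int = 20
    level1_concentration: float = 0.3
    level2_concentration: float = 10.0
    n_private_alleles: int = 2
    private_mass: float = 0.06
    decay_rate: float = 0.003  # per km
    missing_rate: float = 0.02
    disjoint_level1_pools: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individuals_per_site < 1:
            raise ConfigurationError("need at least one individual per site")
        if self.alleles_per_locus < 2:
            raise ConfigurationError("allele pool must have at least 2 alleles per locus")
        if self.decay_rate < 0:
            raise ConfigurationError("decay rate must be non-negative")


def generate_genotypes(cfg: GenotypeSimConfig, sites: pd.DataFrame) -> GenotypeMatrix:
    """Draw diploid genotypes for every site in ``sites``.

    ``sites`` must carry lon/lat, ``refugium`` flags and planted ``level1``
    / ``level2`` labels (as produced by :func:`generate_sites`). Missing
    data is encoded by the conventional 0 ("000") code.
    """
    sites = sites.reset_index(drop=True)
    for col in ("refugium", "level1", "level2"):
        if col not in sites.columns:
            raise ConfigurationError(f"site table lacks required column {col!r}")
    n_sites = len(sites)
    rng = np.random.default_rng(cfg.seed)
    A = cfg.alleles_per_locus
    loci = [f"L{i + 1}" for i in range(cfg.n_loci)]

    ref = sites[sites["refugium"]]
    if len(ref) and cfg.decay_rate > 0:
        dist = min_distance_to_points_km(
            sites["lon"].to_numpy(), sites["lat"].to_numpy(), ref["lon"].to_numpy(), ref["lat"].to_numpy()
        )
    else:
        dist = np.zeros(n_sites)

    l1_labels = sorted(sites["level1"].unique())
    l2_labels = sorted(sites["level2"].unique())
    l2_parent = {l2: sites.loc[sites["level2"] == l2, "level1"].iloc[0] for l2 in l2_labels}

    records = []
    next_private = A + 1  # private allele codes continue past the shared pool
    site_private: Dict[str, List[int]] = {}
    for locus_i, locus in enumerate(loci):
        ancestral = rng.dirichlet(np.full(A, 1.5))
        l1_freq = {}
        for l1 in l1_labels:
            p = rng.dirichlet(cfg.level1_concentration * A * ancestral)
            if cfg.disjoint_level1_pools:
                # planted fixed differences: each level-1 cluster keeps a
                # disjoint slice of the shared pool
                share = np.array_split(np.arange(A), len(l1_labels))
                mask = np.zeros(A)
                mask[share[l1_labels.index(l1)]] = 1.0
                p = p * mask
                p = p / p.sum()
            l1_freq[l1] = p
        l2_freq = {l2: rng.dirichlet(cfg.level2_concentration * A * l1_freq[l2_parent[l2]] + 1e-9) for l2 in l2_labels}
        if cfg.disjoint_level1_pools:
            for l2 in l2_labels:
                p = l2_freq[l2] * (l1_freq[l2_parent[l2]] > 0)
                l2_freq[l2] = p / p.sum()

        for s_i, site in sites.iterrows():
            freq = l2_freq[site["level2"]].copy()
            codes = np.arange(1, A + 1)
            if site["refugium"] and cfg.n_private_alleles > 0:
                key = (site["site_id"], locus)
                priv = np.arange(next_private, next_private + cfg.n_private_alleles)
                next_private += cfg.n_private_alleles
                freq = np.concatenate([freq * (1 - cfg.private_mass), np.full(cfg.n_private_alleles, cfg.private_mass / cfg.n_private_alleles)])
                codes = np.concatenate([codes, priv])
            elif not site["refugium"] and cfg.decay_rate > 0:
                m = max(2, int(round(A * np.exp(-cfg.decay_rate * dist[s_i]))))
                keep = np.argsort(-freq)[:m]
                mask = np.zeros_like(freq)
                mask[keep] = 1.0
                freq = freq * mask
                freq = freq / freq.sum()

            n_ind = cfg.individuals_per_site
            draws = rng.choice(codes, size=(n_ind, 2), p=freq)
            miss = rng.random(n_ind) < cfg.missing_rate
            draws[miss] = MISSING
            for ind_i in range(n_ind):
                records.append(
                    (
                        site["site_id"],
                        f"{site['site_id']}_{ind_i + 1:03d}",
                        locus,
                        int(draws[ind_i, 0]),
                        int(draws[ind_i, 1]),
                    )
                )
    df = pd.DataFrame(records, columns=["site", "individual", "locus", "allele1", "allele2"])
    return GenotypeMatrix(df, loci)


# --------------------------------------------------------------------------- #
# Clustering-run tables and membership matrices
# --------------------------------------------------------------------------- #
def generate_structure_runs(
    true_k: int,
    k_max: int,
    replicates: int = 10,
    seed: int = 0,
    gain: float = 50.0,
    plateau_gain: float = 1.0,
    noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Fabricate a (K, replicate, lnP) table with a break at ``true_k``.

    Mean lnP rises by ``gain`` per cluster up to the true K and by
    ``plateau_gain`` beyond it, with i.i.d. Gaussian replicate noise — the
    second-order rate of change therefore peaks at ``true_k``.
    """
    if not 1 < true_k < k_max:
        raise ConfigurationError("need 1 < true_k < k_max")
    if replicates < 2:
        raise ConfigurationError("DeltaK needs at least 2 replicates per K (sd of lnP)")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, k_max + 1):
        mean = -5000.0 + gain * min(k, true_k) + plateau_gain * max(0, k - true_k)
        for rep in range(1, replicates + 1):
            rows.append((k, rep, mean + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["K", "replicate", "lnP"])


def synthetic_membership(
    sites: pd.DataFrame,
    labels: Dict[str, int],
    individuals_per_site: int = 10,
    admixed_sites: Tuple[str, ...] = (),
    noise: float = 0.02,
    seed: int = 0,
) -> MembershipMatrix:
    """Fabricate per-individual membership proportions for known clusters.

    Individuals of an admixed site split evenly across all clusters; other
    individuals put ``1 - noise`` on their site's cluster.
    """
    k = len(set(labels.values()))
    rng = np.random.default_rng(seed)
    ids, site_col, qs = [], [], []
    for site_id in sites["site_id"]:
        for i in range(individuals_per_site):
            ids.append(f"{site_id}_{i + 1:03d}")
            site_col.append(site_id)
            if site_id in admixed_sites:
                q = np.full(k, 1.0 / k)
            else:
                q = np.full(k, noise / max(1, k - 1))
                q[labels[site_id]] = 1.0 - noise
            q = q + rng.uniform(0, 1e-4, size=k)
            qs.append(q / q.sum())
    return MembershipMatrix(ids=ids, q=np.array(qs), sites=site_col)
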