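"""Per-site and per-cluster diversity and differentiation statistics.

Implements the microsatellite toolbox used throughout the genetics track:

* allele counts/frequencies per site × locus (gene copies, diploid);
* unbiased gene diversity He = n/(n-1) * (1 - sum p^2), averaged over loci;
* rarefied allelic richness and rarefied private alleles at a common
  gene-copy size g, by Monte-Carlo subsampling without replacement and by
  the closed-form hypergeometric expectation
  E[A_g] = sum_i (1 - C(n - N_i, g) / C(n, g));
* Jost's D between groups (Nei–Chesser-corrected Hs/Ht with the
  k/(k-1) group-number factor), arithmetic mean over loci;
* the diversity-versus-distance-to-refugium summary (great-circle distance
  to the nearest refugial cell, binned means, Spearman trend).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .geo import min_distance_to_points_km
from .io_formats import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Allele frequencies
# --------------------------------------------------------------------------- #
@dataclass
class AlleleFrequencyTable:
    """Allele counts per site × locus in long form.

    ``counts`` columns: site, locus, allele, count; ``n`` gene copies per
    site × locus are the column sums. Site × locus cells with no typed
    individual are simply absent.
    """

    counts: pd.DataFrame
    loci: List[str]

    @property
    def sites(self) -> List[str]:
        return list(pd.unique(self.counts["site"]))

    def cell(self, site, locus) -> pd.Series:
        sub = self.counts[(self.counts["site"] == site) & (self.counts["locus"] == locus)]
        return sub.set_index("allele")["count"]

    def n_copies(self, site, locus) -> int:
        return int(self.cell(site, locus).sum())

    def freqs(self, site, locus) -> pd.Series:
        c = self.cell(site, locus)
        return c / c.sum()

    def typed_loci(self, site) -> List[str]:
        present = set(self.counts.loc[self.counts["site"] == site, "locus"])
        return [l for l in self.loci if l in present]


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Tally gene copies per site × locus × allele (missing codes excluded)."""
    long = pd.concat(
        [
            g.data[["site", "locus", "allele1"]].rename(columns={"allele1": "allele"}),
            g.data[["site", "locus", "allele2"]].rename(columns={"allele2": "allele"}),
        ]
    )
    long = long[long["allele"] != MISSING]
    counts = long.groupby(["site", "locus", "allele"], sort=True).size().rename("count").reset_index()
    typed_sites = set(counts["site"])
    dropped = [s for s in g.sites if s not in typed_sites]
    if dropped:
        warnings.warn(f"sites with no typed locus excluded: {dropped}", stacklevel=2)
    return AlleleFrequencyTable(counts=counts, loci=list(g.loci))


# --------------------------------------------------------------------------- #
# Gene diversity
# --------------------------------------------------------------------------- #
def gene_diversity(freqs: AlleleFrequencyTable) -> pd.Series:
    """Unbiased expected heterozygosity per site, averaged over typed loci.

    Loci with fewer than 2 gene copies at a site are undefined there and
    are left out of the site mean.
    """
    he = {}
    for site in freqs.sites:
        vals = []
        for locus in freqs.typed_loci(site):
            c = freqs.cell(site, locus)
            n = int(c.sum())
            if n < 2:
                continue
            p = c / n
            vals.append(n / (n - 1) * (1.0 - float((p**2).sum())))
        he[site] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(he, name="He")


# --------------------------------------------------------------------------- #
# Rarefaction
# --------------------------------------------------------------------------- #
def rarefied_richness_exact(counts: np.ndarray, g: int) -> float:
    """Closed-form expected number of distinct alleles in a size-g subsample.

    E[A_g] = sum_i (1 - C(n - N_i, g) / C(n, g)), computed with log-gamma
    for numerical stability.
    """
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n = counts.sum()
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds sample size n={n}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = n - counts
    with np.errstate(invalid="ignore"):
        miss = np.where(rest >= g, np.exp(log_comb(rest, g) - log_comb(n, g)), 0.0)
    return float(np.sum(1.0 - miss))


def rarefied_richness_mc(counts: np.ndarray, g: int, reps: int, rng: np.random.Generator) -> float:
    """Monte-Carlo mean distinct alleles in size-g subsamples without replacement."""
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n = counts.sum()
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds sample size n={n}")
    draws = rng.multivariate_hypergeometric(counts, g, size=reps)
    return float((draws > 0).sum(axis=1).mean())


def _private_allele_map(freqs: AlleleFrequencyTable, comparison_sites: Iterable[str]) -> Dict[Tuple[str, int], str]:
    """(locus, allele) -> site, for alleles observed at exactly one site."""
    sub = freqs.counts[freqs.counts["site"].isin(set(comparison_sites))]
    occ = sub.groupby(["locus", "allele"])["site"].agg(["nunique", "first"])
    priv = occ[occ["nunique"] == 1]
    return {idx: row["first"] for idx, row in priv.iterrows()}


def auto_rarefaction_size(freqs: AlleleFrequencyTable, exclude_at_most: int = 10) -> int:
    """Default g: floor of the minimum over sites of mean usable gene copies.

    Site × locus cells with <= ``exclude_at_most`` gene copies are treated
    as too small to inform the standardisation and are ignored.
    """
    per_cell = freqs.counts.groupby(["site", "locus"])["count"].sum()
    usable = per_cell[per_cell > exclude_at_most]
    if usable.empty:
        raise ValueError("no site x locus cell exceeds the small-sample threshold")
    per_site = usable.groupby("site").mean()
    return int(np.floor(per_site.min()))


def rarefied_diversity(
    freqs: AlleleFrequencyTable,
    g: Optional[int] = None,
    reps: int = 10_000,
    seed: int = 0,
    exclude_at_most: int = 10,
    comparison_sites: Optional[Iterable[str]] = None,
    method: str = "mc",
) -> pd.DataFrame:
    """Standardised allelic richness Â and rarefied private alleles PÂ per site.

    Â is the mean over loci of the expected distinct-allele count in a
    size-``g`` gene-copy subsample; PÂ counts only alleles private to the
    site within ``comparison_sites`` (default: all sites, i.e. global
    privacy). ``method`` is ``"mc"`` (Monte-Carlo, ``reps`` randomisations)
    or ``"exact"`` (hypergeometric closed form). Site × locus cells with
    n <= ``exclude_at_most`` or n < g are excluded with a warning.
    """
    if method not in ("mc", "exact"):
        raise ValueError("method must be 'mc' or 'exact'")
    comparison = list(comparison_sites) if comparison_sites is not None else freqs.sites
    if g is None:
        g = auto_rarefaction_size(freqs, exclude_at_most)
    priv_map = _private_allele_map(freqs, comparison)
    rng = np.random.default_rng(seed)

    rows = []
    for site in freqs.sites:
        a_vals, p_vals = [], []
        for locus in freqs.typed_loci(site):
            cell = freqs.cell(site, locus)
            n = int(cell.sum())
            if n <= exclude_at_most or n < g:
                warnings.warn(
                    f"site {site!r} locus {locus!r}: n={n} below rarefaction size; excluded",
                    stacklevel=2,
                )
                continue
            counts = cell.to_numpy()
            alleles = cell.index.to_numpy()
            is_priv = np.array([priv_map.get((locus, a)) == site for a in alleles])
            if method == "exact":
                a_vals.append(rarefied_richness_exact(counts, g))
                p_vals.append(rarefied_richness_exact_private(counts, is_priv, g))
            else:
                draws = rng.multivariate_hypergeometric(counts, g, size=reps)
                seen = draws > 0
                a_vals.append(float(seen.sum(axis=1).mean()))
                p_vals.append(float(seen[:, is_priv].sum(axis=1).mean()) if is_priv.any() else 0.0)
        rows.append(
            {
                "site": site,
                "A_hat": float(np.mean(a_vals)) if a_vals else np.nan,
                "PA_hat": float(np.mean(p_vals)) if p_vals else np.nan,
                "n_loci_used": len(a_vals),
                "g": g,
                "reps": reps if method == "mc" else 0,
            }
        )
    return pd.DataFrame(rows).set_index("site")


def rarefied_richness_exact_private(counts: np.ndarray, is_private: np.ndarray, g: int) -> float:
    """Closed-form expected number of *private* distinct alleles at size g."""
    counts = np.asarray(counts, dtype=int)
    is_private = np.asarray(is_private, dtype=bool)
    keep = counts > 0
    counts, is_private = counts[keep], is_private[keep]
    if not is_private.any():
        return 0.0
    n = counts.sum()
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds sample size n={n}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = n - counts[is_private]
    miss = np.where(rest >= g, np.exp(log_comb(rest, g) - log_comb(n, g)), 0.0)
    return float(np.sum(1.0 - miss))


# --------------------------------------------------------------------------- #
# Jost's D
# --------------------------------------------------------------------------- #
def _pair_d_locus(c1: pd.Series, c2: pd.Series) -> Optional[float]:
    """Jost's D for one locus between two groups given allele counts.

    Nei–Chesser-corrected Hs and Ht (harmonic-mean gene-copy size), then
    D = (Ht - Hs) / (1 - Hs) * k/(k-1) with k = 2 groups. Returns None for
    a locus monomorphic for the same allele in both groups; negative
    estimates are clamped to 0.
    """
    alleles = c1.index.union(c2.index)
    x1 = c1.reindex(alleles, fill_value=0).to_numpy(dtype=float)
    x2 = c2.reindex(alleles, fill_value=0).to_numpy(dtype=float)
    n1, n2 = x1.sum(), x2.sum()
    if n1 < 2 or n2 < 2:
        return None
    p1, p2 = x1 / n1, x2 / n2
    if np.count_nonzero(p1) == 1 and np.count_nonzero(p2) == 1 and np.array_equal(p1 > 0, p2 > 0):
        return None  # monomorphic across both groups: D undefined
    k = 2
    n_harm = k / (1.0 / n1 + 1.0 / n2)
    s_mean = 0.5 * (np.sum(p1**2) + np.sum(p2**2))
    hs = (n_harm / (n_harm - 1.0)) * (1.0 - s_mean)
    p_bar = 0.5 * (p1 + p2)
    ht = 1.0 - np.sum(p_bar**2) + hs / (k * n_harm)
    if 1.0 - hs <= 0:
        return None
    d = (ht - hs) / (1.0 - hs) * k / (k - 1.0)
    if d < 0:
        log.debug("negative per-locus D (%.4g) clamped to 0", d)
        d = 0.0
    return float(min(d, 1.0))


def group_allele_counts(freqs: AlleleFrequencyTable, groups: Dict[str, str]) -> AlleleFrequencyTable:
    """Pool site-level counts into group-level counts."""
    sub = freqs.counts[freqs.counts["site"].isin(groups)].copy()
    sub["site"] = sub["site"].map(groups)
    pooled = sub.groupby(["site", "locus", "allele"])["count"].sum().reset_index()
    return AlleleFrequencyTable(counts=pooled, loci=list(freqs.loci))


def josts_d(
    freqs: AlleleFrequencyTable,
    groups: Optional[Dict[str, str]] = None,
    multilocus: str = "arithmetic",
) -> pd.DataFrame:
    """Pairwise Jost's D matrix between groups (default: between sites).

    ``groups`` maps site -> group label; site counts are pooled per group.
    ``multilocus``: "arithmetic" (mean of per-locus D, the default) or
    "pooled" (D from loci-averaged Hs/Ht components).
    """
    if multilocus not in ("arithmetic", "pooled"):
        raise ValueError("multilocus must be 'arithmetic' or 'pooled'")
    table = group_allele_counts(freqs, groups) if groups is not None else freqs
    units = table.sites
    if len(units) < 2:
        raise ValueError("Jost's D needs at least two groups")
    d = pd.DataFrame(0.0, index=units, columns=units)
    for i, a in enumerate(units):
        for b in units[i + 1 :]:
            if multilocus == "pooled":
                val = _pooled_d(table, a, b)
            else:
                per_locus = []
                for locus in table.loci:
                    ca, cb = table.cell(a, locus), table.cell(b, locus)
                    if ca.empty or cb.empty:
                        continue
                    dl = _pair_d_locus(ca, cb)
                    if dl is not None:
                        per_locus.append(dl)
                val = float(np.mean(per_locus)) if per_locus else np.nan
            d.loc[a, b] = d.loc[b, a] = val
    return d


def _pooled_d(table: AlleleFrequencyTable, a, b) -> float:
    """Multi-locus D from loci-averaged (Ht - Hs) and (1 - Hs) components."""
    num, den = [], []
    for locus in table.loci:
        ca, cb = table.cell(a, locus), table.cell(b, locus)
        if ca.empty or cb.empty:
            continue
        alleles = ca.index.union(cb.index)
        x1 = ca.reindex(alleles, fill_value=0).to_numpy(dtype=float)
        x2 = cb.reindex(alleles, fill_value=0).to_numpy(dtype=float)
        n1, n2 = x1.sum(), x2.sum()
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = x1 / n1, x2 / n2
        k = 2
        n_harm = k / (1.0 / n1 + 1.0 / n2)
        hs = (n_harm / (n_harm - 1.0)) * (1.0 - 0.5 * (np.sum(p1**2) + np.sum(p2**2)))
        ht = 1.0 - np.sum((0.5 * (p1 + p2)) ** 2) + hs / (k * n_harm)
        num.append(ht - hs)
        den.append(1.0 - hs)
    if not den or np.mean(den) <= 0:
        return np.nan
    return float(np.clip(np.mean(num) / np.mean(den) * 2.0, 0.0, 1.0))


# --------------------------------------------------------------------------- #
# Diversity vs distance to refugia
# --------------------------------------------------------------------------- #
def distance_to_refugia_km(
    sites: pd.DataFrame, refugium_mask: np.ndarray, lon: np.ndarray, lat: np.ndarray
) -> pd.Series:
    """Great-circle distance (km) from each site to the nearest refugial cell centre."""
    refugium_mask = np.asarray(refugium_mask, dtype=bool)
    if not refugium_mask.any():
        raise ValueError("refugium map is empty")
    rows, cols = np.nonzero(refugium_mask)
    d = min_distance_to_points_km(
        sites["lon"].to_numpy(), sites["lat"].to_numpy(), np.asarray(lon)[cols], np.asarray(lat)[rows]
    )
    return pd.Series(d, index=sites["site_id"].to_numpy(), name="dist_refugium_km")


def diversity_vs_refugia(
    div: pd.DataFrame,
    sites: pd.DataFrame,
    refugium_mask: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    bin_width_km: float = 50.0,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, Tuple[float, float]]]:
    """Join diversity with distance to the nearest refugium.

    Returns (per-site table, per-distance-bin means, Spearman trends); the
    trend dict maps statistic name -> (rho, p) for the monotone association
    between distance and diversity.
    """
    dist = distance_to_refugia_km(sites, refugium_mask, lon, lat)
    table = div.join(dist, how="inner")
    table["bin"] = (table["dist_refugium_km"] // bin_width_km).astype(int)
    binned = (
        table.groupby("bin")
        .agg(
            dist_mid_km=("dist_refugium_km", "mean"),
            mean_A_hat=("A_hat", "mean"),
            mean_PA_hat=("PA_hat", "mean"),
            n_sites=("A_hat", "size"),
        )
        .reset_index()
    )
    trends = {}
    for col in ("A_hat", "PA_hat"):
        ok = table[[col, "dist_refugium_km"]].dropna()
        if len(ok) >= 3:
            rho, p = stats.spearmanr(ok["dist_refugium_km"], ok[col])
            trends[col] = (float(rho), float(p))
    return table, binned, trends
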