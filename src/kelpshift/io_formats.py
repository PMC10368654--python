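"""Readers and writers for the on-disk artifacts of the pipeline.

Formats
-------
* GenePop (``.gen``): diploid microsatellite genotypes, 3-digit allele codes
  (missing = ``000``), one ``Pop`` block per site, comma after the individual
  id. Site ids are recovered from individual labels of the form
  ``<site>_<number>``.
* CSV genotype long format (site, individual, locus, allele1, allele2) —
  the primary internal exchange format.
* ESRI ASCII grid (``.asc``) for rasters: plain-text, north-up, cell-centre
  registration; the ocean mask travels as a dedicated 0/1 layer.
* CSV tables for sites, Bayesian-clustering run log-probabilities
  (K, replicate, lnP) and membership matrices (id[, site], q1..qK).

Readers are strict: ragged or non-numeric records raise ``ParseError`` with
the offending line number, and nothing is silently dropped — repairs (e.g.
membership renormalisation) are logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .stack import EnvStack, GeometryError

log = logging.getLogger(__name__)

MISSING = 0  # internal missing-allele code; "000" on disk


class ParseError(ValueError):
    """A file violated the expected dialect; message carries the line number."""


# --------------------------------------------------------------------------- #
# Genotypes
# --------------------------------------------------------------------------- #
@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes in long form.

    ``data`` columns: site, individual, locus, allele1, allele2 (int codes,
    0 = missing; both alleles of a locus are missing together or typed
    together).
    """

    data: pd.DataFrame
    loci: List[str]

    def __post_init__(self) -> None:
        required = {"site", "individual", "locus", "allele1", "allele2"}
        missing_cols = required - set(self.data.columns)
        if missing_cols:
            raise ValueError(f"genotype table missing columns {sorted(missing_cols)}")
        a1 = self.data["allele1"].to_numpy()
        a2 = self.data["allele2"].to_numpy()
        if np.any((a1 == MISSING) != (a2 == MISSING)):
            raise ValueError("half-missing genotype: both alleles of a locus must be typed together")
        if np.any(a1 < 0) or np.any(a2 < 0):
            raise ValueError("allele codes must be positive or 0 (missing)")
        # an individual belongs to exactly one site
        per_ind = self.data.groupby("individual")["site"].nunique()
        if (per_ind > 1).any():
            bad = per_ind[per_ind > 1].index[0]
            raise ValueError(f"individual {bad!r} mapped to more than one site")

    @property
    def sites(self) -> List[str]:
        return list(pd.unique(self.data["site"]))

    @property
    def n_individuals(self) -> int:
        return int(self.data["individual"].nunique())

    def subset_sites(self, sites: Iterable[str]) -> "GenotypeMatrix":
        keep = set(sites)
        return GenotypeMatrix(self.data[self.data["site"].isin(keep)].reset_index(drop=True), list(self.loci))

    def missing_rate(self) -> float:
        return float((self.data["allele1"] == MISSING).mean())


@dataclass
class MembershipMatrix:
    """Per-individual membership proportions over K clusters."""

    ids: List[str]
    q: np.ndarray  # (n, K), rows sum to 1
    sites: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or len(self.ids) != self.q.shape[0]:
            raise ValueError("membership matrix shape does not match ids")
        if np.any(self.q < -1e-12):
            raise ValueError("membership proportions must be non-negative")
        sums = self.q.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("membership rows must sum to 1 within 1e-6")

    @property
    def k(self) -> int:
        return self.q.shape[1]


# --------------------------------------------------------------------------- #
# Site tables
# --------------------------------------------------------------------------- #
def validate_site_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"site_id", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    if df["site_id"].duplicated().any():
        raise ValueError("site_ids must be unique")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValueError("coordinates outside WGS84 bounds")
    out = df.copy()
    if "region" not in out.columns:
        out["region"] = "all"
    if "refugium" not in out.columns:
        out["refugium"] = False
    out["hemisphere"] = np.where(out["lat"] >= 0, "N", "S")
    return out


def read_site_table(path) -> pd.DataFrame:
    return validate_site_table(pd.read_csv(path))


def write_site_table(df: pd.DataFrame, path) -> None:
    validate_site_table(df).to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# GenePop
# --------------------------------------------------------------------------- #
def write_genepop(g: GenotypeMatrix, path, title: str = "kelpshift export") -> None:
    """Write a GenePop file: 3-digit codes, one Pop block per site."""
    wide = g.data.pivot_table(
        index=["site", "individual"], columns="locus", values=["allele1", "allele2"], aggfunc="first"
    )
    lines = [title]
    lines.extend(g.loci)
    site_order = g.sites
    for site in site_order:
        lines.append("Pop")
        block = wide.loc[site]
        for ind, row in block.iterrows():
            codes = []
            for locus in g.loci:
                a1 = int(row[("allele1", locus)])
                a2 = int(row[("allele2", locus)])
                codes.append(f"{a1:03d}{a2:03d}")
            lines.append(f"{ind} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeMatrix:
    """Parse a GenePop file written in the package dialect."""
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise ParseError("file too short to be GenePop")
    loci: List[str] = []
    i = 1
    # locus names: one per line (or a single comma-separated line) until "Pop"
    while i < len(text) and text[i].strip().lower() != "pop":
        line = text[i].strip()
        if line:
            loci.extend([x.strip() for x in line.split(",") if x.strip()])
        i += 1
    if i == len(text):
        raise ParseError("no 'Pop' separator found")
    records = []
    site = None
    for lineno in range(i, len(text)):
        line = text[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            site = None
            continue
        if "," not in line:
            raise ParseError(f"line {lineno + 1}: expected 'id , genotypes'")
        ind, geno = line.split(",", 1)
        ind = ind.strip()
        if site is None:
            site = ind.rsplit("_", 1)[0] if "_" in ind else ind
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(f"line {lineno + 1}: {len(fields)} genotypes for {len(loci)} loci")
        for locus, code in zip(loci, fields):
            if len(code) != 6 or not code.isdigit():
                raise ParseError(f"line {lineno + 1}: bad diploid code {code!r} (need 6 digits)")
            records.append((site, ind, locus, int(code[:3]), int(code[3:])))
    df = pd.DataFrame(records, columns=["site", "individual", "locus", "allele1", "allele2"])
    g = GenotypeMatrix(df, loci)
    log.info("read_genepop: %d sites, %d individuals, %d loci", len(g.sites), g.n_individuals, len(loci))
    return g


# --------------------------------------------------------------------------- #
# CSV genotypes
# --------------------------------------------------------------------------- #
def write_genotypes_csv(g: GenotypeMatrix, path) -> None:
    g.data.to_csv(path, index=False)


def read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    for col, lineno_offset in (("allele1", 0), ("allele2", 0)):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ParseError(f"line {int(np.nonzero(bad.to_numpy())[0][0]) + 2}: non-numeric allele in {col}")
        df[col] = df[col].astype(int)
    loci = list(pd.unique(df["locus"]))
    g = GenotypeMatrix(df, loci)
    log.info("read_genotypes_csv: %d sites, %d individuals, %d loci", len(g.sites), g.n_individuals, len(loci))
    return g


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    if format == "genepop":
        return read_genepop(path)
    if format == "csv":
        return read_genotypes_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str = "csv") -> None:
    if format == "genepop":
        write_genepop(g, path)
    elif format == "csv":
        write_genotypes_csv(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# --------------------------------------------------------------------------- #
# Rasters (ESRI ASCII grid)
# --------------------------------------------------------------------------- #
NODATA = -9999.0


def write_raster(grid: np.ndarray, path, lon: np.ndarray, lat: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid (north-up, cell centres)."""
    grid = np.asarray(grid, dtype=float)
    res = float(abs(lon[1] - lon[0])) if len(lon) > 1 else float(abs(lat[1] - lat[0]))
    out = np.where(np.isfinite(grid), grid, NODATA)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcenter {lon[0]:.10f}\n"
        f"yllcenter {lat[-1]:.10f}\n"
        f"cellsize {res:.10f}\n"
        f"nodata_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_raster(path):
    """Read an ESRI ASCII grid; returns (grid, lon, lat) with NaN nodata."""
    header: Dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    grid = grid.reshape(nrows, ncols)
    res = header["cellsize"]
    lon = header["xllcenter"] + res * np.arange(ncols)
    lat = header["yllcenter"] + res * np.arange(nrows)[::-1]
    nodata = header.get("nodata_value", NODATA)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, lon, lat


def write_raster_stack(stack: EnvStack, directory, prefix: str = "") -> Dict[str, str]:
    """Write every layer plus bathymetry and masks to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    items = dict(stack.layers)
    items["bathymetry"] = stack.bathymetry
    items["ocean_mask"] = stack.ocean_mask.astype(float)
    items["habitat_mask"] = stack.habitat_mask.astype(float)
    for name, arr in items.items():
        p = directory / f"{prefix}{name}.asc"
        write_raster(arr, p, stack.lon, stack.lat)
        paths[name] = str(p)
    return paths


def read_raster_stack(paths: Dict[str, str], period: str = "present") -> EnvStack:
    """Assemble an EnvStack from named .asc layers; geometry must agree.

    ``paths`` must include ``bathymetry``, ``ocean_mask`` and
    ``habitat_mask`` alongside the predictor layers.
    """
    grids = {}
    geom = None
    for name, p in paths.items():
        grid, lon, lat = read_raster(p)
        if geom is None:
            geom = (lon, lat, grid.shape)
        else:
            if grid.shape != geom[2] or not np.allclose(lon, geom[0]) or not np.allclose(lat, geom[1]):
                raise GeometryError(f"layer {name!r} does not share grid geometry")
        grids[name] = grid
    for required in ("bathymetry", "ocean_mask", "habitat_mask"):
        if required not in grids:
            raise ValueError(f"raster stack needs a {required!r} layer")
    lon, lat, _ = geom
    layers = {k: v for k, v in grids.items() if k not in ("bathymetry", "ocean_mask", "habitat_mask")}
    return EnvStack(
        layers=layers,
        bathymetry=grids["bathymetry"],
        ocean_mask=np.nan_to_num(grids["ocean_mask"]) > 0.5,
        habitat_mask=np.nan_to_num(grids["habitat_mask"]) > 0.5,
        lon=lon,
        lat=lat,
        period=period,
    )


# --------------------------------------------------------------------------- #
# Clustering-run tables and membership matrices
# --------------------------------------------------------------------------- #
def validate_cluster_runs(df: pd.DataFrame) -> pd.DataFrame:
    required = {"K", "replicate", "lnP"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cluster-run table missing columns {sorted(missing)}")
    if not np.isfinite(df["lnP"]).all():
        raise ValueError("lnP must be finite")
    if (df["K"] < 1).any():
        raise ValueError("K must be >= 1")
    ks = sorted(df["K"].unique())
    gaps = set(range(ks[0], ks[-1] + 1)) - set(ks)
    if gaps:
        warnings.warn(f"cluster-run table has K gaps: {sorted(gaps)}", stacklevel=2)
    return df


def read_cluster_runs(path) -> pd.DataFrame:
    return validate_cluster_runs(pd.read_csv(path))


def write_cluster_runs(df: pd.DataFrame, path) -> None:
    validate_cluster_runs(df).to_csv(path, index=False)


def membership_from_frame(df: pd.DataFrame, tol: float = 1e-3) -> MembershipMatrix:
    """Build a MembershipMatrix from columns id[, site], q1..qK.

    Rows whose proportions sum within ``tol`` of 1 are renormalised (logged);
    rows further off are rejected.
    """
    qcols = [c for c in df.columns if str(c).startswith("q")]
    if not qcols:
        raise ValueError("membership table needs q1..qK columns")
    q = df[qcols].to_numpy(dtype=float)
    if np.any(q < -1e-12):
        raise ValueError("membership proportions must be non-negative")
    sums = q.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > tol):
        bad = int(np.argmax(off))
        raise ValueError(f"membership row {bad} sums to {sums[bad]:.4f}, outside tolerance {tol}")
    n_fixed = int(np.sum(off > 1e-9))
    if n_fixed:
        log.info("membership: renormalised %d rows within tolerance %.0e", n_fixed, tol)
    q = q / sums[:, None]
    sites = df["site"].astype(str).tolist() if "site" in df.columns else None
    return MembershipMatrix(ids=df["id"].astype(str).tolist(), q=q, sites=sites)


def read_membership(path, tol: float = 1e-3) -> MembershipMatrix:
    return membership_from_frame(pd.read_csv(path), tol=tol)


def write_membership(m: MembershipMatrix, path) -> None:
    df = pd.DataFrame(m.q, columns=[f"q{i + 1}" for i in range(m.k)])
    df.insert(0, "id", m.ids)
    if m.sites is not None:
        df.insert(1, "site", m.sites)
    df.to_csv(path, index=False)
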