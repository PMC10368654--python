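"""Summaries of external Bayesian-clustering runs.

The clustering MCMC itself runs outside the package; this module consumes
its outputs: per-run log-probabilities lnP(K) and membership matrices.

* :func:`delta_k` — the Evanno second-order rate-of-change criterion
  ΔK = mean|L''(K)| / sd(L(K)), with L''(K) = L(K+1) - 2 L(K) + L(K-1)
  taken per replicate where replicate ids align across K.
* :func:`assign_and_flag` — site-level majority assignment and admixture
  flagging on mean membership.
* :func:`hierarchical_workflow` — bookkeeping for the two-step analysis:
  per level-1 group genotype subsets (admixed sites excluded) ready for a
  second clustering round, and the (level1, level2) label join.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MembershipMatrix, validate_cluster_runs, write_genepop

log = logging.getLogger(__name__)


@dataclass
class DeltaKResult:
    table: pd.DataFrame  # per K: mean_lnP, sd_lnP, mean_abs_lpp, delta_k
    selected_k: int
    ambiguous: bool

    def delta_k_at(self, k: int) -> float:
        return float(self.table.set_index("K").loc[k, "delta_k"])


def delta_k(runs: pd.DataFrame) -> DeltaKResult:
    """Evanno ΔK model choice from a (K, replicate, lnP) table.

    Needs at least 3 consecutive K values with >= 2 replicates each; ΔK is
    defined for interior K. A zero replicate sd yields an infinite ΔK
    sentinel (warned); if every ΔK is (numerically) zero the selection is
    flagged ambiguous.
    """
    runs = validate_cluster_runs(runs)
    ks = np.array(sorted(runs["K"].unique()))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("DeltaK needs >= 3 consecutive K values")
    reps_per_k = runs.groupby("K")["replicate"].nunique()
    if (reps_per_k < 2).any():
        raise ValueError("DeltaK needs >= 2 replicates for every K")

    mean_l = runs.groupby("K")["lnP"].mean().reindex(ks)
    sd_l = runs.groupby("K")["lnP"].std(ddof=1).reindex(ks)

    pivot = runs.pivot_table(index="replicate", columns="K", values="lnP", aggfunc="mean")
    aligned = not pivot.isna().any().any()

    rows = []
    for k in ks[1:-1]:
        if aligned:
            lpp = pivot[k + 1] - 2.0 * pivot[k] + pivot[k - 1]
            mean_abs_lpp = float(lpp.abs().mean())
        else:
            mean_abs_lpp = float(abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1]))
        sd = float(sd_l[k])
        if sd == 0.0:
            warnings.warn(f"K={k}: zero replicate sd; DeltaK reported as inf", stacklevel=2)
            dk = np.inf if mean_abs_lpp > 0 else 0.0
        else:
            dk = mean_abs_lpp / sd
        rows.append({"K": int(k), "mean_lnP": float(mean_l[k]), "sd_lnP": sd, "mean_abs_lpp": mean_abs_lpp, "delta_k": dk})
    table = pd.DataFrame(rows)
    best = table.loc[table["delta_k"].idxmax()]
    ambiguous = bool(np.all(table["delta_k"] < 1e-12))
    return DeltaKResult(table=table, selected_k=int(best["K"]), ambiguous=ambiguous)


# --------------------------------------------------------------------------- #
# Assignments and admixture
# --------------------------------------------------------------------------- #
def assign_and_flag(m: MembershipMatrix, admix_threshold: float = 0.7) -> pd.DataFrame:
    """Per-site mean membership, majority assignment and admixture flag.

    A site is flagged admixed when the maximum of its mean membership falls
    below ``admix_threshold``.
    """
    if m.sites is None:
        raise ValueError("membership matrix carries no site mapping")
    df = pd.DataFrame(m.q, columns=[f"q{i + 1}" for i in range(m.k)])
    df["site"] = m.sites
    mean_q = df.groupby("site").mean()
    if (mean_q.index.value_counts() < 1).any() or mean_q.empty:
        raise ValueError("empty site in membership matrix")
    out = pd.DataFrame(index=mean_q.index)
    out["assigned"] = mean_q.to_numpy().argmax(axis=1)
    out["max_membership"] = mean_q.max(axis=1)
    out["admixed"] = out["max_membership"] < admix_threshold
    return pd.concat([mean_q, out], axis=1)


# --------------------------------------------------------------------------- #
# Two-step hierarchical workflow
# --------------------------------------------------------------------------- #
def hierarchical_workflow(
    g: GenotypeMatrix,
    level1: Dict[str, int],
    admixed_sites: Iterable[str] = (),
    outdir=None,
) -> Dict[int, GenotypeMatrix]:
    """Split genotypes into per level-1 group subsets for the second step.

    Admixed sites are excluded from every subset; groups with fewer than 2
    remaining sites are skipped with a warning. When ``outdir`` is given,
    each subset is written as a GenePop file ready for external clustering.
    """
    missing = [s for s in g.sites if s not in level1]
    if missing:
        raise ValueError(f"level-1 assignment does not cover sites: {missing}")
    admixed = set(admixed_sites)
    subsets: Dict[int, GenotypeMatrix] = {}
    for group in sorted(set(level1.values())):
        keep = [s for s in g.sites if level1[s] == group and s not in admixed]
        if len(keep) < 2:
            warnings.warn(f"level-1 group {group}: fewer than 2 sites after exclusions; skipped", stacklevel=2)
            continue
        sub = g.subset_sites(keep)
        subsets[group] = sub
        if outdir is not None:
            from pathlib import Path

            path = Path(outdir) / f"level1_group{group}.gen"
            write_genepop(sub, path, title=f"level-1 group {group} subset")
            log.info("wrote %s (%d sites)", path, len(keep))
    return subsets


def combine_levels(level1: Dict[str, int], level2_per_group: Dict[int, Dict[str, int]]) -> pd.DataFrame:
    """Bookkeeping table mapping each site to its (level1, level2) labels.

    ``level2_per_group`` maps a level-1 group id to the within-group
    level-2 assignment read back from the second clustering round. The
    final label enumerates (level1, level2) pairs.
    """
    rows = []
    for site, l1 in level1.items():
        l2 = level2_per_group.get(l1, {}).get(site)
        rows.append({"site": site, "level1": l1, "level2": l2})
    df = pd.DataFrame(rows).set_index("site")
    pairs = df.dropna().apply(lambda r: (r["level1"], r["level2"]), axis=1)
    codes = {pair: i for i, pair in enumerate(sorted(pairs.unique()))}
    df["final_label"] = pairs.map(codes)
    return df
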