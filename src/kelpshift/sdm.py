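"""Distribution-modelling track: monotone boosted trees, hindcast, range shifts.

The model is a boosted-regression-tree classifier (gradient boosting on
Bernoulli deviance, xgboost backend) of presence vs pseudo-absence, with
hard monotone constraints encoding physiology: responses are forced
non-increasing in maximum temperature and ice thickness and non-decreasing
in nutrients, salinity and minimum temperature. The surrounding procedure:

1. spatial pruning of records below the correlogram-derived autocorrelation
   distance (Moran's I per distance class, permutation significance);
2. pseudo-absences matched 1:1 with presences on unoccupied habitat cells;
3. tenfold cross-validation over independent latitudinal bands to select
   the hyper-parameters (number of trees, tree complexity, learning rate);
4. relative predictor contributions by deviance-explained increments and a
   stepwise parsimony reduction;
5. physiological tolerance limits read off partial response curves at the
   max-sensitivity+specificity threshold tau;
6. binary present/glacial surfaces, range-shift areas per region
   ((present - LGM) / present * 100) and the glacial refugium raster;
7. Schoener's D niche overlap between suitability surfaces.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .geo import cell_area_km2, pairwise_haversine_km
from .stack import EnvStack, GeometryError
from .synthdata import OccurrenceSet

log = logging.getLogger(__name__)

#: monotone direction per predictor: -1 forces a non-increasing response
MONOTONE_DIRECTIONS: Dict[str, int] = {
    "max_temperature": -1,
    "ice_thickness": -1,
    "min_temperature": +1,
    "nitrate": +1,
    "phosphate": +1,
    "salinity": +1,
}


def full_hyper_grid() -> List[Dict]:
    """The complete hyper-parameter grid: trees 50..1000 step 50, complexity
    1..6, learning rate {0.01, 0.005, 0.001} (360 combinations)."""
    return [
        {"n_trees": t, "complexity": c, "learning_rate": lr}
        for t, c, lr in itertools.product(range(50, 1001, 50), range(1, 7), (0.01, 0.005, 0.001))
    ]


def default_hyper_grid() -> List[Dict]:
    """A small sub-grid of :func:`full_hyper_grid` used by default so a full
    cross-validated search stays interactive on one CPU."""
    return [
        {"n_trees": t, "complexity": c, "learning_rate": lr}
        for t, c, lr in itertools.product((500, 1000), (1, 2, 3), (0.01,))
    ]


def _make_model(hypers: Dict, predictors: Sequence[str], monotone: Dict[str, int], seed: int = 0) -> XGBClassifier:
    cst = tuple(int(monotone.get(p, 0)) for p in predictors)
    return XGBClassifier(
        n_estimators=int(hypers["n_trees"]),
        max_depth=int(hypers["complexity"]),
        learning_rate=float(hypers["learning_rate"]),
        monotone_constraints=cst,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="exact",
        n_jobs=1,
        random_state=seed,
        base_score=0.5,
        verbosity=0,
    )


# --------------------------------------------------------------------------- #
# Correlogram pruning
# --------------------------------------------------------------------------- #
def _morans_i(z: np.ndarray, w: np.ndarray) -> float:
    zc = z - z.mean()
    denom = float(zc @ zc)
    wsum = w.sum()
    if wsum == 0 or denom == 0:
        return 0.0
    return float(len(z) / wsum * (zc @ w @ zc) / denom)


def correlogram_prune(
    points: OccurrenceSet,
    stack: EnvStack,
    seed: int = 0,
    class_width_km: Optional[float] = None,
    n_classes: int = 10,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> Tuple[OccurrenceSet, float, pd.DataFrame]:
    """Spatial thinning below the correlogram-derived autocorrelation distance.

    Moran's I of every predictor is evaluated per distance class (default
    width: twice the cell size in km) with one-sided permutation
    significance (``n_perm`` shuffles). The pruning distance is the upper
    bound of the first class in which no predictor is significantly
    positively autocorrelated; if every class is significant the maximum
    tested distance is used with a warning. Pruning then keeps one
    seeded-random representative per conflict neighbourhood: records are
    visited in random order and kept only if no kept record lies within the
    pruning distance.
    """
    df = points.data.reset_index(drop=True)
    if len(df) < 20:
        raise ValueError("correlogram needs at least 20 records")
    if class_width_km is None:
        class_width_km = 2.0 * stack.resolution * 111.32
    env = stack.extract(df["lon"].to_numpy(), df["lat"].to_numpy())
    dist = pairwise_haversine_km(df["lon"].to_numpy(), df["lat"].to_numpy())
    rng = np.random.default_rng(seed)

    rows = []
    prune_km = None
    for c in range(1, n_classes + 1):
        lo, hi = (c - 1) * class_width_km, c * class_width_km
        w = ((dist > lo) & (dist <= hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        any_sig = False
        for name in env.columns:
            z = env[name].to_numpy(dtype=float)
            i_obs = _morans_i(z, w)
            if w.sum() == 0:
                rows.append({"class": c, "upper_km": hi, "predictor": name, "I": np.nan, "p": np.nan})
                continue
            count = 0
            for _ in range(n_perm):
                if _morans_i(z[rng.permutation(len(z))], w) >= i_obs:
                    count += 1
            p = (1 + count) / (1 + n_perm)
            sig = (p <= alpha) and (i_obs > 0)
            any_sig |= sig
            rows.append({"class": c, "upper_km": hi, "predictor": name, "I": i_obs, "p": p})
        if not any_sig and prune_km is None:
            prune_km = hi
            break
    correlogram = pd.DataFrame(rows)
    if prune_km is None:
        prune_km = n_classes * class_width_km
        warnings.warn("predictors significantly autocorrelated up to the maximum tested distance", stacklevel=2)

    order = rng.permutation(len(df))
    kept: List[int] = []
    for i in order:
        if all(dist[i, j] >= prune_km for j in kept):
            kept.append(i)
    kept_df = df.iloc[sorted(kept)].reset_index(drop=True)
    log.info("correlogram_prune: distance %.1f km, kept %d of %d records", prune_km, len(kept_df), len(df))
    return OccurrenceSet(kept_df), float(prune_km), correlogram


# --------------------------------------------------------------------------- #
# Pseudo-absences
# --------------------------------------------------------------------------- #
def sample_pseudo_absences(points: OccurrenceSet, stack: EnvStack, seed: int = 0) -> OccurrenceSet:
    """One pseudo-absence per presence, on habitat cells without presences."""
    pres = points.presences
    n = len(pres)
    rows, cols = stack.cell_of(pres["lon"].to_numpy(), pres["lat"].to_numpy())
    occupied = set(zip(rows.tolist(), cols.tolist()))
    hr, hc = np.nonzero(stack.habitat_mask)
    candidates = [(r, c) for r, c in zip(hr.tolist(), hc.tolist()) if (r, c) not in occupied]
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} unoccupied habitat cells for {n} pseudo-absences")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates), size=n, replace=False)
    rr = np.array([candidates[i][0] for i in pick])
    cc = np.array([candidates[i][1] for i in pick])
    absent = pd.DataFrame(
        {"lon": stack.lon[cc], "lat": stack.lat[rr], "label": "pseudo_absence", "source": "sampled"}
    )
    return OccurrenceSet(pd.concat([points.data, absent], ignore_index=True))


def training_table(points: OccurrenceSet, stack: EnvStack) -> pd.DataFrame:
    """Labelled predictor table for model fitting (y = 1 for presence)."""
    df = points.data.reset_index(drop=True)
    env = stack.extract(df["lon"].to_numpy(), df["lat"].to_numpy())
    env.insert(0, "lat", df["lat"].to_numpy())
    env.insert(0, "lon", df["lon"].to_numpy())
    env["y"] = (df["label"] == "presence").astype(int)
    return env


# --------------------------------------------------------------------------- #
# Threshold selection
# --------------------------------------------------------------------------- #
def select_threshold(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity.

    Candidates are the unique scores; a point is predicted present when its
    score >= tau. Ties resolve to the higher sensitivity, then the lower
    tau. Returns (tau, sensitivity, specificity); a degenerate best of
    sens + spec <= 1 is logged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("threshold selection needs both classes")
    pos, neg = labels == 1, labels == 0
    best = None
    for tau in np.unique(scores):
        pred = scores >= tau
        sens = float(pred[pos].mean())
        spec = float((~pred[neg]).mean())
        key = (sens + spec, sens, -tau)
        if best is None or key > best[0]:
            best = (key, tau, sens, spec)
    _, tau, sens, spec = best
    if sens + spec <= 1.0:
        log.debug("degenerate threshold: best sensitivity+specificity = %.3f", sens + spec)
    return float(tau), sens, spec


# --------------------------------------------------------------------------- #
# Deviance
# --------------------------------------------------------------------------- #
def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def deviance_explained(y: np.ndarray, p: np.ndarray) -> float:
    """1 - D_model / D_null (null = intercept-only prevalence model)."""
    y = np.asarray(y, dtype=float)
    p_null = np.full_like(y, y.mean())
    d_null = bernoulli_deviance(y, p_null)
    if d_null <= 0:
        raise ValueError("null deviance is zero; labels are constant")
    return 1.0 - bernoulli_deviance(y, p) / d_null


# --------------------------------------------------------------------------- #
# Cross-validated fit
# --------------------------------------------------------------------------- #
@dataclass
class FittedSDM:
    model: XGBClassifier
    predictors: List[str]
    monotone: Dict[str, int]
    hypers: Dict
    cv_auc_mean: float
    cv_auc_sd: float
    cv_sens_mean: float
    cv_sens_sd: float
    final_auc: float
    final_sensitivity: float
    threshold: float
    cv_table: pd.DataFrame
    train: pd.DataFrame = field(repr=False, default=None)

    def predict_proba_frame(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks predictors {missing}")
        return self.model.predict_proba(frame[self.predictors].to_numpy())[:, 1]


def latitudinal_bands(lat: np.ndarray, n_bands: int = 10) -> np.ndarray:
    """Equal-count latitude-quantile fold labels (0..n_bands-1)."""
    return pd.qcut(pd.Series(lat).rank(method="first"), n_bands, labels=False).to_numpy()


def fit_brt_cv(
    data: pd.DataFrame,
    predictors: Optional[Sequence[str]] = None,
    hyper_grid: Optional[List[Dict]] = None,
    n_bands: int = 10,
    monotone: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> FittedSDM:
    """Hyper-parameter search with latitudinal-band cross-validation.

    ``data`` needs columns lon, lat, y and the predictors. For every grid
    combination, the mean held-out AUC across the 10 latitude-band folds is
    computed; the best combination (ties: fewer trees, lower complexity,
    higher learning rate) is refit on all records with monotone
    constraints. Per-fold sensitivity is taken at that fold's
    max-sens+spec threshold. Folds with one class are skipped (logged);
    more than 2 skipped folds abort.
    """
    monotone = monotone or MONOTONE_DIRECTIONS
    if predictors is None:
        predictors = [c for c in data.columns if c not in ("lon", "lat", "y")]
    predictors = list(predictors)
    hyper_grid = hyper_grid or default_hyper_grid()
    y = data["y"].to_numpy()
    bands = latitudinal_bands(data["lat"].to_numpy(), n_bands)
    both = sum(1 for b in range(n_bands) if len(np.unique(y[bands == b])) == 2)
    if both < n_bands - 2:
        raise ValueError(f"only {both} of {n_bands} latitudinal bands contain both classes")

    x = data[predictors].to_numpy()
    folds = []
    skipped = 0
    for b in range(n_bands):
        test = bands == b
        if len(np.unique(y[test])) < 2 or len(np.unique(y[~test])) < 2:
            skipped += 1
            log.info("fold %d skipped: single class", b)
            continue
        folds.append((~test, test))
    if skipped > 2:
        raise ValueError(f"{skipped} folds with a single class")

    results = []
    for hypers in hyper_grid:
        aucs, senss = [], []
        for train, test in folds:
            m = _make_model(hypers, predictors, monotone, seed)
            m.fit(x[train], y[train])
            p = m.predict_proba(x[test])[:, 1]
            aucs.append(roc_auc_score(y[test], p))
            tau, sens, _ = select_threshold(p, y[test])
            senss.append(sens)
        results.append(
            {
                **hypers,
                "cv_auc_mean": float(np.mean(aucs)),
                "cv_auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "cv_sens_mean": float(np.mean(senss)),
                "cv_sens_sd": float(np.std(senss, ddof=1)) if len(senss) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(results)
    # best by AUC; ties -> cheapest model
    table = table.sort_values(
        by=["cv_auc_mean", "n_trees", "complexity", "learning_rate"],
        ascending=[False, True, True, False],
        kind="mergesort",
    )
    best = table.iloc[0]
    hypers = {"n_trees": int(best["n_trees"]), "complexity": int(best["complexity"]), "learning_rate": float(best["learning_rate"])}
    model = _make_model(hypers, predictors, monotone, seed)
    model.fit(x, y)
    p_all = model.predict_proba(x)[:, 1]
    tau, final_sens, _ = select_threshold(p_all, y)
    final_auc = float(roc_auc_score(y, p_all))
    return FittedSDM(
        model=model,
        predictors=predictors,
        monotone=monotone,
        hypers=hypers,
        cv_auc_mean=float(best["cv_auc_mean"]),
        cv_auc_sd=float(best["cv_auc_sd"]),
        cv_sens_mean=float(best["cv_sens_mean"]),
        cv_sens_sd=float(best["cv_sens_sd"]),
        final_auc=final_auc,
        final_sensitivity=final_sens,
        threshold=float(tau),
        cv_table=table.reset_index(drop=True),
        train=data.copy(),
    )


# --------------------------------------------------------------------------- #
# Contributions and stepwise parsimony
# --------------------------------------------------------------------------- #
def relative_contributions(
    data: pd.DataFrame,
    predictors: Sequence[str],
    hypers: Dict,
    monotone: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> pd.Series:
    """Per-predictor contribution (%) by deviance-explained increments.

    Contribution of predictor j is the increase in training deviance
    explained when j is added to the model with all other predictors;
    negative raw increments are floored at 0 and the result rescaled to
    sum to 100.
    """
    monotone = monotone or MONOTONE_DIRECTIONS
    predictors = list(predictors)
    y = data["y"].to_numpy()
    full = _make_model(hypers, predictors, monotone, seed)
    full.fit(data[predictors].to_numpy(), y)
    de_full = deviance_explained(y, full.predict_proba(data[predictors].to_numpy())[:, 1])
    if de_full <= 0:
        raise ValueError("full model explains no deviance")
    raw = {}
    for p in predictors:
        rest = [q for q in predictors if q != p]
        if not rest:
            raw[p] = de_full
            continue
        m = _make_model(hypers, rest, monotone, seed)
        m.fit(data[rest].to_numpy(), y)
        de = deviance_explained(y, m.predict_proba(data[rest].to_numpy())[:, 1])
        raw[p] = max(0.0, de_full - de)
    total = sum(raw.values())
    if total == 0:
        # all increments floored: fall back to equal shares
        return pd.Series({p: 100.0 / len(predictors) for p in predictors})
    return pd.Series({p: 100.0 * v / total for p, v in raw.items()}).sort_values(ascending=False)


def stepwise_reduce(
    data: pd.DataFrame,
    predictors: Sequence[str],
    hypers: Dict,
    monotone: Optional[Dict[str, int]] = None,
    tol: float = 1e-6,
    seed: int = 0,
) -> Tuple[List[str], pd.DataFrame]:
    """Drop predictors least-contributive-first while parsimony is free.

    A removal is accepted while the deviance explained of the reduced
    model stays within ``tol`` of the full model's; the scan stops before
    the first removal that loses fit. Returns (retained predictors,
    removal log).
    """
    monotone = monotone or MONOTONE_DIRECTIONS
    current = list(predictors)
    y = data["y"].to_numpy()

    def devexp(preds: List[str]) -> float:
        m = _make_model(hypers, preds, monotone, seed)
        m.fit(data[preds].to_numpy(), y)
        return deviance_explained(y, m.predict_proba(data[preds].to_numpy())[:, 1])

    de_full = devexp(current)
    log_rows = []
    while len(current) > 1:
        contrib = relative_contributions(data, current, hypers, monotone, seed)
        candidate = contrib.index[-1]
        reduced = [p for p in current if p != candidate]
        de_reduced = devexp(reduced)
        accept = (de_full - de_reduced) <= tol
        log_rows.append(
            {"removed": candidate, "devexp_reduced": de_reduced, "devexp_full": de_full, "accepted": accept}
        )
        if not accept:
            break
        current = reduced
    return current, pd.DataFrame(log_rows)


# --------------------------------------------------------------------------- #
# Tolerance limits
# --------------------------------------------------------------------------- #
def response_tolerance_limits(model: FittedSDM, n_grid: int = 512) -> pd.DataFrame:
    """Tolerance limit per predictor from partial response curves.

    Each curve evaluates the model on a ``n_grid``-point grid over the
    predictor's observed range with all other predictors fixed at their
    record means. The limit is the predictor value where the response
    crosses the binarisation threshold tau (linear interpolation): the
    upper crossing for negative-monotone predictors (a tolerance maximum),
    the lower crossing for positive-monotone ones (a tolerance minimum).
    A response violating its monotone constraint raises; a curve that
    never crosses tau reports the range boundary with a flag.
    """
    if model.train is None:
        raise ValueError("model carries no training records")
    means = model.train[model.predictors].mean()
    tau = model.threshold
    rows = []
    for pred in model.predictors:
        lo, hi = model.train[pred].min(), model.train[pred].max()
        grid = np.linspace(lo, hi, n_grid)
        frame = pd.DataFrame({p: np.full(n_grid, means[p]) for p in model.predictors})
        frame[pred] = grid
        resp = model.predict_proba_frame(frame)
        direction = model.monotone.get(pred, 0)
        diffs = np.diff(resp)
        if direction < 0 and np.any(diffs > 1e-9):
            raise RuntimeError(f"monotone constraint violated for {pred} (should be non-increasing)")
        if direction > 0 and np.any(diffs < -1e-9):
            raise RuntimeError(f"monotone constraint violated for {pred} (should be non-decreasing)")
        limit, flagged = _crossing(grid, resp, tau, direction)
        rows.append(
            {
                "predictor": pred,
                "direction": direction,
                "kind": "max" if direction < 0 else "min",
                "limit": limit,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def _crossing(grid: np.ndarray, resp: np.ndarray, tau: float, direction: int) -> Tuple[float, bool]:
    above = resp >= tau
    if above.all():
        return (float(grid[-1]), True) if direction <= 0 else (float(grid[0]), True)
    if not above.any():
        return (float(grid[0]), True) if direction <= 0 else (float(grid[-1]), True)
    if direction < 0:
        i = int(np.nonzero(above)[0][-1])  # last point at/above tau
        if i == len(grid) - 1:
            return float(grid[-1]), True
        x0, x1, y0, y1 = grid[i], grid[i + 1], resp[i], resp[i + 1]
    else:
        i = int(np.nonzero(above)[0][0])  # first point at/above tau
        if i == 0:
            return float(grid[0]), True
        x0, x1, y0, y1 = grid[i - 1], grid[i], resp[i - 1], resp[i]
    if y1 == y0:
        return float(x1), False
    return float(x0 + (tau - y0) * (x1 - x0) / (y1 - y0)), False


# --------------------------------------------------------------------------- #
# Prediction, binarisation, areas
# --------------------------------------------------------------------------- #
def predict_and_binarize(model: FittedSDM, stack: EnvStack) -> Tuple[np.ndarray, np.ndarray]:
    """Suitability (NaN off-habitat) and >= tau binary surfaces for a stack."""
    missing = [p for p in model.predictors if p not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks predictors {missing}")
    suit = np.full(stack.shape, np.nan)
    rows, cols = np.nonzero(stack.habitat_mask)
    frame = pd.DataFrame({p: stack.layers[p][rows, cols] for p in model.predictors})
    suit[rows, cols] = model.predict_proba_frame(frame)
    binary = np.zeros(stack.shape, dtype=bool)
    binary[rows, cols] = suit[rows, cols] >= model.threshold
    return suit, binary


def percent_change(lgm_area: float, present_area: float) -> float:
    """Range change from the glacial period to the present, % of present area."""
    if present_area == 0:
        return np.nan
    return (present_area - lgm_area) / present_area * 100.0


def area_and_change(
    binary_lgm: np.ndarray,
    binary_present: np.ndarray,
    lat: np.ndarray,
    resolution: float,
    regions: Optional[Dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Range-shift accounting per region and overall.

    Cell areas are (resolution * 111.32 km)^2 * cos(latitude); areas are
    reported in 10^3 km^2 and the change column is
    (present - LGM) / present * 100. ``regions`` maps region name to a
    boolean cell mask partitioning the analysis cells; the "all" row sums
    them.
    """
    binary_lgm = np.asarray(binary_lgm, dtype=bool)
    binary_present = np.asarray(binary_present, dtype=bool)
    if binary_lgm.shape != binary_present.shape:
        raise GeometryError("binary maps are not co-registered")
    area = cell_area_km2(np.asarray(lat)[:, None], resolution) * np.ones_like(binary_lgm, dtype=float)
    if regions is None:
        regions = {}
    rows = []
    for name, mask in regions.items():
        a_l = float(area[mask & binary_lgm].sum()) / 1e3
        a_p = float(area[mask & binary_present].sum()) / 1e3
        rows.append({"region": name, "lgm_area": a_l, "present_area": a_p, "pct_change": percent_change(a_l, a_p)})
    a_l = float(area[binary_lgm].sum()) / 1e3
    a_p = float(area[binary_present].sum()) / 1e3
    rows.append({"region": "all", "lgm_area": a_l, "present_area": a_p, "pct_change": percent_change(a_l, a_p)})
    return pd.DataFrame(rows).set_index("region")


def schoener_overlap(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Schoener's D between two suitability surfaces (cell-normalised)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError("maps are not co-registered")
    valid = np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        raise ValueError("maps share no valid cells")
    pa, pb = a[valid], b[valid]
    sa, sb = pa.sum(), pb.sum()
    if sa == 0 and sb == 0:
        return 1.0  # both empty: identical (degenerate)
    if sa == 0 or sb == 0:
        return 0.0
    return float(1.0 - 0.5 * np.abs(pa / sa - pb / sb).sum())
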