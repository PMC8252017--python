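"""Modern-ecoregion stage: guild extrema, skewness, spatial autocovariate,
and the boosted regression-tree model of maximum lagomorph body mass.

Per ecoregion the largest leporid lagomorph (``m_maxlag``) and the
smallest ungulate-type herbivore (``m_minuth``; artiodactyls,
perissodactyls, and ungulate-like or leporid-like caviomorph rodents,
excluding omnivorous or semiaquatic taxa) are identified from species
lists.  log10 m_maxlag is then modeled on m_minuth plus environmental
covariates with gradient-boosted regression trees (tree complexity 3,
learning rate 0.005, bag fraction 0.75; number of trees by
cross-validation), in two passes: a first fit without a spatial term,
whose residuals supply a neighbor-mean autocovariate for the final fit.
Boosting itself is delegated to scikit-learn's GradientBoostingRegressor;
this module owns the hyperparameters, the CV tree-count selection, the
autocovariate loop, and the influence/partial-dependence extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "SkewnessStat", "BRTResult", "DEFAULT_BRT_HYPERPARAMS",
    "UTH_CLADES", "EXCLUDED_UTH_GENERA",
    "guild_extrema", "skewness_g1", "neighbor_mean_residual", "brt_model",
]

#: Clade tags counting toward the ungulate-type-herbivore minimum.
UTH_CLADES = frozenset({"artiodactyl", "perissodactyl", "caviomorph_uth"})

#: Omnivorous or semiaquatic genera excluded from the UTH set
#: (suids, tayassuids, hippopotamids, capybara).
EXCLUDED_UTH_GENERA = frozenset({
    "Sus", "Babyrousa", "Hylochoerus", "Phacochoerus", "Porcula",
    "Potamochoerus", "Tayassu", "Pecari", "Catagonus", "Dicotyles",
    "Hippopotamus", "Choeropsis", "Hexaprotodon", "Hydrochoerus",
})

DEFAULT_BRT_HYPERPARAMS = {
    "tree_complexity": 3,
    "learning_rate": 0.005,
    "bag_fraction": 0.75,
}


def guild_extrema(species: pd.DataFrame) -> tuple[float, float]:
    """(m_maxlag, m_minuth) in kg for one ecoregion's species list.

    ``species`` has columns ``species``, ``clade`` (leporid, ochotonid,
    artiodactyl, perissodactyl, caviomorph_uth, ...), ``mass_kg`` and
    optionally ``excluded`` (omnivorous/semiaquatic flag).  m_maxlag is
    the maximum over leporids; m_minuth the minimum over the UTH clades
    after dropping flagged rows and the built-in excluded genera.  A
    missing guild yields NaN.
    """
    if species.empty:
        return (float("nan"), float("nan"))
    df = species.copy()
    genus = df["species"].astype(str).str.split().str[0]
    excl = genus.isin(EXCLUDED_UTH_GENERA)
    if "excluded" in df.columns:
        excl |= df["excluded"].fillna(False).astype(bool)
    lep = df[df["clade"] == "leporid"]["mass_kg"]
    uth = df[df["clade"].isin(UTH_CLADES) & ~excl]["mass_kg"]
    m_maxlag = float(lep.max()) if len(lep) else float("nan")
    m_minuth = float(uth.min()) if len(uth) else float("nan")
    return (m_maxlag, m_minuth)


@dataclass(frozen=True)
class SkewnessStat:
    g1: float
    n: int


def skewness_g1(values) -> SkewnessStat:
    """Sample-size-adjusted Fisher-Pearson skewness coefficient
    ``G1 = sqrt(n(n-1))/(n-2) * m3 / m2**1.5`` with central sample
    moments m2, m3."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"skewness needs n >= 3, got {n}")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("values must be finite")
    d = x - x.mean()
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    if m2 == 0:
        return SkewnessStat(g1=0.0, n=n)
    g1 = np.sqrt(n * (n - 1)) / (n - 2) * m3 / m2**1.5
    return SkewnessStat(g1=float(g1), n=n)


def _neighbor_map(adjacency, valid_ids) -> dict:
    """Normalize adjacency (edge list or dict) into id -> neighbor list."""
    valid = set(valid_ids)
    if isinstance(adjacency, dict):
        nbrs = {k: list(v) for k, v in adjacency.items()}
        refs = set(nbrs) | {x for v in nbrs.values() for x in v}
    else:
        nbrs = {}
        refs = set()
        for a, b in adjacency:
            nbrs.setdefault(a, []).append(b)
            nbrs.setdefault(b, []).append(a)
            refs.update((a, b))
    dangling = refs - valid
    if dangling:
        raise InvalidArgumentError(
            f"adjacency references unknown ecoregions: {sorted(dangling)[:5]}")
    return nbrs


def neighbor_mean_residual(residuals: pd.Series, adjacency) -> pd.Series:
    """Spatial autocovariate: mean residual over each ecoregion's
    neighbors.  ``adjacency`` is an undirected edge list of id pairs or a
    dict id -> neighbor ids.  Ecoregions with no neighbors get 0 (with a
    warning)."""
    nbrs = _neighbor_map(adjacency, residuals.index)
    out = pd.Series(0.0, index=residuals.index)
    isolated = []
    for rid in residuals.index:
        nn = [x for x in nbrs.get(rid, []) if x in residuals.index]
        if nn:
            out[rid] = float(residuals.loc[nn].mean())
        else:
            isolated.append(rid)
    if isolated:
        warnings.warn(f"{len(isolated)} ecoregions have no neighbors; "
                      "autocovariate set to 0", stacklevel=2)
    return out


@dataclass
class BRTResult:
    """Fitted two-pass boosted regression-tree model."""

    model: GradientBoostingRegressor = field(repr=False)
    n_trees: int
    relative_influence: pd.Series          # percent, sums to 100
    partial_dependence: dict               # predictor -> (grid, effect)
    cv_deviance: float                     # mean held-out squared error
    deviance_explained: float              # 1 - cv_deviance / var(y)
    residuals: pd.Series = field(repr=False, default=None)
    autocovariate: pd.Series = field(repr=False, default=None)


def _cv_select_n_trees(X, y, params, max_trees, cv_folds, seed):
    """Pick the boosting length minimizing K-fold held-out squared error."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errs = np.zeros((cv_folds, max_trees))
    for f, (tr, te) in enumerate(kf.split(X)):
        gbm = GradientBoostingRegressor(n_estimators=max_trees,
                                        random_state=seed + f, **params)
        gbm.fit(X[tr], y[tr])
        for i, pred in enumerate(gbm.staged_predict(X[te])):
            errs[f, i] = np.mean((y[te] - pred) ** 2)
    mean_err = errs.mean(axis=0)
    best = int(np.argmin(mean_err)) + 1
    return best, float(mean_err[best - 1])


def _partial_dependence_1d(model, X, j, n_grid=25):
    """Mean-response partial dependence of feature j on its value grid."""
    grid = np.linspace(X[:, j].min(), X[:, j].max(), n_grid)
    effect = np.empty(n_grid)
    Xw = X.copy()
    for g, v in enumerate(grid):
        Xw[:, j] = v
        effect[g] = float(model.predict(Xw).mean())
    return grid, effect


def brt_model(table: pd.DataFrame, adjacency, response: str = "log10_m_maxlag",
              predictors: list[str] | None = None,
              hyperparams: dict | None = None, max_trees: int = 2000,
              cv_folds: int = 5, seed: int = 0) -> BRTResult:
    """Two-pass boosted regression-tree model of the response.

    Pass 1 fits the response on the predictors alone; its residuals give
    each ecoregion's neighbor-mean spatial autocovariate (computed once,
    no fixpoint iteration); pass 2 refits with the autocovariate
    included.  The number of trees is chosen by ``cv_folds``-fold
    cross-validation on the pass-2 design.  Relative influences are
    normalized to sum to 100.
    """
    hp = dict(DEFAULT_BRT_HYPERPARAMS, **(hyperparams or {}))
    params = {
        "max_depth": int(hp["tree_complexity"]),
        "learning_rate": float(hp["learning_rate"]),
        "subsample": float(hp["bag_fraction"]),
    }
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in (response, "ecoregion_id")]
    data = table.dropna(subset=[response, *predictors])
    if len(data) < 50:
        raise InsufficientDataError(
            f"BRT needs >=50 complete rows, got {len(data)}")
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDesignError("response is constant")
    X1 = data[predictors].to_numpy(dtype=float)

    # pass 1: no spatial term; modest fixed length is enough for residuals
    gbm1 = GradientBoostingRegressor(n_estimators=min(max_trees, 500),
                                     random_state=seed, **params)
    gbm1.fit(X1, y)
    resid = pd.Series(y - gbm1.predict(X1), index=data.index)
    # rows dropped for missing data leave the neighbor graph silently
    if not isinstance(adjacency, dict):
        adjacency = [(a, b) for a, b in adjacency
                     if a in data.index and b in data.index]
    else:
        adjacency = {k: [x for x in v if x in data.index]
                     for k, v in adjacency.items() if k in data.index}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        autocov = neighbor_mean_residual(resid, adjacency)

    # pass 2: refit with autocovariate; CV-selected boosting length
    cols2 = [*predictors, "spatial_autocov"]
    X2 = np.column_stack([X1, autocov.to_numpy()])
    n_trees, cv_dev = _cv_select_n_trees(X2, y, params, max_trees,
                                         cv_folds, seed)
    gbm2 = GradientBoostingRegressor(n_estimators=n_trees,
                                     random_state=seed, **params)
    gbm2.fit(X2, y)

    infl = pd.Series(gbm2.feature_importances_, index=cols2)
    total = infl.sum()
    infl = infl / total * 100.0 if total > 0 else infl
    pd_curves = {c: _partial_dependence_1d(gbm2, X2, j)
                 for j, c in enumerate(cols2)}
    return BRTResult(
        model=gbm2, n_trees=n_trees, relative_influence=infl,
        partial_dependence=pd_curves, cv_deviance=cv_dev,
        deviance_explained=float(1.0 - cv_dev / np.var(y)),
        residuals=pd.Series(y - gbm2.predict(X2), index=data.index),
        autocovariate=autocov,
    )
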