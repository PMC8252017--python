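"""AICc model selection over candidate drivers of maximum lagomorph mass.

Eleven linear regression models of the per-bin maximum lagomorph log10
body mass are compared: five single-predictor models (competitive
ceiling, minimum perissodactyl mass, benthic d18O, ungulate hypsodonty,
glires sampling probability) and six stated two-predictor combinations.
Each model carries a temporal autocovariate: the residual of the
preceding time bin from a preliminary fit that ignored autocorrelation.
Models are ranked by the small-sample Akaike information criterion on an
identical complete-case row set.

Age and mass uncertainty is propagated by pseudo-replication: locality
ages are redrawn uniformly within their bounds (one draw per locality,
shared by its taxa), log10 masses normally around their point estimates,
the per-bin series is rebuilt, and the roster refit; best-model tallies
and delta-AICc distributions are aggregated over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import EnergyLine
from .exceptions import InsufficientDataError, InvalidArgumentError
from .fossil_timeseries import (
    BinGrid, DEFAULT_GRID, DEFAULT_REGIMES, MAX_AGE_UNCERTAINTY,
    build_series_table,
)

__all__ = [
    "ModelSpec", "MODEL_ROSTER", "ModelComparison",
    "autocov_regression", "aicc", "compare_models",
    "pseudoreplicate_analysis", "ReplicateEnsemble",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an id and its predictor columns."""

    id: int
    predictors: tuple[str, ...]

    @property
    def label(self) -> str:
        return "+".join(self.predictors)


#: The default candidate roster: five singletons and six pairs.
MODEL_ROSTER = (
    ModelSpec(1, ("m_ceiling",)),
    ModelSpec(2, ("m_minper",)),
    ModelSpec(3, ("d18o",)),
    ModelSpec(4, ("h_ung",)),
    ModelSpec(5, ("r_glires",)),
    ModelSpec(6, ("m_ceiling", "r_glires")),
    ModelSpec(7, ("m_minper", "r_glires")),
    ModelSpec(8, ("m_ceiling", "h_ung")),
    ModelSpec(9, ("m_minper", "h_ung")),
    ModelSpec(10, ("m_ceiling", "d18o")),
    ModelSpec(11, ("m_minper", "d18o")),
)


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def autocov_regression(table: pd.DataFrame, response: str,
                       predictors: tuple[str, ...]) -> dict:
    """Two-pass least-squares fit with a lagged-residual autocovariate.

    ``table`` has one row per time bin, oldest first.  Pass 1 regresses
    the response on the predictors by ordinary least squares over the
    complete rows; pass 2 adds, for each row, the pass-1 residual of the
    nearest older complete row as an extra column (rows with no available
    lag are dropped).  Returns coefficients, the Gaussian profile
    log-likelihood, the parameter count ``k`` (intercept + predictors +
    autocovariate + residual variance) and ``n``.
    """
    cols = [response, *predictors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"missing columns: {missing}")
    sub = table[cols].astype(float)
    complete = sub.dropna()
    p = len(predictors)
    if len(complete) < p + 3:
        raise InsufficientDataError(
            f"{len(complete)} complete rows for {p} predictors")
    y1 = complete[response].to_numpy()
    X1 = np.column_stack([np.ones(len(complete))]
                         + [complete[c].to_numpy() for c in predictors])
    _, resid1 = _ols(X1, y1)
    resid_by_row = pd.Series(resid1, index=complete.index)

    # autocovariate: pass-1 residual of the nearest older complete row
    rows, lags = [], []
    prev = None
    for idx in complete.index:
        if prev is not None:
            rows.append(idx)
            lags.append(resid_by_row[prev])
        prev = idx
    if len(rows) < p + 3:
        raise InsufficientDataError("too few rows after lagging")
    sub2 = complete.loc[rows]
    y = sub2[response].to_numpy()
    X = np.column_stack([np.ones(len(sub2))]
                        + [sub2[c].to_numpy() for c in predictors]
                        + [np.array(lags)])
    beta, resid = _ols(X, y)
    n = len(y)
    rss = float(resid @ resid)
    s2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    k = p + 3  # intercept + predictors + autocovariate + residual variance
    names = ["intercept", *predictors, "autocov"]
    return {
        "coefficients": dict(zip(names, beta.astype(float))),
        "loglik": float(loglik),
        "k": k,
        "n": n,
        "rows": list(rows),
        "residuals": resid,
    }


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion
    ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``."""
    if n <= k + 1:
        raise InvalidArgumentError(
            f"AICc correction undefined for n={n}, k={k}")
    return float(-2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class ModelComparison:
    """AICc ranking of a model roster on one series realization."""

    table: pd.DataFrame          # per-model: aicc, delta_aicc, evidence_ratio
    best_id: int
    fits: dict = field(repr=False, default_factory=dict)


def compare_models(series: pd.DataFrame, roster=MODEL_ROSTER,
                   response: str = "m_maxlag") -> ModelComparison:
    """Fit every roster model on an identical complete-case row set and
    rank by AICc.

    Rows with a missing value in the response or in any predictor used by
    any roster model are dropped for all models, so every AICc shares the
    same ``n``.  Evidence ratios are ``exp(0.5 * delta_AICc)`` relative to
    the best model; AICc ties break toward fewer predictors.
    """
    if not roster:
        raise InvalidArgumentError("empty model roster")
    all_cols = {response}
    for spec in roster:
        all_cols.update(spec.predictors)
    aligned = series.copy()
    mask = aligned[sorted(all_cols)].notna().all(axis=1)
    aligned.loc[~mask, list(all_cols)] = np.nan

    rows = []
    fits = {}
    for spec in roster:
        fit = autocov_regression(aligned, response, spec.predictors)
        fits[spec.id] = fit
        rows.append({
            "model_id": spec.id,
            "predictors": spec.label,
            "n_predictors": len(spec.predictors),
            "k": fit["k"],
            "n": fit["n"],
            "loglik": fit["loglik"],
            "aicc": aicc(fit["loglik"], fit["k"], fit["n"]),
        })
    tab = pd.DataFrame(rows).set_index("model_id")
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    tab["evidence_ratio"] = np.exp(np.minimum(0.5 * tab["delta_aicc"], 700.0))
    best_id = int(tab.sort_values(["aicc", "n_predictors"]).index[0])
    return ModelComparison(table=tab, best_id=best_id, fits=fits)


@dataclass
class ReplicateEnsemble:
    """Aggregate of best-model tallies across pseudo-replicates."""

    best_counts: pd.Series        # model_id -> #replicates won
    delta_aicc: pd.DataFrame      # replicates x model_id
    n_replicates: int
    n_failed: int
    point_estimate: ModelComparison | None = None

    @property
    def support_fraction(self) -> pd.Series:
        total = max(self.n_replicates - self.n_failed, 1)
        return self.best_counts / total


def pseudoreplicate_analysis(records: pd.DataFrame, line_lag: EnergyLine,
                             line_ung: EnergyLine, d18o=None, h_ung=None,
                             roster=MODEL_ROSTER, regimes=DEFAULT_REGIMES,
                             grid: BinGrid = DEFAULT_GRID,
                             window: tuple[float, float] = (37.5, 1.5),
                             n_reps: int = 1000, seed: int = 0,
                             max_uncertainty: float = MAX_AGE_UNCERTAINTY,
                             ) -> ReplicateEnsemble:
    """Monte-Carlo propagation of locality-age and body-mass uncertainty.

    Per replicate, one age is drawn uniformly within each locality's
    bounds (shared by all taxa at that locality, independent across
    localities and replicates) and each taxon's log10 mass is drawn
    normally around its point estimate with its model-informed standard
    error; the per-bin series is rebuilt over the analysis window
    (default 37.5-1.5 Ma, excluding the most recent bin) and the roster
    refit.  Replicate substreams are derived from the master seed by
    replicate index, so earlier replicates are unchanged when ``n_reps``
    grows.  Replicates that fail for data sparsity are counted, not
    fatal.
    """
    if n_reps < 1:
        raise InvalidArgumentError("need at least one replicate")
    recs = filter_frame = records.reset_index(drop=True)
    span = filter_frame["age_max"] - filter_frame["age_min"]
    recs = filter_frame[span <= max_uncertainty].reset_index(drop=True)
    locs = recs["locality_id"].to_numpy()
    uniq_locs, loc_inv = np.unique(locs, return_inverse=True)
    lo = recs.groupby("locality_id")["age_min"].first()
    hi = recs.groupby("locality_id")["age_max"].first()
    lo = lo.loc[uniq_locs].to_numpy()
    hi = hi.loc[uniq_locs].to_numpy()
    taxa = recs["taxon"].to_numpy()
    uniq_taxa, taxon_inv = np.unique(taxa, return_inverse=True)
    mass_mean = recs.groupby("taxon")["mass_log10"].mean().loc[uniq_taxa].to_numpy()
    mass_se = (recs.groupby("taxon")["mass_se_log10"].mean()
               .reindex(uniq_taxa).fillna(0.0).to_numpy()
               if "mass_se_log10" in recs.columns
               else np.zeros(len(uniq_taxa)))

    window_bins = grid.window_bins(*window)
    ids = [spec.id for spec in roster]
    counts = pd.Series(0, index=ids, dtype=int)
    deltas = []
    n_failed = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed) % (2**31), rep])
        ages = rng.uniform(lo, hi)[loc_inv]
        masses = mass_mean + rng.standard_normal(len(uniq_taxa)) * mass_se
        rep_recs = recs.copy()
        rep_recs["mass_log10"] = masses[taxon_inv]
        try:
            series = build_series_table(
                rep_recs, line_lag, line_ung, d18o=d18o, h_ung=h_ung,
                regimes=regimes, grid=grid,
                ages=pd.Series(ages, index=rep_recs.index),
                max_uncertainty=max_uncertainty)
            comp = compare_models(series.loc[window_bins], roster)
        except (InsufficientDataError, InvalidArgumentError):
            n_failed += 1
            continue
        counts[comp.best_id] += 1
        deltas.append(comp.table["delta_aicc"])
    delta_df = (pd.DataFrame(deltas).reset_index(drop=True)
                if deltas else pd.DataFrame(columns=ids))

    point = None
    try:
        point_series = build_series_table(
            recs, line_lag, line_ung, d18o=d18o, h_ung=h_ung,
            regimes=regimes, grid=grid, max_uncertainty=max_uncertainty)
        point = compare_models(point_series.loc[window_bins], roster)
    except (InsufficientDataError, InvalidArgumentError):
        pass
    return ReplicateEnsemble(best_counts=counts, delta_aicc=delta_df,
                             n_replicates=n_reps, n_failed=n_failed,
                             point_estimate=point)
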