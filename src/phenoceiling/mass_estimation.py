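"""Allometric body-mass estimation for fossil taxa.

Log10 body mass is regressed on a log10 mandibular or dental dimension
across extant species by lambda-GLS, with intraspecific variation
entering as per-species variance inflation (within-species variance of
the species mean).  Model accuracy is summarized by |D|, the mean
absolute percent prediction error from leave-one-out refits on the
arithmetic (kg) scale.  Fossil measurements are converted to point
estimates and standard errors on the log10 kg scale; a fossil with a
known phylogenetic position uses the conditional-normal new-tip
prediction, otherwise the fixed-effect line with full prediction
variance.  Estimates stay on the log10 scale downstream (the
pseudo-replicate mass draws are normal on log10), with back-transforms
for display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidArgumentError, ValidationError
from .phylo_gls import AllometricFit, pgls_fit, pgls_predict_newtip

__all__ = ["MassModel", "MassEstimate", "species_means", "fit_mass_model",
           "estimate_fossil_mass", "combine_estimates"]


@dataclass
class MassModel:
    """A fitted log10 mass ~ log10 dimension allometry.

    ``intraspecific_var`` is the pooled within-species variance of log10
    mass; ``accuracy`` the leave-one-out mean absolute percent prediction
    error |D| (percent, on the kg scale; NaN when not computed).
    """

    predictor_name: str
    fit: AllometricFit
    intraspecific_var: float
    accuracy: float


@dataclass
class MassEstimate:
    taxon: str
    mean_log10: float
    se_log10: float
    model_used: str

    @property
    def mass_kg(self) -> float:
        return float(10.0 ** self.mean_log10)


def species_means(specimens: pd.DataFrame,
                  dimension_col: str = "dimension_mm",
                  mass_col: str = "mass_kg") -> pd.DataFrame:
    """Per-species log10 means and within-species variances.

    ``specimens`` has one row per individual with columns ``species``,
    the dimension (mm) and the individual body mass (kg).  Returns a
    species-indexed table of mean log10 dimension/mass, their sample
    variances (0 with ``single_specimen=True`` for n=1), and n.
    """
    req = {"species", dimension_col, mass_col}
    missing = req - set(specimens.columns)
    if missing:
        raise ValidationError(f"specimen table missing columns: {sorted(missing)}")
    vals = specimens[[dimension_col, mass_col]].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValidationError("measurements and masses must be positive finite")
    df = specimens.assign(
        _ld=np.log10(specimens[dimension_col].astype(float)),
        _lm=np.log10(specimens[mass_col].astype(float)),
    )
    g = df.groupby("species", sort=True)
    out = pd.DataFrame({
        "mean_log10_dim": g["_ld"].mean(),
        "mean_log10_mass": g["_lm"].mean(),
        "var_log10_dim": g["_ld"].var(ddof=1).fillna(0.0),
        "var_log10_mass": g["_lm"].var(ddof=1).fillna(0.0),
        "n": g.size(),
    })
    out["single_specimen"] = out["n"] == 1
    return out


def _loo_abs_percent_error(table: pd.DataFrame, tree, lam, weights) -> float:
    """Leave-one-out |D|: refit without each species, predict it from the
    fixed-effect line, average |pred - obs| / obs * 100 on the kg scale."""
    errors = []
    for sp in table.index:
        rest = table.drop(index=sp)
        try:
            fit = pgls_fit(rest["mean_log10_dim"], rest["mean_log10_mass"],
                           tree, weights=weights.drop(index=sp)
                           if weights is not None else None, lam=lam)
        except InsufficientDataError:
            continue
        pred = 10.0 ** fit.predict(table.at[sp, "mean_log10_dim"])
        obs = 10.0 ** table.at[sp, "mean_log10_mass"]
        errors.append(abs(pred - obs) / obs * 100.0)
    return float(np.mean(errors)) if errors else float("nan")


def fit_mass_model(species_table: pd.DataFrame, tree,
                   predictor_name: str = "dimension",
                   lam: float | None = None,
                   compute_accuracy: bool = True) -> MassModel:
    """Fit a mass-prediction allometry from a species-mean table.

    ``species_table`` is the output of :func:`species_means`.  The GLS
    uses per-species variance inflation ``var_log10_mass / n`` (the
    sampling variance of each species mean); species with a single
    specimen contribute zero inflation.
    """
    if len(species_table) < 4:
        raise InsufficientDataError(
            f"need >=4 species, got {len(species_table)}")
    weights = species_table["var_log10_mass"] / species_table["n"]
    if (weights <= 0).all():
        weights_arg = None
    else:
        weights_arg = weights
    fit = pgls_fit(species_table["mean_log10_dim"],
                   species_table["mean_log10_mass"],
                   tree, weights=weights_arg, lam=lam)
    pooled = float(np.average(species_table["var_log10_mass"],
                              weights=np.maximum(species_table["n"] - 1, 0))
                   if (species_table["n"] > 1).any() else 0.0)
    acc = (_loo_abs_percent_error(species_table, tree, lam, weights_arg)
           if compute_accuracy else float("nan"))
    return MassModel(predictor_name=predictor_name, fit=fit,
                     intraspecific_var=pooled, accuracy=acc)


def estimate_fossil_mass(model: MassModel, measurement: float, taxon: str = "",
                         placement=None) -> MassEstimate:
    """Estimate a fossil's log10 body mass from one measurement (mm).

    ``placement`` is either ``None`` (taxon of uncertain position: the
    fixed-effect line with full prediction variance, residual plus
    parameter terms) or a ``(tree_with_new_tip, tip_label)`` pair for a
    fossil attached to the reference tree, which then uses the
    conditional-normal prediction.
    """
    if not np.isfinite(measurement) or measurement <= 0:
        raise InvalidArgumentError(
            f"measurement must be positive, got {measurement}")
    x = float(np.log10(measurement))
    fit = model.fit
    if placement is None:
        mean = float(fit.predict(x))
        x0 = np.array([1.0, x])
        var = fit.sigma2 + float(x0 @ fit.param_cov @ x0)
    else:
        tree, tip = placement
        mean, var = pgls_predict_newtip(fit, tree, tip, x)
    return MassEstimate(taxon=taxon, mean_log10=mean,
                        se_log10=float(np.sqrt(max(var, 0.0))),
                        model_used=model.predictor_name)


def combine_estimates(estimates: list[MassEstimate], taxon: str = "") -> MassEstimate:
    """Inverse-variance-weighted combination of specimen-level estimates
    into a species-level mass; zero-variance inputs dominate."""
    if not estimates:
        raise InvalidArgumentError("no estimates to combine")
    means = np.array([e.mean_log10 for e in estimates])
    variances = np.array([e.se_log10**2 for e in estimates])
    if np.any(variances == 0):
        sel = variances == 0
        mean = float(means[sel].mean())
        se = 0.0
    else:
        w = 1.0 / variances
        mean = float(np.sum(w * means) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
    return MassEstimate(taxon=taxon or estimates[0].taxon, mean_log10=mean,
                        se_log10=se, model_used=estimates[0].model_used)
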