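"""From fossil occurrences to per-bin predictor series.

Occurrence records (taxon, clade, locality, age bounds, log10 mass
estimate) are filtered by locality-age uncertainty, grouped into fixed
1.5-Myr time bins starting at 43.5 Ma, and expanded to range-through
presence (a species is assumed present in every bin between its first and
last appearance).  Per bin the module extracts the guild extrema
(maximum lagomorph, minimum artiodactyl, minimum perissodactyl log10
mass), the range-through sampling probability of glires genera on the
empirical-logit scale, bin means of the benthic d18O temperature proxy,
the ungulate hypsodonty index interpolated to bin midpoints, and the
competitive-ceiling predictor that switches between the energy-equivalent
mass of the smallest perissodactyl and the smallest artiodactyl mass by
time window.

Bins are half-open with the older bound inclusive: a boundary age belongs
to the older bin, so every age maps to exactly one bin.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import EnergyLine, energy_equivalent_log10
from .exceptions import InvalidArgumentError

__all__ = [
    "BinGrid", "DEFAULT_GRID", "DEFAULT_REGIMES",
    "filter_localities", "assign_bin", "locality_midpoint_ages",
    "range_through", "bin_extrema", "sampling_probability_glires",
    "align_proxies", "build_ceiling", "build_series_table",
]


@dataclass(frozen=True)
class BinGrid:
    """Contiguous equal-width time bins counted from an old starting age.

    Bin ``k`` covers ages in ``(start - (k+1)*width, start - k*width]``
    except that a boundary age is assigned to the older of its two bins.
    """

    start: float = 43.5   # Ma
    width: float = 1.5    # Myr
    n_bins: int = 29      # reaches the present from 43.5 Ma

    def __post_init__(self):
        if self.width <= 0:
            raise InvalidArgumentError("bin width must be positive")
        if self.n_bins < 1:
            raise InvalidArgumentError("need at least one bin")

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoint ages, oldest first."""
        k = np.arange(self.n_bins)
        return self.start - (k + 0.5) * self.width

    @property
    def older_edges(self) -> np.ndarray:
        return self.start - np.arange(self.n_bins) * self.width

    def assign(self, age: float) -> int:
        return assign_bin(age, self)

    def window_bins(self, oldest: float, youngest: float) -> np.ndarray:
        """Indices of bins fully inside [youngest, oldest] Ma."""
        k = np.arange(self.n_bins)
        older = self.start - k * self.width
        younger = older - self.width
        return k[(older <= oldest + 1e-9) & (younger >= youngest - 1e-9)]


DEFAULT_GRID = BinGrid()


#: (older Ma, younger Ma, ceiling source) windows for the competitive
#: ceiling: perissodactyl energy-equivalent mass 37.5-24.0 and
#: 15.0-1.5 Ma, minimum artiodactyl mass 24.0-15.0 Ma.
DEFAULT_REGIMES = (
    (37.5, 24.0, "perissodactyl_equivalent"),
    (24.0, 15.0, "artiodactyl_minimum"),
    (15.0, 1.5, "perissodactyl_equivalent"),
)


#: Locality-age uncertainty cutoff (Myr): the duration of the longest
#: North American Land Mammal Age subage.  Records *exceeding* it are
#: dropped; exactly 4.2 Myr is kept.
MAX_AGE_UNCERTAINTY = 4.2


def filter_localities(records: pd.DataFrame,
                      max_uncertainty: float = MAX_AGE_UNCERTAINTY) -> pd.DataFrame:
    """Drop records whose age range (age_max - age_min) exceeds the cutoff;
    a span exactly at the cutoff is kept (tolerance guards float subtraction)."""
    span = records["age_max"] - records["age_min"]
    return records[span <= max_uncertainty + 1e-9].reset_index(drop=True)


def assign_bin(age: float, grid: BinGrid = DEFAULT_GRID) -> int:
    """Bin index for an age; boundary ages go to the older bin."""
    if not 0.0 <= age <= grid.start:
        raise InvalidArgumentError(
            f"age {age} outside grid range [0, {grid.start}]")
    k = math.ceil((grid.start - age) / grid.width - 1e-12) - 1
    return int(min(max(k, 0), grid.n_bins - 1))


def locality_midpoint_ages(records: pd.DataFrame) -> pd.Series:
    """Per-record locality midpoint age (age_max + age_min) / 2."""
    return (records["age_max"] + records["age_min"]) / 2.0


def _assigned_bins(records: pd.DataFrame, grid: BinGrid,
                   ages: pd.Series | None = None) -> np.ndarray:
    if ages is None:
        ages = locality_midpoint_ages(records)
    else:
        ages = pd.Series(ages).loc[records.index]
    return np.array([assign_bin(a, grid) for a in ages])


def range_through(occurrence_bins, grid: BinGrid = DEFAULT_GRID) -> np.ndarray:
    """Bins a taxon occupies: the contiguous interval from its oldest to
    youngest occupied bin, inclusive."""
    bins = np.asarray(list(occurrence_bins), dtype=int)
    if bins.size == 0:
        raise InvalidArgumentError("taxon has no occurrences")
    return np.arange(bins.min(), bins.max() + 1)


def bin_extrema(records: pd.DataFrame, grid: BinGrid = DEFAULT_GRID,
                ages: pd.Series | None = None) -> pd.DataFrame:
    """Per-bin guild extrema of log10 body mass under range-through presence.

    Returns a DataFrame indexed by bin with columns ``m_maxlag`` (maximum
    lagomorph), ``m_minart`` (minimum artiodactyl) and ``m_minper``
    (minimum perissodactyl); NaN where the clade is absent.  A taxon
    carries a single mass (its mean estimate) through all bins in which it
    is present.  ``ages`` overrides the default locality-midpoint ages
    (used by the pseudo-replicate machinery to bin by sampled ages).
    """
    df = records.copy()
    df["bin"] = _assigned_bins(df, grid, ages)
    out = pd.DataFrame(index=pd.RangeIndex(grid.n_bins, name="bin"),
                       columns=["m_maxlag", "m_minart", "m_minper"],
                       dtype=float)
    agg = {"lagomorph": ("m_maxlag", np.fmax),
           "artiodactyl": ("m_minart", np.fmin),
           "perissodactyl": ("m_minper", np.fmin)}
    for (taxon, clade), grp in df.groupby(["taxon", "clade"], sort=False):
        if clade not in agg:
            continue
        mass = grp["mass_log10"].dropna()
        if mass.empty:
            continue
        m = float(mass.mean())
        col, op = agg[clade]
        for b in range_through(grp["bin"], grid):
            cur = out.at[b, col]
            out.at[b, col] = m if np.isnan(cur) else op(cur, m)
    return out


def sampling_probability_glires(records: pd.DataFrame,
                                grid: BinGrid = DEFAULT_GRID,
                                ages: pd.Series | None = None) -> pd.DataFrame:
    """Range-through sampling probability for glires genera, per bin.

    ``p = k / n`` where ``n`` counts glires (rodent + lagomorph) genera
    inferred present in the bin by range-through and ``k`` those actually
    sampled in the bin (in-bin occurrences only, so ``k <= n``).  Returned
    on the empirical-logit scale ``r = ln((k + 0.5) / (n - k + 0.5))``,
    which stays finite when every genus is sampled.  Bins with ``n = 0``
    are NaN.
    """
    df = records[records["clade"].isin(("rodent", "lagomorph"))].copy()
    df["bin"] = _assigned_bins(df, grid, ages)
    n = np.zeros(grid.n_bins, dtype=int)
    k = np.zeros(grid.n_bins, dtype=int)
    for genus, grp in df.groupby("genus", sort=False):
        occupied = np.unique(grp["bin"].to_numpy())
        n[range_through(occupied, grid)] += 1
        k[occupied] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    r = np.where(n > 0, np.log((k + 0.5) / (n - k + 0.5)), np.nan)
    return pd.DataFrame({"n_genera": n, "n_sampled": k, "p": p, "r_glires": r},
                        index=pd.RangeIndex(grid.n_bins, name="bin"))


def align_proxies(d18o: pd.DataFrame | None, h_ung: pd.DataFrame | None,
                  grid: BinGrid = DEFAULT_GRID) -> pd.DataFrame:
    """Align proxy series to the bin grid.

    d18O records (columns age, value) are averaged within each bin using
    the same boundary convention as occurrence binning; the hypsodonty
    series (age = interval midpoint, value = interval mean) is linearly
    interpolated to bin midpoints, with no extrapolation beyond its range.
    """
    out = pd.DataFrame(index=pd.RangeIndex(grid.n_bins, name="bin"),
                       columns=["d18o", "h_ung"], dtype=float)
    if d18o is not None and len(d18o):
        ok = (d18o["age"] >= 0) & (d18o["age"] <= grid.start)
        sub = d18o[ok]
        bins = np.array([assign_bin(a, grid) for a in sub["age"]])
        sums = np.bincount(bins, weights=sub["value"], minlength=grid.n_bins)
        counts = np.bincount(bins, minlength=grid.n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out["d18o"] = means
    if h_ung is not None and len(h_ung) >= 2:
        xs = h_ung["age"].to_numpy(dtype=float)
        ys = h_ung["value"].to_numpy(dtype=float)
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        mids = grid.midpoints
        vals = np.interp(mids, xs, ys, left=np.nan, right=np.nan)
        vals[(mids < xs[0]) | (mids > xs[-1])] = np.nan
        out["h_ung"] = vals
    elif h_ung is not None and len(h_ung) == 1:
        mids = grid.midpoints
        hit = np.isclose(mids, float(h_ung["age"].iloc[0]))
        out.loc[hit, "h_ung"] = float(h_ung["value"].iloc[0])
    return out


def _regime_for(age: float, regimes) -> str | None:
    """Ceiling source for a bin midpoint age; windows are (younger, older]
    so a boundary age falls in the older window."""
    for older, younger, source in regimes:
        if younger < age <= older:
            return source
    return None


def build_ceiling(extrema: pd.DataFrame, line_lag: EnergyLine,
                  line_ung: EnergyLine, regimes=DEFAULT_REGIMES,
                  grid: BinGrid = DEFAULT_GRID) -> pd.Series:
    """Competitive-ceiling log10 mass per bin.

    In perissodactyl windows the ceiling is the lagomorph mass whose
    local-population energy use equals that of the smallest contemporary
    perissodactyl; in artiodactyl windows it is the smallest artiodactyl
    mass passed through directly.  Bins outside all windows, or lacking
    the window's source extremum, are NaN.
    """
    for older, younger, source in regimes:
        if older <= younger:
            raise InvalidArgumentError("regime windows must run old to young")
        if source not in ("perissodactyl_equivalent", "artiodactyl_minimum"):
            raise InvalidArgumentError(f"unknown ceiling source {source!r}")
    mids = grid.midpoints
    out = pd.Series(np.nan, index=extrema.index, name="m_ceiling")
    for b in extrema.index:
        source = _regime_for(mids[b], regimes)
        if source is None:
            continue
        if source == "artiodactyl_minimum":
            out.at[b] = extrema.at[b, "m_minart"]
        else:
            mp = extrema.at[b, "m_minper"]
            if np.isfinite(mp):
                out.at[b] = float(energy_equivalent_log10(line_lag, line_ung, mp))
    return out


def build_series_table(records: pd.DataFrame, line_lag: EnergyLine,
                       line_ung: EnergyLine, d18o=None, h_ung=None,
                       regimes=DEFAULT_REGIMES, grid: BinGrid = DEFAULT_GRID,
                       ages: pd.Series | None = None,
                       max_uncertainty: float = MAX_AGE_UNCERTAINTY) -> pd.DataFrame:
    """Full per-bin series table: extrema, ceiling, proxies, r_glires.

    One row per bin with columns m_maxlag, m_minart, m_minper, m_ceiling,
    d18o, h_ung, r_glires and the bin midpoint age.
    """
    span = records["age_max"] - records["age_min"]
    keep = span <= max_uncertainty
    recs = records[keep]
    if ages is not None:
        ages = pd.Series(ages).loc[recs.index]
    ext = bin_extrema(recs, grid, ages)
    samp = sampling_probability_glires(recs, grid, ages)
    prox = align_proxies(d18o, h_ung, grid)
    table = ext.copy()
    table["m_ceiling"] = build_ceiling(ext, line_lag, line_ung, regimes, grid)
    table["d18o"] = prox["d18o"]
    table["h_ung"] = prox["h_ung"]
    table["r_glires"] = samp["r_glires"]
    table["age_mid"] = grid.midpoints
    return table
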