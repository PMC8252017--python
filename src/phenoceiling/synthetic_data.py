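"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the data the analysis consumes — time-calibrated trees, scaling
traits evolved under lambda-scaled Brownian covariance, fossil occurrence
records with bounded locality-age uncertainty and clade labels, proxy
series, and ecoregion tables with spatial adjacency — so that parameter
recovery and end-to-end behaviour are testable without any downloads.

The default scenario parameters define the study conditions: a shared
metabolic-rate allometry (log10 R = 0.6 + 0.7 log10 M) and guild-specific
density allometries (lagomorphs log10 D = 2.2 - 1.9 log10 M; ungulates
log10 D = 1.6 - 1.15 log10 M) compose to energy lines with intercepts and
slopes (2.8, -1.2) and (2.2, -0.45), which cross at ~6.3 kg — the
geometry of the continental lagomorph size ceiling.  The fossil scenario
uses 1.5-Myr bins from 43.5 Ma with locality-age half-widths capped at
2.1 Myr (so every record passes the 4.2-Myr uncertainty filter) and
log10-mass standard errors of 0.05.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .energetics import EnergyLine, energy_equivalent_log10
from .exceptions import InvalidArgumentError
from .fossil_timeseries import BinGrid, DEFAULT_GRID, DEFAULT_REGIMES, _regime_for
from .phylo_gls import lambda_correlation

__all__ = [
    "SimulationConfig", "default_energy_lines", "default_trajectories",
    "simulate_tree", "simulate_scaling_traits", "simulate_fossil_record",
    "simulate_proxies", "simulate_ecoregion_table", "simulate_fossil_scenario",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic study system."""

    n_tips: int = 128
    birth_rate: float = 0.1            # per Myr
    lambda_true: float = 0.5
    r_intercept: float = 0.6           # log10 metabolic rate at 1 kg
    r_slope: float = 0.7
    d_intercept_lag: float = 2.2       # log10 density at 1 kg, lagomorphs
    d_slope_lag: float = -1.9
    d_intercept_ung: float = 1.6       # log10 density at 1 kg, ungulates
    d_slope_ung: float = -1.15
    sigma_resid: float = 0.1           # log10 residual SD of trait scaling
    n_bins: int = 29
    bin_width: float = 1.5             # Myr
    locality_age_halfwidth_max: float = 2.1   # Myr
    mass_se: float = 0.05              # log10 kg
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_true <= 1.0:
            raise InvalidArgumentError("lambda_true must be in [0, 1]")
        if self.bin_width <= 0:
            raise InvalidArgumentError("bin_width must be positive")
        if self.birth_rate <= 0:
            raise InvalidArgumentError("birth_rate must be positive")
        if self.sigma_resid < 0 or self.mass_se < 0:
            raise InvalidArgumentError("noise scales must be nonnegative")
        if self.locality_age_halfwidth_max < 0:
            raise InvalidArgumentError("age halfwidth must be nonnegative")

    @property
    def grid(self) -> BinGrid:
        return BinGrid(start=43.5, width=self.bin_width, n_bins=self.n_bins)


def default_energy_lines(config: SimulationConfig | None = None
                         ) -> tuple[EnergyLine, EnergyLine]:
    """(lagomorph, ungulate) energy lines implied by the config's
    allometries; (2.8, -1.2) and (2.2, -0.45) at the defaults."""
    c = config or SimulationConfig()
    lag = EnergyLine(alpha=c.r_intercept + c.d_intercept_lag,
                     beta=c.r_slope + c.d_slope_lag, guild="lagomorph")
    ung = EnergyLine(alpha=c.r_intercept + c.d_intercept_ung,
                     beta=c.r_slope + c.d_slope_ung, guild="ungulate")
    return lag, ung


# ------------------------------------------------------------------ trees

class _Lineage:
    __slots__ = ("birth", "split", "children", "label")

    def __init__(self, birth):
        self.birth = birth
        self.split = None
        self.children = None
        self.label = None


def simulate_tree(n_tips: int, birth_rate: float = 0.1,
                  seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` extant tips.

    Lineages split at rate ``birth_rate`` per lineage per Myr; all tips
    extend to the present, so root-to-tip distances are equal.  Tip
    labels are ``t1..tN``.
    """
    if n_tips < 2:
        raise InvalidArgumentError(f"need >=2 tips, got {n_tips}")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root_children = [_Lineage(0.0), _Lineage(0.0)]
    active = list(root_children)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node = active.pop(i)
        node.split = t
        node.children = [_Lineage(t), _Lineage(t)]
        active.extend(node.children)
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))
    counter = iter(range(1, n_tips + 1))

    def newick(node):
        if node.children is None:
            node.label = f"t{next(counter)}"
            return f"{node.label}:{present - node.birth:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.split - node.birth:.10f}"

    text = "(" + ",".join(newick(c) for c in root_children) + ");"
    return dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)


# ------------------------------------------------------------- trait data

def simulate_scaling_traits(tree, intercept: float, slope: float,
                            lambda_true: float, sigma_resid: float,
                            mass_range: tuple[float, float] = (-1.0, 2.5),
                            seed: int = 0,
                            response_name: str = "response") -> pd.DataFrame:
    """Tip traits under the regression-with-phylogenetic-residuals model.

    log10 masses are uniform on ``mass_range``; the response is
    ``intercept + slope * log10M + eps`` with ``eps`` multivariate normal
    with covariance ``sigma_resid**2 * C(lambda_true)`` from the tree.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise InvalidArgumentError("lambda_true must be in [0, 1]")
    if sigma_resid < 0:
        raise InvalidArgumentError("sigma_resid must be nonnegative")
    labels, C = lambda_correlation(tree, lambda_true)
    rng = np.random.default_rng(seed)
    n = len(labels)
    x = rng.uniform(mass_range[0], mass_range[1], size=n)
    if sigma_resid > 0:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
        eps = sigma_resid * (L @ rng.standard_normal(n))
    else:
        eps = np.zeros(n)
    return pd.DataFrame({
        "species": labels,
        "log10_mass": x,
        response_name: intercept + slope * x + eps,
    })


# ----------------------------------------------------------- trajectories

def default_trajectories(config: SimulationConfig | None = None,
                         window: tuple[float, float] = (37.5, 1.5),
                         tracking_noise_sd: float = 0.0,
                         seed: int = 0) -> dict[str, np.ndarray]:
    """Per-bin true extrema (log10 kg) emulating the continental record.

    The minimum perissodactyl mass rises roughly eightfold across the
    window; the minimum artiodactyl mass starts very small, overlapping
    the lagomorph range, and climbs past it; the maximum lagomorph mass
    tracks the competitive ceiling implied by the config's energy lines
    (offset just below it, optionally with noise), so that the ceiling
    model is the generating model of the response.
    """
    c = config or SimulationConfig()
    grid = c.grid
    lag_line, ung_line = default_energy_lines(c)
    rng = np.random.default_rng(seed)
    mids = grid.midpoints
    old, young = window
    frac = np.clip((old - mids) / (old - young), 0.0, 1.0)  # 0 oldest -> 1

    m_minper = np.full(grid.n_bins, np.nan)
    m_minart = np.full(grid.n_bins, np.nan)
    m_maxlag = np.full(grid.n_bins, np.nan)
    inside = (mids <= old) & (mids >= young)
    # eightfold rise: log10 12 kg -> log10 96 kg
    m_minper[inside] = np.log10(12.0) + frac[inside] * np.log10(8.0)
    # artiodactyl minimum: 150 g rising to ~8 kg with a mild sinusoid
    m_minart[inside] = (-0.82 + 1.7 * frac[inside]
                        + 0.05 * np.sin(6.0 * frac[inside]))
    ceiling = np.full(grid.n_bins, np.nan)
    for b in range(grid.n_bins):
        if not inside[b]:
            continue
        src = _regime_for(mids[b], DEFAULT_REGIMES)
        if src == "artiodactyl_minimum":
            ceiling[b] = m_minart[b]
        elif src == "perissodactyl_equivalent":
            ceiling[b] = float(energy_equivalent_log10(
                lag_line, ung_line, m_minper[b]))
    noise = (tracking_noise_sd * rng.standard_normal(grid.n_bins)
             if tracking_noise_sd > 0 else np.zeros(grid.n_bins))
    m_maxlag[inside] = ceiling[inside] - 0.08 + noise[inside]
    return {"lagomorph": m_maxlag, "artiodactyl": m_minart,
            "perissodactyl": m_minper, "ceiling": ceiling}


# ----------------------------------------------------------- fossil record

def simulate_fossil_record(true_trajectories: dict[str, np.ndarray],
                           n_localities: int = 4,
                           age_halfwidth: float = 0.5,
                           mass_se: float = 0.05, seed: int = 0,
                           grid: BinGrid = DEFAULT_GRID,
                           taxa_per_clade_bin: int = 3,
                           n_rodent_genera: int = 10,
                           rodent_sampling_p: float = 0.8,
                           ) -> tuple[pd.DataFrame, dict]:
    """Occurrence table realizing per-bin true extrema, plus ground truth.

    For each bin and clade with a trajectory value, ``taxa_per_clade_bin``
    single-bin taxa are generated; one sits exactly at the clade's
    extremum and the rest on its non-extremal side, so at zero noise the
    binned extrema equal the generating trajectory.  Rodent genera span
    multi-bin ranges and are sampled per bin with probability
    ``rodent_sampling_p`` (always at their range ends), supplying the
    glires sampling-probability truth.  Locality ages are true bin-interior
    ages with symmetric bounds ``age +/- age_halfwidth``; mass point
    estimates are normal around the truth with SD ``mass_se``.

    Returns ``(records, truth)`` where ``truth`` has the per-bin extrema,
    the glires sampling counts/probability, and the empirical-logit
    ``r_glires``.
    """
    if age_halfwidth < 0 or mass_se < 0:
        raise InvalidArgumentError("uncertainty scales must be nonnegative")
    needed = {"lagomorph", "artiodactyl", "perissodactyl"}
    if not needed <= set(true_trajectories):
        raise InvalidArgumentError(f"trajectories must cover clades {needed}")
    for clade in needed:
        arr = np.asarray(true_trajectories[clade], dtype=float)
        if arr.shape != (grid.n_bins,):
            raise InvalidArgumentError(
                f"trajectory for {clade} must have {grid.n_bins} bins")
        if not np.any(np.isfinite(arr)):
            raise InvalidArgumentError(f"empty trajectory for {clade}")
    rng = np.random.default_rng(seed)
    rows = []
    offsets = {"lagomorph": -1, "artiodactyl": +1, "perissodactyl": +1}
    older_edges = grid.older_edges

    glires_n = np.zeros(grid.n_bins, dtype=int)
    glires_k = np.zeros(grid.n_bins, dtype=int)

    def bin_localities(b):
        older = older_edges[b]
        younger = older - grid.width
        # interior true ages keep the bounds' midpoint inside the bin
        pad = 0.02 * grid.width
        ages = rng.uniform(younger + pad, older - pad, size=n_localities)
        out = []
        for i, a in enumerate(ages):
            amax = min(a + age_halfwidth, grid.start)
            amin = max(a - age_halfwidth, 0.0)
            # re-center so the midpoint stays at the true age when clipped
            half = min(amax - a, a - amin)
            out.append((f"loc_b{b:02d}_{i}", a + half, a - half))
        return out

    for b in range(grid.n_bins):
        locs = bin_localities(b)
        for clade in ("lagomorph", "artiodactyl", "perissodactyl"):
            true_val = np.asarray(true_trajectories[clade], dtype=float)[b]
            if not np.isfinite(true_val):
                continue
            sign = offsets[clade]
            for t in range(taxa_per_clade_bin):
                mass = true_val if t == 0 else (
                    true_val + sign * rng.uniform(0.1, 0.6))
                est = mass + (rng.standard_normal() * mass_se
                              if mass_se > 0 else 0.0)
                loc = locs[int(rng.integers(len(locs)))]
                genus = f"{clade[:3].capitalize()}g{b:02d}"
                rows.append((f"{genus} sp{t}", genus, clade, loc[0],
                             loc[1], loc[2], est, mass_se))
            if clade == "lagomorph":
                glires_n[b] += 1
                glires_k[b] += 1

    # multi-bin rodent genera with partial per-bin sampling
    fin = np.where(np.isfinite(
        np.asarray(true_trajectories["lagomorph"], dtype=float)))[0]
    lo_bin, hi_bin = int(fin.min()), int(fin.max())
    for g in range(n_rodent_genera):
        start = int(rng.integers(lo_bin, hi_bin))
        length = int(rng.integers(2, max(3, (hi_bin - lo_bin) // 2 + 1)))
        rng_bins = np.arange(start, min(start + length, hi_bin + 1))
        sampled = rng.random(rng_bins.size) < rodent_sampling_p
        sampled[0] = sampled[-1] = True  # anchor the observed range
        glires_n[rng_bins] += 1
        genus = f"Rodg{g:02d}"
        mass = rng.uniform(-1.5, 0.0)
        for b, s in zip(rng_bins, sampled):
            if not s:
                continue
            glires_k[b] += 1
            locs = bin_localities(b)
            loc = locs[int(rng.integers(len(locs)))]
            rows.append((f"{genus} sp", genus, "rodent", loc[0],
                         loc[1], loc[2], mass, 0.0))

    records = pd.DataFrame(rows, columns=[
        "taxon", "genus", "clade", "locality_id",
        "age_max", "age_min", "mass_log10", "mass_se_log10"])
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(glires_n > 0, glires_k / np.maximum(glires_n, 1), np.nan)
        r = np.where(glires_n > 0,
                     np.log((glires_k + 0.5) / (glires_n - glires_k + 0.5)),
                     np.nan)
    truth = {
        "m_maxlag": np.asarray(true_trajectories["lagomorph"], dtype=float),
        "m_minart": np.asarray(true_trajectories["artiodactyl"], dtype=float),
        "m_minper": np.asarray(true_trajectories["perissodactyl"], dtype=float),
        "glires_n": glires_n, "glires_k": glires_k,
        "p_glires": p, "r_glires": r,
    }
    if "ceiling" in true_trajectories:
        truth["m_ceiling"] = np.asarray(true_trajectories["ceiling"],
                                        dtype=float)
    return records, truth


# ---------------------------------------------------------------- proxies

def simulate_proxies(grid: BinGrid = DEFAULT_GRID, seed: int = 0,
                     records_per_bin: int = 3) -> dict[str, pd.DataFrame]:
    """Synthetic benthic d18O records and hypsodonty interval means.

    d18O drifts from ~0.5 permil (warm Eocene) toward ~3.5 permil with
    noise, several records per bin at random in-bin ages; the hypsodonty
    index rises from ~1 (brachydont) toward ~2.5 at 2.5-Myr interval
    midpoints spanning the grid.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(grid.n_bins):
        older = grid.older_edges[b]
        ages = rng.uniform(older - grid.width, older, size=records_per_bin)
        frac = (grid.start - ages) / (grid.start)
        vals = 0.5 + 3.0 * frac + 0.15 * rng.standard_normal(records_per_bin)
        rows.extend(zip(ages, vals))
    d18o = pd.DataFrame(rows, columns=["age", "value"]).sort_values(
        "age", ascending=False, kind="stable").reset_index(drop=True)
    mids = np.arange(grid.start - 1.25, -0.01, -2.5)
    frac = (grid.start - mids) / grid.start
    hvals = 1.0 + 1.5 * frac + 0.05 * rng.standard_normal(mids.size)
    h_ung = pd.DataFrame({"age": mids, "value": hvals})
    return {"d18o": d18o, "h_ung": h_ung}


# -------------------------------------------------------------- ecoregions

def _lattice_adjacency(n: int) -> list[tuple[str, str]]:
    """Approximately square lattice over ecoregion ids er000..er{n-1}."""
    side = int(np.ceil(np.sqrt(n)))
    edges = []
    for i in range(n):
        r, c = divmod(i, side)
        for dr, dc in ((0, 1), (1, 0)):
            j = (r + dr) * side + (c + dc)
            if j < n and (c + dc) < side:
                edges.append((f"er{i:03d}", f"er{j:03d}"))
    return edges


def simulate_ecoregion_table(n_ecoregions: int = 300, adjacency=None,
                             effect_spec: dict | None = None,
                             noise_sd: float = 0.1,
                             spatial_rho: float = 0.5,
                             seed: int = 0) -> tuple[pd.DataFrame, list]:
    """Ecoregion table with a known response function and spatial noise.

    Covariates mimic the modern-ecoregion predictors (minimum UTH mass,
    temperature, precipitation and its variance, soil nutrient class,
    tree cover, elevation, introduction flag).  The response
    ``log10_m_maxlag`` is the sum of ``effect_spec`` functions applied to
    named covariates (default: 0.55 * log10_m_minuth) plus noise whose
    spatial component mixes each ecoregion's draw with its neighbors'
    mean.  Returns ``(table, adjacency_edges)``.
    """
    from .ecoregion_macro import _neighbor_map  # avoid cycle at import time

    if n_ecoregions < 1:
        raise InvalidArgumentError("need at least one ecoregion")
    ids = [f"er{i:03d}" for i in range(n_ecoregions)]
    if adjacency is None:
        adjacency = _lattice_adjacency(n_ecoregions)
    nbrs = _neighbor_map(adjacency, ids)
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "ecoregion_id": ids,
        "log10_m_minuth": rng.uniform(-0.5, 2.0, n_ecoregions),
        "temperature": rng.normal(18.0, 7.0, n_ecoregions),
        "precipitation": rng.lognormal(6.5, 0.6, n_ecoregions),
        "precipitation_var": rng.lognormal(3.0, 0.8, n_ecoregions),
        "soil_nutrients": rng.integers(1, 5, n_ecoregions).astype(float),
        "tree_cover": rng.uniform(0.0, 100.0, n_ecoregions),
        "elevation": rng.uniform(0.0, 3500.0, n_ecoregions),
        "introduced": rng.integers(0, 2, n_ecoregions).astype(float),
    }).set_index("ecoregion_id", drop=False)
    if effect_spec is None:
        effect_spec = {"log10_m_minuth": lambda v: 0.55 * v}
    response = np.zeros(n_ecoregions)
    for name, fn in effect_spec.items():
        if name not in table.columns:
            raise InvalidArgumentError(f"unknown covariate {name!r}")
        response = response + np.asarray(fn(table[name].to_numpy()), dtype=float)
    if noise_sd > 0:
        eps = pd.Series(rng.normal(0.0, noise_sd, n_ecoregions), index=ids)
        nbr_mean = pd.Series(
            [eps.loc[nbrs[i]].mean() if nbrs.get(i) else 0.0 for i in ids],
            index=ids)
        response = response + (eps + spatial_rho * nbr_mean).to_numpy()
    table["log10_m_maxlag"] = response
    return table.reset_index(drop=True), list(adjacency)


# ------------------------------------------------------------ full scenario

def simulate_fossil_scenario(config: SimulationConfig | None = None,
                             tracking_noise_sd: float = 0.05,
                             age_halfwidth: float | None = None,
                             n_localities: int = 4) -> dict:
    """Generate a complete fossil-pipeline input set under the default
    study conditions: trajectories where maximum lagomorph mass tracks
    the competitive ceiling, an occurrence record realizing them, proxy
    series, and the generating energy lines."""
    c = config or SimulationConfig()
    if age_halfwidth is None:
        age_halfwidth = min(1.1, c.locality_age_halfwidth_max)
    traj = default_trajectories(c, tracking_noise_sd=tracking_noise_sd,
                                seed=c.seed)
    records, truth = simulate_fossil_record(
        traj, n_localities=n_localities, age_halfwidth=age_halfwidth,
        mass_se=c.mass_se, seed=c.seed + 1, grid=c.grid)
    proxies = simulate_proxies(c.grid, seed=c.seed + 2)
    lag_line, ung_line = default_energy_lines(c)
    return {"config": c, "grid": c.grid, "trajectories": traj,
            "records": records, "truth": truth, "proxies": proxies,
            "line_lag": lag_line, "line_ung": ung_line}
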