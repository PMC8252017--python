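"""Readers and writers for the pipeline's file formats.

Trees travel as Newick, tables as UTF-8 comma-separated CSV with a header
row, run configuration as YAML, and result summaries as JSON.  Readers
validate invariants and reject offending rows with row-numbered
diagnostics rather than silently coercing them.  Ages are in Ma before
present (larger = older); masses are carried internally on the log10 kg
scale, converted only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .exceptions import NewickParseError, ValidationError

logger = logging.getLogger("phenoceiling")

CLADES = ("lagomorph", "artiodactyl", "perissodactyl", "rodent")

OCCURRENCE_COLUMNS = ("taxon", "genus", "clade", "locality_id",
                      "age_max", "age_min")

__all__ = [
    "read_newick", "write_newick",
    "read_occurrences", "write_occurrences",
    "read_series", "read_traits",
    "load_config", "save_config", "write_json",
    "CLADES", "OCCURRENCE_COLUMNS",
]


# ---------------------------------------------------------------- trees

def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal string.

    Requires branch lengths on all non-root edges and unique tip labels.
    """
    text = str(source)
    if "(" not in text:  # looks like a path
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as err:
        raise NewickParseError(f"malformed Newick: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {s for s in labels if labels.count(s) > 1}
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise NewickParseError(
                f"missing branch length on edge above "
                f"{node.taxon.label if node.taxon else 'internal node'}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize to Newick; writes to ``path`` when given, returns the text."""
    text = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# --------------------------------------------------------------- tables

def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def read_occurrences(path, schema_map: dict | None = None) -> pd.DataFrame:
    """Read a fossil occurrence table.

    ``schema_map`` renames source columns to the canonical schema
    (taxon, genus, clade, locality_id, age_max, age_min, and optionally
    mass_log10, mass_se_log10).  Rows violating invariants
    (age_min > age_max, negative ages, unknown clade, negative mass SE)
    are dropped with row-numbered warnings; valid rows are kept.
    """
    df = _read_csv(path)
    if schema_map:
        df = df.rename(columns=schema_map)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"occurrence table missing columns: {missing}")
    if df.empty:
        logger.warning("occurrence file %s is empty", path)
        warnings.warn(f"occurrence file {path} is empty", stacklevel=2)
        return df

    df = df.copy()
    for col in ("age_max", "age_min", "mass_log10", "mass_se_log10"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = pd.Series(False, index=df.index)
    reasons = {}

    def flag(mask, reason):
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad[mask] = True

    flag(df["age_max"].isna() | df["age_min"].isna(), "non-numeric age")
    flag(~bad & (df["age_min"] < 0), "negative age")
    flag(~bad & (df["age_min"] > df["age_max"]), "age_min > age_max")
    flag(~df["clade"].isin(CLADES), f"clade not in {CLADES}")
    if "mass_se_log10" in df.columns:
        flag(df["mass_se_log10"].notna() & (df["mass_se_log10"] < 0),
             "negative mass_se_log10")
    if bad.any():
        detail = "; ".join(f"row {i + 2}: {r}" for i, r in
                           sorted(reasons.items())[:20])
        warnings.warn(f"rejected {int(bad.sum())} occurrence rows "
                      f"({detail})", stacklevel=2)
    return df[~bad].reset_index(drop=True)


def write_occurrences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_series(path, age_col: str | None = None,
                value_col: str | None = None) -> pd.DataFrame:
    """Read a two-column (age Ma, value) proxy series.

    Returns a DataFrame with columns ``age`` and ``value`` sorted by age
    descending (oldest first) with a stable sort, duplicates preserved.
    """
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("series file needs two columns (age, value)")
    age_col = age_col or df.columns[0]
    value_col = value_col or df.columns[1]
    out = df[[age_col, value_col]].rename(
        columns={age_col: "age", value_col: "value"})
    for col in ("age", "value"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        nonnum = coerced.isna() & out[col].notna()
        if nonnum.any():
            rows = [int(i) + 2 for i in out.index[nonnum][:10]]
            raise ValidationError(f"non-numeric {col} in rows {rows}")
        out[col] = coerced
    out = out.dropna()
    return out.sort_values("age", ascending=False,
                           kind="stable").reset_index(drop=True)


def read_traits(path) -> pd.DataFrame:
    """Read a species trait table (species, mass kg, optional density, bmr).

    All trait values must be positive where present; offending rows are
    rejected with warnings.  BMR is treated as an opaque positive quantity
    in whatever units the source table uses (they must be consistent
    within a run).
    """
    df = _read_csv(path)
    if "species" not in df.columns or "mass" not in df.columns:
        raise ValidationError("trait table needs 'species' and 'mass' columns")
    df = df.copy()
    bad = pd.Series(False, index=df.index)
    for col in ("mass", "density", "bmr"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            bad |= df[col].notna() & (df[col] <= 0)
    bad |= df["mass"].isna()
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:10]]
        warnings.warn(f"rejected {int(bad.sum())} trait rows "
                      f"(nonpositive or missing values) at rows {rows}",
                      stacklevel=2)
    return df[~bad].reset_index(drop=True)


# ---------------------------------------------------------------- config

def load_config(path, cls=None):
    """Load a YAML config; instantiate ``cls`` from it when given."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if cls is None:
        return data
    return cls(**data)


def save_config(obj, path) -> None:
    data = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
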