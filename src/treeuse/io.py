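"""CSV readers/writers for fixes, trees, visits and metric tables.

Schemas
-------
Fix CSV: ``animal_id, t, x, y`` with ISO-8601 timestamps carrying a UTC
offset; coordinates are projected meters.  Tree CSV: ``tree_id, x, y,
species, dbh_cm, height_m, cover, leaf_n_pct, fpc_mg_g``; missing chemistry
is tolerated (loaded as NaN and dropped, with a count, by the models).
Malformed rows are rejected with their line numbers.  Output tables are
UTF-8 comma-separated with a header row; a leading ``#``-comment carries
the run's config hash for provenance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .raster import read_ascii_grid, write_ascii_grid  # re-export

__all__ = [
    "read_fixes",
    "read_trees",
    "write_table",
    "read_table",
    "read_ascii_grid",
    "write_ascii_grid",
]

log = logging.getLogger("treeuse")

_FIX_COLUMNS = ["animal_id", "t", "x", "y"]
_TREE_COLUMNS = ["tree_id", "x", "y", "species", "dbh_cm", "height_m",
                 "cover", "leaf_n_pct", "fpc_mg_g"]
_TREE_REQUIRED = ["tree_id", "x", "y"]


def read_fixes(path: str | Path) -> pd.DataFrame:
    """Read and validate a fix CSV.

    Requires the four schema columns, parseable timezone-aware timestamps,
    and strictly increasing times within each animal; violations are
    reported with 1-based data row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fix CSV missing columns {missing}")
    try:
        df["t"] = pd.to_datetime(df["t"], utc=False, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamps: {exc}") from exc
    if getattr(df["t"].dtype, "tz", None) is None:
        if pd.api.types.is_datetime64_any_dtype(df["t"]):
            # parsed cleanly but without any zone information
            raise ValueError(f"{path}: timestamps must carry a UTC offset")
        # mixed offsets parse to object; normalize to UTC instants
        df["t"] = pd.to_datetime(df["t"], utc=True)
    bad = df[df[["x", "y"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"{path}: missing coordinates at data rows "
            f"{[i + 1 for i in bad.index[:5]]}")
    _validate_monotone(df, path)
    return df[_FIX_COLUMNS + [c for c in df.columns
                              if c not in _FIX_COLUMNS]]


def _validate_monotone(df: pd.DataFrame, path) -> None:
    for animal, grp in df.groupby("animal_id", sort=False):
        dt = grp["t"].diff().dropna()
        dup = dt[dt == pd.Timedelta(0)]
        if len(dup):
            row = int(dup.index[0]) + 1
            raise ValueError(
                f"{path}: duplicated timestamp for animal {animal!r} at "
                f"data row {row}")
        neg = dt[dt < pd.Timedelta(0)]
        if len(neg):
            row = int(neg.index[0]) + 1
            raise ValueError(
                f"{path}: non-monotone timestamp for animal {animal!r} at "
                f"data row {row}")


def read_trees(path: str | Path) -> pd.DataFrame:
    """Read and validate a tree CSV.

    Positions are required; attribute columns may be absent or contain
    missing values (logged), which downstream model fitting drops row-wise.
    Duplicate tree ids are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _TREE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: tree CSV missing columns {missing}")
    dup = df["tree_id"][df["tree_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate tree_id values {list(dup[:5])}")
    for col in ("dbh_cm", "height_m", "leaf_n_pct", "fpc_mg_g"):
        if col in df.columns:
            n_missing = int(df[col].isna().sum())
            if n_missing:
                log.info("%s: %d trees missing %s (kept as NaN)",
                         path, n_missing, col)
            if (df[col].dropna() < 0).any():
                raise ValueError(f"{path}: negative values in {col}")
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                config_hash: str | None = None) -> None:
    """Write a CSV with an optional leading config-hash comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
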