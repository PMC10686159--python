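"""Reading OWID-style cause-of-death tables and writing result files.

The expected input layout is the wide "causes of death" CSV: one row per
(Entity, Year) with columns ``Entity``, ``Code``, ``Year`` and one numeric
column per cause, plus an optional population column for converting death
counts into rates as % of population.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import replace
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ComponentSeries, Panel

__all__ = [
    "SchemaError",
    "ParseError",
    "read_rate_table",
    "exclude_components",
    "write_results",
    "write_panel",
    "read_curve",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("Entity", "Code", "Year")


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ParseError(ValueError):
    """A cell that should be numeric could not be parsed."""


def _coerce_numeric(frame: pd.DataFrame, column: str) -> pd.Series:
    """Parse a column as float, raising :class:`ParseError` with the first
    offending row number (1-based, counting the header as row 1)."""
    raw = frame[column]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"column {column!r}, file row {row + 2}: "
            f"cannot parse value {raw.iloc[row]!r} as a number"
        )
    return coerced


def read_rate_table(
    csv_path: str | PathLike,
    cause_columns: Sequence[str],
    population_column: str | None = None,
    threshold: float | Mapping[str, float] = 1.0,
) -> Panel:
    """Read a wide cause-of-death CSV into a :class:`Panel`.

    One :class:`ComponentSeries` is created per (Entity, cause).  If
    ``population_column`` is given the cause columns are death counts and
    are converted to rates via ``deaths / population * 100`` (% of
    population); otherwise they are taken as already-in-% rates.  Rows
    with a missing value for a cause are dropped from that component only.

    ``threshold`` is the failure limit eta assigned to every component
    (in % of population), or a mapping from component id to eta.
    """
    cause_columns = list(cause_columns)
    if not cause_columns:
        raise ValueError("at least one cause column is required")
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    needed = list(_REQUIRED_COLUMNS) + cause_columns
    if population_column is not None:
        needed.append(population_column)
    for col in needed:
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} is missing from {csv_path}")

    frame = frame.copy()
    year = _coerce_numeric(frame, "Year")
    if year.isna().any():
        row = int(np.flatnonzero(year.isna().to_numpy())[0])
        raise ParseError(f"column 'Year', file row {row + 2}: missing year")
    if not np.allclose(year, np.round(year)):
        raise ParseError("column 'Year' contains non-integer values")
    frame["Year"] = year.astype(np.int64)
    for col in cause_columns:
        frame[col] = _coerce_numeric(frame, col)
    if population_column is not None:
        frame[population_column] = _coerce_numeric(frame, population_column)

    single_cause = len(cause_columns) == 1
    components: list[ComponentSeries] = []
    for entity, group in frame.groupby("Entity", sort=True):
        group = group.sort_values("Year")
        for cause in cause_columns:
            sub = group[group[cause].notna()]
            if population_column is not None:
                sub = sub[sub[population_column].notna()]
            if sub.empty:
                continue
            values = sub[cause].to_numpy(dtype=float)
            if population_column is not None:
                values = values / sub[population_column].to_numpy(dtype=float) * 100.0
            cid = str(entity) if single_cause else f"{entity}|{cause}"
            eta = threshold[cid] if isinstance(threshold, Mapping) else float(threshold)
            components.append(
                ComponentSeries(
                    component_id=cid,
                    times=sub["Year"].to_numpy(),
                    values=values,
                    threshold=eta,
                )
            )
    if not components:
        raise ValueError(f"no usable components found in {csv_path}")
    meta = {
        "source": str(csv_path),
        "cause_columns": cause_columns,
        "population_column": population_column,
        "units": "% of population per year",
    }
    return Panel(components=tuple(components), metadata=meta)


def exclude_components(panel: Panel, excluded_ids: Iterable[str]) -> Panel:
    """Drop the named components (exact, case-sensitive id match).

    Unknown ids produce a warning, not an error.  Excluding everything is
    an error: an empty panel has no meaning downstream.
    """
    excluded = list(excluded_ids)
    present = set(panel.component_ids)
    for cid in excluded:
        if cid in present:
            logger.info("excluding component %r", cid)
        else:
            warnings.warn(f"exclusion id {cid!r} not present in panel", stacklevel=2)
    keep = tuple(c for c in panel.components if c.component_id not in set(excluded))
    if not keep:
        raise ValueError("exclusions would remove every component")
    if len(keep) == len(panel.components):
        return panel
    meta = dict(panel.metadata)
    meta["excluded"] = sorted(set(excluded) & present)
    return Panel(components=keep, metadata=meta)


def write_panel(panel: Panel, out_path: str | PathLike, cause_name: str = "rate") -> None:
    """Write a panel in the same wide CSV schema :func:`read_rate_table` reads.

    Values and years round-trip losslessly (full float precision)."""
    rows = []
    for comp in panel.components:
        for t, v in zip(comp.times, comp.values):
            rows.append({"Entity": comp.component_id, "Code": "", "Year": int(t), cause_name: v})
    frame = pd.DataFrame(rows, columns=["Entity", "Code", "Year", cause_name])
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_path, index=False, float_format="%.17g")


def _curve_frame(curve) -> pd.DataFrame:
    n = curve.lambdas.size
    if n == 0:
        raise ValueError("cannot serialize an empty exceedance curve")
    nan = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "lambda": curve.lambdas,
            "p": curve.p,
            "ci_lo": nan if curve.ci_lo is None else curve.ci_lo,
            "ci_hi": nan if curve.ci_hi is None else curve.ci_hi,
            "n_cond": curve.n_cond,
            "n_exc": curve.n_exc,
            "k": np.full(n, curve.k, dtype=int),
            "N": np.full(n, curve.N, dtype=int),
        }
    )


def write_results(obj, out_path: str | PathLike, format: str | None = None) -> None:
    """Serialize a result object (round-trippable, full precision).

    ``ExceedanceCurve`` goes to CSV (columns lambda, p, ci_lo, ci_hi,
    n_cond, n_exc, k, N); anything exposing ``to_dict`` (``Prediction``,
    ``TailFit``) or a plain mapping goes to JSON.  ``format`` defaults to
    the path suffix.
    """
    out_path = Path(out_path)
    if format is None:
        format = out_path.suffix.lstrip(".").lower() or "json"
    if format not in ("csv", "json"):
        raise ValueError(f"unsupported format {format!r}")
    out_path.parent.mkdir(parents=True, exist_ok=True)

    if hasattr(obj, "lambdas") and hasattr(obj, "p"):  # ExceedanceCurve
        frame = _curve_frame(obj)
        if format == "csv":
            frame.to_csv(out_path, index=False, float_format="%.17g")
        else:
            out_path.write_text(frame.to_json(orient="records", double_precision=15))
        return
    if hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    elif isinstance(obj, Mapping):
        payload = dict(obj)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")
    if format == "csv":
        pd.DataFrame([payload]).to_csv(out_path, index=False)
    else:
        out_path.write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)!r}")


def read_curve(path: str | PathLike):
    """Read back an exceedance-curve CSV written by :func:`write_results`."""
    from .core import ExceedanceCurve  # local import to avoid a cycle

    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise ValueError(f"empty curve file: {path}")
    ci_lo = frame["ci_lo"].to_numpy(dtype=float)
    ci_hi = frame["ci_hi"].to_numpy(dtype=float)
    has_ci = not (np.isnan(ci_lo).all() and np.isnan(ci_hi).all())
    return ExceedanceCurve(
        k=int(frame["k"].iloc[0]),
        lambdas=frame["lambda"].to_numpy(dtype=float),
        p=frame["p"].to_numpy(dtype=float),
        n_cond=frame["n_cond"].to_numpy(dtype=np.int64),
        n_exc=frame["n_exc"].to_numpy(dtype=np.int64),
        N=int(frame["N"].iloc[0]),
        ci_lo=ci_lo if has_ci else None,
        ci_hi=ci_hi if has_ci else None,
    )
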