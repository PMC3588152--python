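"""Reading and writing abundance tables.

Two CSV layouts are supported:

* **wide** — first column is a time identifier, each remaining column one
  species, header row required;
* **long** — columns ``time, species, abundance`` (any order, matched by
  header name).

The reader auto-detects the layout from the header; the writer emits wide
format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import AbundanceMatrix

__all__ = ["read_abundance_csv", "write_abundance_csv"]

_LONG_COLUMNS = {"time", "species", "abundance"}


def read_abundance_csv(path, format: str = "auto") -> AbundanceMatrix:
    """Read an abundance table from CSV.

    Parameters
    ----------
    path : str or file-like
    format : {"auto", "wide", "long"}
        With "auto", a header containing exactly the columns
        ``time, species, abundance`` is treated as long format.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface parser diagnostics with context
        raise ValueError(f"could not parse abundance CSV {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError("abundance CSV needs at least two columns")
    cols_lower = {str(c).strip().lower() for c in df.columns}
    if format == "auto":
        format = "long" if cols_lower == _LONG_COLUMNS else "wide"
    if format == "long":
        if not _LONG_COLUMNS.issubset(cols_lower):
            raise ValueError(
                "long format requires columns time, species, abundance; "
                f"got {list(df.columns)}"
            )
        df.columns = [str(c).strip().lower() for c in df.columns]
        wide = df.pivot(index="time", columns="species", values="abundance")
        if wide.isna().any().any():
            missing = wide.isna().stack()
            t, s = missing[missing].index[0]
            raise ValueError(f"missing abundance for species {s!r} at time {t!r}")
        values = wide.to_numpy(dtype=float)
        return AbundanceMatrix(
            values=values,
            species_ids=tuple(map(str, wide.columns)),
            time_ids=tuple(wide.index),
        )
    elif format == "wide":
        time_ids = tuple(df.iloc[:, 0])
        species_ids = tuple(map(str, df.columns[1:]))
        body = df.iloc[:, 1:]
        try:
            values = body.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            # locate the first non-numeric cell for the error message
            for i, row in body.iterrows():
                for c, val in row.items():
                    try:
                        float(val)
                    except (TypeError, ValueError):
                        raise ValueError(
                            f"non-numeric abundance {val!r} at line {i + 2}, "
                            f"column {c!r}"
                        ) from exc
            raise
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing abundance at line {i + 2}, column {species_ids[j]!r}"
            )
        return AbundanceMatrix(values=values, species_ids=species_ids, time_ids=time_ids)
    raise ValueError(f"unknown format {format!r}; use 'wide', 'long' or 'auto'")


def write_abundance_csv(ts: AbundanceMatrix, path) -> None:
    """Write an abundance table as wide CSV (time column first)."""
    df = ts.to_dataframe()
    df.index.name = "time"
    df.to_csv(path)
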