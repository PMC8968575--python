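"""Delimited-text formats: time-series files and flat key=value configs.

A series file is two columns (time in days, cumulative value), comma- or
whitespace/tab-delimited, with optional ``#`` comment lines; the value unit
is declared in a header comment ``# unit: <label>``.  Values are written
with 12 significant digits, which round-trips bit-identically through
float parsing.
"""

from __future__ import annotations

import logging
import os
from typing import Union

import numpy as np

from .series import TimeSeries

__all__ = ["read_series", "write_series", "read_config"]

log = logging.getLogger("adkin")


def read_series(path: Union[str, os.PathLike]) -> TimeSeries:
    """Read and validate a two-column time-series file.

    Raises ``ValueError`` (with the offending line number) on malformed
    rows, and on duplicate or non-increasing times.  A missing unit header
    defaults to "arbitrary" with a logged warning.
    """
    times: list[float] = []
    values: list[float] = []
    unit = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("unit:"):
                    unit = body[5:].strip()
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric entry in {parts!r}") from None
            times.append(t)
            values.append(v)
    if len(times) < 2:
        raise ValueError(f"{path}: a series file needs at least 2 data rows")
    t = np.array(times)
    if np.any(np.diff(t) == 0):
        raise ValueError(f"{path}: duplicate time values")
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    if unit is None:
        log.warning("%s: no '# unit:' header found, assuming arbitrary units", path)
        unit = "arbitrary"
    return TimeSeries(t, np.array(values), unit)


def write_series(series: TimeSeries, path: Union[str, os.PathLike]) -> None:
    """Write a series in the format :func:`read_series` accepts (12 sig. digits)."""
    if len(series) == 0:
        raise ValueError("refusing to write an empty series")
    with open(path, "w") as fh:
        fh.write(f"# unit: {series.unit}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.12g},{v:.12g}\n")


def read_config(path: Union[str, os.PathLike]) -> dict[str, str]:
    """Read a flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out
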