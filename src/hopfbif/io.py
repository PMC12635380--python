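"""Plain-text I/O for time series and matrices.

Time series are stored as delimited text, N rows by T columns, with the
sampling interval carried in a ``# tr=<seconds>`` comment on the first line
so a file is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .sim import BoldTimeSeries

__all__ = ["save_timeseries", "load_timeseries", "save_matrix"]


def save_timeseries(ts: BoldTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.values, header=f"tr={ts.tr}", comments="# ")


def load_timeseries(path: str | Path, tr: float | None = None) -> BoldTimeSeries:
    """Load an N x T delimited-text series; ``tr`` overrides any header value."""
    path = Path(path)
    header_tr = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "tr=" in first:
        header_tr = float(first.split("tr=")[1].split()[0])
    if tr is None:
        tr = header_tr
    if tr is None:
        raise ValueError(f"{path}: no tr header found and none supplied")
    delim = "," if "," in first or "," in Path(path).read_text()[:500] else None
    values = np.loadtxt(path, delimiter=delim, ndmin=2)
    return BoldTimeSeries(values, tr)


def save_matrix(matrix: np.ndarray, path: str | Path, header: str = "") -> None:
    np.savetxt(path, np.asarray(matrix), header=header, comments="# " if header else "")
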