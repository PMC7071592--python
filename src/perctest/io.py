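"""Data ingestion and seeded fixture generation."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import SummaryStats, summarize
from .errors import InputDataError

__all__ = ["read_measurements", "generate_fixture"]

log = logging.getLogger("perctest")


def read_measurements(
    path: Union[str, Path], column: Optional[Union[str, int]] = None
) -> Tuple[SummaryStats, np.ndarray]:
    """Read one numeric column of measurements from a CSV file.

    ``column`` may be a header name or a 0-based index; by default the
    first column is used.  Missing values are dropped (and counted in the
    log); at least two finite values are required.  Returns the summary
    statistics (SD with divisor ``n - 1``) together with the raw values.
    """
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"no such file: {path}")
    try:
        header = "infer"
        with open(path) as fh:
            first = fh.readline()
        # headerless files: first row parses entirely as numbers
        if first.strip():
            try:
                [float(tok) for tok in first.strip().split(",")]
                header = None
            except ValueError:
                header = "infer"
        df = pd.read_csv(path, header=header)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InputDataError(f"could not parse CSV {path}: {exc}") from exc
    if df.empty:
        raise InputDataError(f"{path} contains no data rows")

    if column is None:
        series = df.iloc[:, 0]
    elif isinstance(column, int) or (isinstance(column, str) and column.isdigit()):
        idx = int(column)
        if idx >= df.shape[1]:
            raise InputDataError(f"column index {idx} out of range ({df.shape[1]} columns)")
        series = df.iloc[:, idx]
    else:
        if column not in df.columns:
            raise InputDataError(f"column {column!r} not found in {list(df.columns)}")
        series = df[column]

    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    n_missing = int(np.sum(~np.isfinite(values)))
    if n_missing:
        log.info("dropped %d missing/non-numeric values from %s", n_missing, path)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise InputDataError(
            f"need at least 2 numeric values in {path}, found {values.size} "
            f"({n_missing} missing)"
        )
    return summarize(values), values


def generate_fixture(
    mu: float, sigma: float, n: int, seed=None, exact_moments: bool = False
) -> np.ndarray:
    """Seeded i.i.d. normal draws, optionally rescaled to exact sample moments.

    With ``exact_moments=True`` the draws are affinely transformed so the
    sample mean and SD (divisor ``n - 1``) equal ``mu`` and ``sigma``
    exactly — useful for reconstructing a dataset from published summary
    statistics.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sigma, size=n) if sigma > 0 else np.full(n, float(mu))
    if exact_moments and sigma > 0:
        s = x.std(ddof=1)
        if s == 0:  # pragma: no cover - measure-zero event
            raise ValueError("degenerate draw; retry with another seed")
        x = (x - x.mean()) / s * sigma + mu
    return x
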