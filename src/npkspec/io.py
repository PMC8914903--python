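"""Delimited-text readers and writers for spectra, sample and feature tables.

Spectra matrix: CSV, first column ``sample_id``, remaining columns one
per band with the wavelength in nm as header.  White-board / dark-board
reference spectra travel as extra rows tagged ``WHITE`` / ``DARK``.
Sample table: CSV with ``sample_id, treatment, N, P, K``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_IDS",
    "read_spectra",
    "write_spectra",
    "read_samples",
    "write_samples",
    "read_table",
    "write_table",
]

REFERENCE_IDS = ("WHITE", "DARK")


def write_spectra(
    spectra: pd.DataFrame,
    path: str | Path,
    white: np.ndarray | pd.Series | None = None,
    dark: np.ndarray | pd.Series | None = None,
) -> Path:
    """Write a spectra matrix, optionally appending WHITE/DARK reference rows."""
    path = Path(path)
    out = spectra.copy()
    out.columns = [f"{float(c):.10g}" for c in out.columns]
    out.index.name = "sample_id"
    for tag, ref in (("WHITE", white), ("DARK", dark)):
        if ref is not None:
            out.loc[tag] = np.asarray(ref, dtype=float)
    out.to_csv(path)
    return path


def read_spectra(path: str | Path) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Read a spectra matrix; returns (samples, references).

    ``references`` maps ``"WHITE"`` / ``"DARK"`` to their spectra when
    present, else is empty.
    """
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(float)
    refs = {tag: df.loc[tag] for tag in REFERENCE_IDS if tag in df.index}
    df = df.drop(index=[t for t in REFERENCE_IDS if t in df.index])
    return df, refs


def write_samples(samples: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
    return path


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Generic keyed table writer (feature tables, correlation tables...)."""
    path = Path(path)
    table.to_csv(path)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
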