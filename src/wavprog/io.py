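"""Tab-delimited readers/writers for the pipeline's external formats.

Expression and methylation matrices are features-in-rows, samples-in-columns
TSVs with a header row of sample ids; clinical tables are sample-indexed
with ``group``, ``time_months`` and ``event`` columns; probe maps have one
``probe``/``gene`` row per mapping.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate feature ids")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"group", "time_months", "event"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing clinical column(s) {sorted(missing)}")
    return df


def read_probe_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if missing := {"probe", "gene"} - set(df.columns):
        raise ValueError(f"{path}: missing probe-map column(s) {sorted(missing)}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.6g")
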