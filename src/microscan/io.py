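"""TSV readers/writers shared by the pipeline and CLI.

All tables are tab-separated with a header row and the sample identifier
in the first column; missing values are written as ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path: str | Path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values="NA")


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA",
              index_label=index_label or df.index.name or "id")
    return path


def write_frame(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format frame without its integer index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", index=False)
    return path


def read_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
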