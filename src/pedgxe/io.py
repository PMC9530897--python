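"""Plain-text I/O: phenotype CSVs with configurable column mapping, BLUE
tables, and YAML configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .stage_one import PHENO_COLUMNS

BLUE_COLUMNS = ("genotype", "year", "condition", "environment", "blue", "se")


def load_column_map(path: str | Path) -> dict[str, str]:
    """YAML mapping from canonical column names to file column names."""
    mapping = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(mapping, dict):
        raise ValueError("column map YAML must be a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_phenotype_csv(
    path: str | Path, column_map: dict[str, str] | str | Path | None = None
) -> pd.DataFrame:
    """Long-format phenotype CSV -> canonical columns.

    ``column_map`` maps canonical names (genotype, year, ... GY, DTF, PH) to
    the file's column names; identity by default.  Missing optional columns
    (season, block, PH, DTF) are tolerated.
    """
    if isinstance(column_map, (str, Path)):
        column_map = load_column_map(column_map)
    df = pd.read_csv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    required = {"genotype", "year", "condition", "trial", "rep", "GY"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    for col in PHENO_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[list(PHENO_COLUMNS)]


def write_blues_csv(blues: pd.DataFrame, path: str | Path) -> None:
    blues[list(BLUE_COLUMNS)].to_csv(path, index=False)


def read_blues_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BLUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"BLUE file lacks columns: {sorted(missing)}")
    return df
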