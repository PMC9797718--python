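"""Readers and writers for the pipeline's tabular formats.

All tables are TSV/CSV with headers: an expression matrix (first column
gene symbol, remaining columns cell lines), a two-column drug-target map,
a monotherapy response table (drug_id, cell_line_id, ic50, unit), long
viability plates, and GMT gene-set collections.  Readers validate up front
and report what they dropped; writers round-trip with their paired reader.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("multisyn")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_drug_targets",
    "write_drug_targets",
    "read_response_table",
    "write_response_table",
    "read_gmt",
    "write_gmt",
    "read_plate_table",
    "write_plate_table",
    "RunConfig",
]

_UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_expression_matrix(path: str | Path, impute_mean: bool = False) -> pd.DataFrame:
    """Gene x cell-line matrix; duplicate gene rows collapsed by mean.

    Non-numeric cells raise with their coordinates; missing values raise
    unless ``impute_mean`` fills them with the column mean.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene column plus at least one cell line")
    df = df.set_index(df.columns[0])
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric value at gene {gene!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        if not impute_mean:
            rows = df.index[df.isna().any(axis=1)][:3].tolist()
            raise ValueError(f"{path}: missing values (e.g. genes {rows}); pass impute_mean=True")
        df = df.fillna(df.mean())
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    logger.info("expression matrix: %d genes x %d cell lines", *df.shape)
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_drug_targets(path: str | Path) -> dict[str, frozenset[str]]:
    """drug_id -> de-duplicated target set from a two-column TSV."""
    df = _read_table(path)
    if not {"drug_id", "target_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns drug_id, target_id")
    out: dict[str, set[str]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        drug, target = str(rec.drug_id).strip(), str(rec.target_id).strip()
        if not drug or drug == "nan" or not target or target == "nan":
            raise ValueError(f"{path}: blank drug or target id at line {i}")
        out.setdefault(drug, set()).add(target)
    universe = sorted({t for ts in out.values() for t in ts})
    logger.info("drug-target map: %d drugs, %d distinct targets", len(out), len(universe))
    return {d: frozenset(ts) for d, ts in out.items()}


def write_drug_targets(target_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(d, t) for d in sorted(target_map) for t in sorted(target_map[d])]
    pd.DataFrame(rows, columns=["drug_id", "target_id"]).to_csv(path, sep="\t", index=False)


def read_response_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Validated monotherapy records plus a report of what was dropped.

    Rows with IC50 <= 0 or missing are rejected and counted.  Duplicate
    (drug, cell line) pairs are resolved to the geometric mean (IC50 is a
    log-scale quantity), expressed in nM, with a warning.
    """
    df = _read_table(path)
    required = {"drug_id", "cell_line_id", "ic50", "unit"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df["ic50"] = pd.to_numeric(df["ic50"], errors="coerce")
    bad = df["ic50"].isna() | (df["ic50"] <= 0)
    n_rejected = int(bad.sum())
    df = df[~bad].copy()
    if df.empty:
        raise ValueError(f"{path}: no valid response rows")
    unknown_units = set(df["unit"]) - set(_UNIT_TO_NM)
    if unknown_units:
        raise ValueError(f"{path}: unknown units {sorted(unknown_units)}")
    dup_mask = df.duplicated(subset=["drug_id", "cell_line_id"], keep=False)
    if dup_mask.any():
        warnings.warn(
            f"{int(dup_mask.sum())} duplicate (drug, cell line) rows resolved by geometric mean",
            stacklevel=2,
        )
        df["_nm"] = df["ic50"] * df["unit"].map(_UNIT_TO_NM)
        agg = (
            df.groupby(["drug_id", "cell_line_id"], sort=False)["_nm"]
            .apply(lambda v: float(np.exp(np.mean(np.log(v)))))
            .reset_index()
        )
        df = agg.rename(columns={"_nm": "ic50"})
        df["unit"] = "nM"
    report = {
        "n_records": len(df),
        "n_rejected": n_rejected,
        "per_unit": df["unit"].value_counts().to_dict(),
    }
    logger.info("response table: %(n_records)d records, %(n_rejected)d rejected", report)
    return df.reset_index(drop=True), report


def write_response_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Gene sets from GMT (set name, description, members per tab-separated line)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {i} has no members")
        members = frozenset(p for p in parts[2:] if p)
        if not members:
            raise ValueError(f"{path}: line {i} has no members")
        sets[parts[0]] = members
    if not sets:
        raise ValueError(f"{path} contains no gene sets")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)]) for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_plate_table(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    required = {"combination_id", "ratio_label", "drug_id", "dose", "unit", "viability_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: plate table missing columns {sorted(missing)}")
    return df


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Serializable snapshot of one pipeline run's inputs and options."""

    expression_path: str = ""
    targets_path: str = ""
    responses_path: str = ""
    gene_panel_path: str = ""
    label_scale: str = "ln_uM"
    classification_threshold: float = 10.0
    threshold_unit: str = "nM"
    model: str = "dnn"
    task: str = "regression"
    hyperparameters: dict = field(default_factory=dict)
    train_fraction: float = 0.8
    seed: int = 0
    output_dir: str = "."

    def validate(self) -> "RunConfig":
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.model not in ("dnn", "knn", "rf", "svm", "gbm"):
            raise ValueError(f"unknown model {self.model!r}")
        return self

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text())).validate()
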