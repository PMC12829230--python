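"""Tabular readers/writers and the run-configuration record.

Everything on disk is plain text: TSV with a header row for tables
(count matrix with window_id as the first column; design as
sample_id/group; truth labels; tidy results), JSON for reports and the
run manifest.  Readers validate schemas and point at the offending
row/column on failure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters of one pipeline run; echoed beside every output."""

    seed: int | None = None
    mapq_min: int = 10
    max_window: int = 300
    min_window: int = 20
    max_fragment_len: int = 1500
    ambiguous: str = "drop"
    trim_m: float = 0.30
    trim_a: float = 0.05
    scale: float = 1.0
    n_iter: int = 1000
    subset: int = 10000
    alpha: float = 0.05
    corrections: tuple = ("BH", "bonferroni")
    sim_variant: str = "paper"

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["corrections"] = list(self.corrections)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_counts_tsv(counts: CountMatrix | pd.DataFrame, path) -> None:
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    c.rename_axis("window_id").to_csv(path, sep="\t")


def read_counts_tsv(path, design: pd.Series | None = None) -> CountMatrix:
    """Read a windows x samples count TSV (first column window_id).

    Non-integer or negative cells are rejected with the offending cell named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"counts file {path}: cell ({row!r}, {col!r}) is not a nonnegative integer"
            )
    return CountMatrix(df.astype(np.int64), design=design)


def write_design_tsv(design: pd.Series, path) -> None:
    design.rename_axis("sample_id").rename("group").to_csv(path, sep="\t")


def read_design_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError(f"design file {path}: expected columns sample_id, group")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"design file {path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")["group"]


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="window_id")
    if "is_true_dmr" not in df.columns:
        raise ValueError(f"truth file {path}: missing is_true_dmr column")
    df["is_true_dmr"] = df["is_true_dmr"].astype(bool)
    return df


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"window_id", "method", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results file {path}: missing columns {sorted(missing)}")
    return df


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
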