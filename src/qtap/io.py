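"""Delimited-text input/output for every pipeline stage.

All interchange is plain CSV/TSV with documented headers; the pipeline's
processing boundary starts at integrated transition peak areas, so no vendor
or acquisition-software formats are read. Malformed rows are collected with
their file line numbers rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["RowError", "read_transition_table", "write_transition_table",
           "read_design_table", "read_spike_load_table",
           "read_amino_acid_table", "read_ct_table"]

TRANSITION_COLUMNS = ["sample_id", "protein", "peptide", "transition_id",
                      "label", "peak_area", "detected"]


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based file line number (header is line 1)
    reason: str


def _read_csv(path, required, name):
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read {name} '{path}': {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} '{path}' lacks required column(s): {missing}")
    return df


_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(value):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return None


def read_transition_table(path):
    """Read and validate a transition-level CSV/TSV.

    Returns ``(records, errors)``: validated records (peak_area numeric and
    ≥ 0, label in {light, heavy}, detected boolean) and a list of
    :class:`RowError` for rejected rows, keyed by file line number.
    """
    df = _read_csv(path, TRANSITION_COLUMNS, "transition table")
    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    areas = pd.to_numeric(df["peak_area"], errors="coerce")
    for i in range(len(df)):
        line = i + 2  # header occupies line 1
        if not np.isfinite(areas.iloc[i]):
            errors.append(RowError(line, f"peak_area '{df['peak_area'].iloc[i]}' is not numeric"))
            keep[i] = False
            continue
        if areas.iloc[i] < 0:
            errors.append(RowError(line, f"negative peak_area {areas.iloc[i]}"))
            keep[i] = False
            continue
        if df["label"].iloc[i] not in ("light", "heavy"):
            errors.append(RowError(line, f"label '{df['label'].iloc[i]}' is not light/heavy"))
            keep[i] = False
            continue
        if _parse_bool(df["detected"].iloc[i]) is None:
            errors.append(RowError(line, f"detected '{df['detected'].iloc[i]}' is not boolean"))
            keep[i] = False
    out = df[keep].copy()
    out["peak_area"] = areas[keep]
    out["detected"] = [_parse_bool(v) for v in out["detected"]]
    return out.reset_index(drop=True), errors


def write_transition_table(records: pd.DataFrame, path) -> None:
    cols = TRANSITION_COLUMNS + [c for c in ("group",) if c in records.columns]
    ordered = [c for c in ("sample_id", "group") if c in cols]
    ordered += [c for c in TRANSITION_COLUMNS if c not in ordered]
    records[ordered].to_csv(path, index=False)


def read_design_table(path) -> pd.Series:
    """sample_id → group mapping from a two-column CSV."""
    df = _read_csv(path, ["sample_id", "group"], "design table")
    if df["sample_id"].duplicated().any():
        dup = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"design table '{path}' has duplicate sample id(s): {dup}")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def read_spike_load_table(path):
    """Per-sample spike (fmol) and protein load (μg) as two Series."""
    df = _read_csv(path, ["sample_id", "spike_fmol", "protein_load_ug"],
                   "spike/load table")
    spike = pd.Series(pd.to_numeric(df["spike_fmol"]).to_numpy(), index=df["sample_id"])
    load = pd.Series(pd.to_numeric(df["protein_load_ug"]).to_numpy(), index=df["sample_id"])
    if (spike <= 0).any() or (load <= 0).any():
        raise FormatError(f"spike/load table '{path}' has nonpositive entries")
    return spike, load


def read_amino_acid_table(path) -> pd.DataFrame:
    from .amino_acids import MEASUREMENT_COLUMNS
    return _read_csv(path, MEASUREMENT_COLUMNS, "amino-acid table")


def read_ct_table(path) -> pd.DataFrame:
    from .qpcr import CT_COLUMNS
    return _read_csv(path, CT_COLUMNS, "Ct table")
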