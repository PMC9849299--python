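"""Isotope-dilution relative quantification of amino acids.

Each analyte is measured against a co-spiked stable-isotope-labelled
internal standard (IS); the relative level of a sample is

    level = (analyte area / IS area) / normalizer

where the normalizer is tissue wet weight (mg) for brain or sample volume
(μL) for plasma — making the ratio's units explicit and auditable. Levels
are reported as percent of the control group (control mean ≡ 100%), the
presentation used for between-group amino-acid comparisons. The
method-acceptance precision gate requires ≤ 15% relative standard deviation
on QC replicates.

Percent change between groups is the ratio of group means by default
(mean-of-per-sample-ratios is available via ``method="mean_of_ratios"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .stats import TestResult, student_t_raw

__all__ = [
    "RelativeLevel",
    "AminoAcidComparison",
    "PrecisionResult",
    "relative_quantify",
    "compare_amino_acids",
    "precision_gate",
]

RSD_LIMIT_PERCENT = 15.0  # inclusive method-acceptance bound

MEASUREMENT_COLUMNS = ["sample_id", "group", "analyte", "analyte_area",
                       "is_area", "matrix", "normalizer"]


@dataclass(frozen=True)
class AminoAcidComparison:
    analyte: str
    percent_change: float  # treatment mean as % of control − 100
    test: TestResult
    control_mean_level: float
    treatment_mean_level: float


@dataclass(frozen=True)
class PrecisionResult:
    analyte: str
    rsd_percent: float
    passed: bool | None  # None when RSD is undefined (zero mean)
    n_replicates: int


# kept as a named alias for the per-sample output rows
RelativeLevel = pd.DataFrame


def relative_quantify(measurements: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Compute per-sample relative levels and percent-of-control.

    Returns the input rows with two added columns: ``level`` (analyte/IS
    area ratio per normalizer unit) and ``percent_of_control`` (control-group
    mean per analyte ≡ 100). Missing or nonpositive IS areas are a
    data-integrity error — the ratio is undefined without the standard.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise DataIntegrityError(f"measurement table lacks column(s): {sorted(missing)}")
    if control_group not in set(measurements["group"]):
        raise ConfigurationError(f"control group '{control_group}' not present")
    bad_is = measurements["is_area"].isna() | (measurements["is_area"] <= 0)
    if bad_is.any():
        rows = measurements.loc[bad_is, ["sample_id", "analyte"]].to_dict("records")
        raise DataIntegrityError(f"missing/invalid internal-standard area(s): {rows}")
    bad_norm = measurements["normalizer"].isna() | (measurements["normalizer"] <= 0)
    if bad_norm.any():
        rows = measurements.loc[bad_norm, ["sample_id", "analyte"]].to_dict("records")
        raise DataIntegrityError(f"nonpositive normalizer(s): {rows}")

    out = measurements.copy()
    out["level"] = (out["analyte_area"] / out["is_area"]) / out["normalizer"]
    control_means = (out[out["group"] == control_group]
                     .groupby("analyte")["level"].mean())
    missing_aa = set(out["analyte"]) - set(control_means.index)
    if missing_aa:
        raise DataIntegrityError(
            f"analyte(s) {sorted(missing_aa)} have no control-group measurements")
    out["percent_of_control"] = (out["level"]
                                 / out["analyte"].map(control_means) * 100.0)
    return out


def compare_amino_acids(levels: pd.DataFrame, control_group: str,
                        treatment_group: str,
                        method: str = "ratio_of_means") -> list[AminoAcidComparison]:
    """Per-analyte unpaired t-test on levels plus percent change.

    ``method="ratio_of_means"`` (default) computes the percent change as
    100·(mean_t/mean_c − 1); ``"mean_of_ratios"`` averages per-sample
    percent-of-control in the treatment group instead.
    """
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ConfigurationError(f"unknown percent-change method '{method}'")
    results = []
    for analyte, grp in levels.groupby("analyte", sort=True):
        c = grp.loc[grp["group"] == control_group, "level"].to_numpy(dtype=float)
        t = grp.loc[grp["group"] == treatment_group, "level"].to_numpy(dtype=float)
        if len(c) < 2 or len(t) < 2:
            raise ConfigurationError(
                f"analyte '{analyte}': each group needs ≥ 2 samples")
        test = student_t_raw(t, c)
        if method == "ratio_of_means":
            pct = 100.0 * (np.mean(t) / np.mean(c)) - 100.0
        else:
            pct = float(np.mean(
                grp.loc[grp["group"] == treatment_group, "percent_of_control"])) - 100.0
        results.append(AminoAcidComparison(
            analyte=analyte, percent_change=float(pct), test=test,
            control_mean_level=float(np.mean(c)),
            treatment_mean_level=float(np.mean(t))))
    return results


def precision_gate(qc_replicates, analyte: str = "",
                   limit_percent: float = RSD_LIMIT_PERCENT) -> PrecisionResult:
    """Method-acceptance precision gate: RSD% = 100·sd/mean ≤ limit (inclusive)."""
    x = np.asarray(qc_replicates, dtype=float)
    if x.size < 3:
        raise ConfigurationError(f"precision gate needs ≥ 3 replicates, got {x.size}")
    mean = float(np.mean(x))
    if mean == 0.0:
        return PrecisionResult(analyte=analyte, rsd_percent=math.nan,
                               passed=None, n_replicates=x.size)
    rsd = 100.0 * float(np.std(x, ddof=1)) / abs(mean)
    return PrecisionResult(analyte=analyte, rsd_percent=rsd,
                           passed=bool(rsd <= limit_percent), n_replicates=x.size)
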