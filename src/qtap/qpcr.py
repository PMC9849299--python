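"""Normalized fold gene expression from qPCR Ct values (ΔΔCt method).

Per sample, target Ct is normalized against the housekeeping gene
(ΔCt = Ct_target − Ct_housekeeping), referenced to the calibrator group
(ΔΔCt = ΔCt − mean ΔCt of the calibrator group), and converted to a linear
fold with the primer amplification efficiency E (fold per cycle):

    fold = E^(−ΔΔCt)

With E = 2 this is exactly the classic 2^(−ΔΔCt) computation; per-gene
efficiencies in (1, 2] give the efficiency-corrected variant. Group
statistics run on linear fold values by default (matching mean ± SD bar
displays), with an optional log2 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .stats import TestResult, student_t_raw

__all__ = ["normalized_fold_expression", "compare_fold_expression"]

CT_COLUMNS = ["sample_id", "group", "gene", "ct", "is_housekeeping", "efficiency"]


def normalized_fold_expression(records: pd.DataFrame,
                               calibrator_group: str) -> pd.DataFrame:
    """Per-sample, per-gene normalized fold expression.

    Requires exactly one housekeeping Ct per sample. Returns a DataFrame with
    columns ``sample_id, group, gene, delta_ct, delta_delta_ct, fold``.
    The calibrator group's geometric-mean fold is 1 by construction when
    efficiencies are shared.
    """
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise DataIntegrityError(f"Ct table lacks column(s): {sorted(missing)}")
    if (records["ct"] <= 0).any():
        bad = records.loc[records["ct"] <= 0, ["sample_id", "gene"]].to_dict("records")
        raise DataIntegrityError(f"nonpositive Ct value(s): {bad}")
    eff = records["efficiency"]
    if ((eff <= 1) | (eff > 2)).any():
        bad = sorted(set(records.loc[(eff <= 1) | (eff > 2), "gene"]))
        raise ConfigurationError(f"primer efficiency outside (1, 2] for gene(s): {bad}")
    if calibrator_group not in set(records["group"]):
        raise ConfigurationError(f"calibrator group '{calibrator_group}' not present")

    hk = records[records["is_housekeeping"].astype(bool)]
    hk_per_sample = hk.groupby("sample_id")["ct"]
    if (hk_per_sample.count() > 1).any():
        raise DataIntegrityError("more than one housekeeping Ct for some sample(s)")
    hk_ct = hk_per_sample.first()
    targets = records[~records["is_housekeeping"].astype(bool)].copy()
    no_hk = sorted(set(targets["sample_id"]) - set(hk_ct.index))
    if no_hk:
        raise DataIntegrityError(f"missing housekeeping Ct for sample(s): {no_hk}")

    targets["delta_ct"] = targets["ct"] - targets["sample_id"].map(hk_ct)
    calib_mean = (targets[targets["group"] == calibrator_group]
                  .groupby("gene")["delta_ct"].mean())
    no_calib = sorted(set(targets["gene"]) - set(calib_mean.index))
    if no_calib:
        raise DataIntegrityError(
            f"gene(s) {no_calib} have no calibrator-group measurements")
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(calib_mean)
    targets["fold"] = targets["efficiency"] ** (-targets["delta_delta_ct"])
    return targets[["sample_id", "group", "gene", "delta_ct",
                    "delta_delta_ct", "fold"]].reset_index(drop=True)


def compare_fold_expression(folds: pd.DataFrame, control_group: str,
                            treatment_group: str,
                            scale: str = "linear") -> dict[str, TestResult]:
    """Per-gene unpaired Student's t-test on fold values.

    ``scale="linear"`` tests the folds as displayed; ``"log2"`` tests
    log2-transformed folds (symmetric treatment of up/down regulation).
    """
    if scale not in ("linear", "log2"):
        raise ConfigurationError(f"unknown scale '{scale}'")
    results: dict[str, TestResult] = {}
    for gene, grp in folds.groupby("gene", sort=True):
        c = grp.loc[grp["group"] == control_group, "fold"].to_numpy(dtype=float)
        t = grp.loc[grp["group"] == treatment_group, "fold"].to_numpy(dtype=float)
        if len(c) < 2 or len(t) < 2:
            raise ConfigurationError(f"gene '{gene}': each group needs ≥ 2 samples")
        if scale == "log2":
            c, t = np.log2(c), np.log2(t)
        results[gene] = student_t_raw(t, c)
    return results
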