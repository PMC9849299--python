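"""End-to-end orchestration: transitions → matrix → comparison → reports.

``run_pipeline`` chains the stages on files named in a :class:`RunConfig`
and writes a report bundle (expression matrix CSV + JSON sidecar,
comparison table, optional purity / amino-acid / qPCR outputs) plus a run
manifest recording the package version, seed, settings and per-protein
decisions (ULQ cells, removed outliers), so every reported number is
reproducible from the manifest. Output is deterministic: repeated runs on
the same inputs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import ConfigurationError, PipelineError
from .io import (read_amino_acid_table, read_ct_table, read_design_table,
                 read_spike_load_table, read_transition_table)
from .amino_acids import compare_amino_acids, relative_quantify
from .qpcr import compare_fold_expression, normalized_fold_expression
from .quantify import build_expression_matrix, quantify_dataset
from .reporting import (purity_assessment, render_comparison_table,
                        rows_to_json, summarize_groups)

__all__ = ["run_pipeline"]


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False
    return _Ctx()


def _quantify_stage(config: RunConfig):
    records, row_errors = read_transition_table(config.transitions)
    if records.empty:
        raise ConfigurationError("empty protein panel: transition table has no valid rows")
    if config.spike_load:
        spike, load = read_spike_load_table(config.spike_load)
    else:
        if config.spike_fmol is None or config.protein_load_ug is None:
            raise ConfigurationError(
                "provide either spike_load table or scalar spike_fmol + protein_load_ug")
        spike, load = config.spike_fmol, config.protein_load_ug
    if config.design:
        design = read_design_table(config.design)
    elif "group" in records.columns:
        design = (records[["sample_id", "group"]].drop_duplicates()
                  .set_index("sample_id")["group"])
    else:
        raise ConfigurationError("no design table and no group column in transitions")
    quants, unpaired = quantify_dataset(records, spike, load,
                                        lloq_by_protein=config.lloq)
    matrix = build_expression_matrix(quants, design)
    return matrix, row_errors, unpaired


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "qtap",
        "version": __version__,
        "seed": config.seed,
        "settings": json.loads(config.stats.model_dump_json()),
        "inputs": {k: getattr(config, k) for k in
                   ("transitions", "spike_load", "design", "tissue_transitions",
                    "amino_acids", "qpcr")},
        "stages": {},
    }

    with _stage("quantify"):
        matrix, row_errors, unpaired = _quantify_stage(config)
        matrix.to_csv(out / "expression_matrix.csv")
        matrix.to_json(out / "expression_matrix.json")
        manifest["stages"]["quantify"] = {
            "proteins": matrix.proteins,
            "samples": matrix.samples,
            "rejected_rows": [vars(e) for e in row_errors],
            "unpaired_records": int(len(unpaired)),
            "ulq_cells": {p: [s for s in matrix.samples
                              if matrix.flags.loc[p, s] == "ULQ"]
                          for p in matrix.proteins
                          if (matrix.flags.loc[p] == "ULQ").any()},
        }

    with _stage("compare"):
        rows = summarize_groups(matrix, config.control_group,
                                config.treatment_group, config.stats)
        table = render_comparison_table(rows, config.control_group,
                                        config.treatment_group,
                                        config.stats.ratio_sigfigs)
        table.to_csv(out / "comparison_table.csv", index=False)
        with open(out / "comparison_table.json", "w") as fh:
            json.dump(rows_to_json(rows), fh, indent=1, sort_keys=True)
        manifest["stages"]["compare"] = {
            "outliers_removed": {r.protein: list(r.test.outliers_removed)
                                 for r in rows
                                 if r.test is not None and r.test.outliers_removed},
            "not_testable": [r.protein for r in rows if r.test is None],
        }

    if config.tissue_transitions and config.luminal_marker:
        with _stage("purity"):
            tissue_cfg = config.model_copy(
                update={"transitions": config.tissue_transitions})
            tissue_matrix, _, _ = _quantify_stage(tissue_cfg)
            report = purity_assessment(matrix, tissue_matrix,
                                       config.luminal_marker,
                                       config.abluminal_marker)
            payload = {
                "luminal_marker": report.luminal_marker,
                "abluminal_marker": report.abluminal_marker,
                "marker_group_means": report.marker_group_means,
                "enrichment_ratio": report.enrichment_ratio,
                "enrichment_is_lower_bound": report.enrichment_is_lower_bound,
                "luminal_between_group_p": (
                    None if report.luminal_between_group_test is None
                    else report.luminal_between_group_test.p_value),
            }
            with open(out / "purity.json", "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            manifest["stages"]["purity"] = payload

    if config.amino_acids:
        with _stage("amino-acids"):
            measurements = read_amino_acid_table(config.amino_acids)
            levels = relative_quantify(measurements, config.control_group)
            comparisons = compare_amino_acids(levels, config.control_group,
                                              config.treatment_group)
            pd.DataFrame([{
                "analyte": c.analyte,
                "percent_change": c.percent_change,
                "p_value": c.test.p_value,
            } for c in comparisons]).to_csv(out / "amino_acid_comparison.csv",
                                            index=False)
            manifest["stages"]["amino-acids"] = {
                "analytes": [c.analyte for c in comparisons]}

    if config.qpcr:
        with _stage("qpcr"):
            ct = read_ct_table(config.qpcr)
            calibrator = config.calibrator_group or config.control_group
            folds = normalized_fold_expression(ct, calibrator)
            folds.to_csv(out / "qpcr_folds.csv", index=False)
            tests = compare_fold_expression(folds, config.control_group,
                                            config.treatment_group)
            pd.DataFrame([{
                "gene": g,
                "p_value": t.p_value,
                "t_statistic": t.t_statistic,
            } for g, t in tests.items()]).to_csv(out / "qpcr_comparison.csv",
                                                 index=False)
            manifest["stages"]["qpcr"] = {"genes": sorted(tests)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
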