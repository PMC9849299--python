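"""Isotope-dilution MRM quantification: transition areas → fmol/μg.

Each target protein is quantified through one unique surrogate peptide
monitored on three to four MRM transitions in a light (endogenous) and heavy
(stable-isotope-labelled internal standard, spiked at a known fmol amount)
channel. Per transition, the quantitative value is

    (light area / heavy area) × spike_fmol / protein_load_ug   [fmol/μg]

and the protein's expression is the arithmetic mean of the three or four
per-transition values. When only two or one transitions yield a usable pair
the protein is reported as under the limit of quantification (ULQ) in that
sample, carrying the protein's LLOQ bound for table rendering. The LLOQ of a
protein is determined from a dilution series of the labelled peptide as the
lowest level producing three or four detected transitions.

A transition contributes only when BOTH channels are detected — the ratio is
undefined otherwise; what "detected" means is decided upstream (peak
integration software, or the simulator's area floor).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError

__all__ = [
    "PeptideQuant",
    "ExpressionMatrix",
    "pair_transitions",
    "quantify_peptide",
    "quantify_dataset",
    "determine_lloq",
    "build_expression_matrix",
]

MIN_TRANSITIONS = 3  # fewer usable transitions ⇒ ULQ

STATUS_QUANTIFIED = "quantified"
STATUS_ULQ = "ULQ"

_KEY = ["sample_id", "protein", "peptide", "transition_id"]


@dataclass(frozen=True)
class PeptideQuant:
    """Quantification outcome for one (sample, peptide)."""

    sample_id: str
    protein: str
    peptide: str
    transition_values: tuple  # per-transition fmol/μg, contributing pairs only
    n_detected: int
    status: str  # STATUS_QUANTIFIED or STATUS_ULQ
    expression: float | None = None  # fmol/μg, present iff quantified
    lloq: float | None = None        # bound attached when ULQ

    @property
    def quantified(self) -> bool:
        return self.status == STATUS_QUANTIFIED


def pair_transitions(records: pd.DataFrame):
    """Group light/heavy records into transition pairs.

    Returns ``(pairs, unpaired)``: pairs carry both areas and detected flags
    per (sample, peptide, transition); records lacking a partner are returned
    in ``unpaired`` rather than silently dropped.

    Raises
    ------
    DataIntegrityError
        if any (sample, peptide, transition, label) appears more than once.
    """
    required = set(_KEY + ["label", "peak_area", "detected"])
    missing = required - set(records.columns)
    if missing:
        raise DataIntegrityError(f"transition table lacks column(s): {sorted(missing)}")
    dup_mask = records.duplicated(subset=_KEY + ["label"], keep=False)
    if dup_mask.any():
        dups = (records.loc[dup_mask, _KEY + ["label"]]
                .drop_duplicates().to_dict("records"))
        raise DataIntegrityError(f"duplicate transition rows: {dups}")

    light = records[records["label"] == "light"]
    heavy = records[records["label"] == "heavy"]
    extra = [c for c in ("group",) if c in records.columns]
    merged = pd.merge(
        light[_KEY + extra + ["peak_area", "detected"]],
        heavy[_KEY + ["peak_area", "detected"]],
        on=_KEY, how="outer", suffixes=("_light", "_heavy"), indicator=True)
    pairs = merged[merged["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)
    pairs = pairs.rename(columns={"peak_area_light": "light_area",
                                  "peak_area_heavy": "heavy_area",
                                  "detected_light": "light_detected",
                                  "detected_heavy": "heavy_detected"})
    unpaired = merged[merged["_merge"] != "both"].copy()
    unpaired["missing_label"] = np.where(unpaired["_merge"] == "left_only", "heavy", "light")
    unpaired = unpaired[_KEY + ["missing_label"]].reset_index(drop=True)
    return pairs, unpaired


def _contributing(pairs: pd.DataFrame) -> pd.DataFrame:
    both = pairs[pairs["light_detected"].astype(bool)
                 & pairs["heavy_detected"].astype(bool)]
    zero_heavy = both[both["heavy_area"] == 0]
    if len(zero_heavy):
        keys = zero_heavy[_KEY].to_dict("records")
        raise DataIntegrityError(
            f"internal standard missing: heavy area 0 on detected pair(s) {keys}")
    return both


def quantify_peptide(pairs: pd.DataFrame, spike_fmol: float,
                     protein_load_ug: float, lloq: float | None = None) -> PeptideQuant:
    """Quantify one (sample, peptide) from its transition pairs.

    Pairs contribute only when both channels are detected; expression is the
    arithmetic mean of per-transition values when ≥ 3 contribute, otherwise
    the peptide is ULQ and carries the ``lloq`` bound.
    """
    if spike_fmol <= 0:
        raise ConfigurationError(f"spike_fmol must be > 0, got {spike_fmol}")
    if protein_load_ug <= 0:
        raise ConfigurationError(f"protein_load_ug must be > 0, got {protein_load_ug}")
    if pairs.empty:
        raise DataIntegrityError("quantify_peptide called with no transition pairs")
    keys = pairs[["sample_id", "protein", "peptide"]].drop_duplicates()
    if len(keys) != 1:
        raise DataIntegrityError(f"pairs span multiple (sample, peptide): {keys.to_dict('records')}")
    sample_id, protein, peptide = keys.iloc[0]

    both = _contributing(pairs)
    values = tuple((both["light_area"] / both["heavy_area"]
                    * spike_fmol / protein_load_ug).tolist())
    n = len(values)
    if n >= MIN_TRANSITIONS:
        return PeptideQuant(sample_id, protein, peptide, values, n,
                            STATUS_QUANTIFIED, expression=float(np.mean(values)),
                            lloq=lloq)
    return PeptideQuant(sample_id, protein, peptide, values, n,
                        STATUS_ULQ, expression=None, lloq=lloq)


def quantify_dataset(records: pd.DataFrame, spike_fmol, protein_load_ug,
                     lloq_by_protein: dict | None = None):
    """Quantify every (sample, peptide) in a transition table.

    ``spike_fmol`` / ``protein_load_ug`` may be scalars or per-sample
    mappings (dict or Series indexed by sample_id). Returns
    ``(quants, unpaired)`` where ``quants`` is a list of PeptideQuant.
    """
    pairs, unpaired = pair_transitions(records)
    if len(unpaired):
        warnings.warn(f"{len(unpaired)} unpaired transition record(s) excluded",
                      stacklevel=2)
    lloq_by_protein = lloq_by_protein or {}

    def _per_sample(value, sid, name):
        if np.isscalar(value):
            return float(value)
        try:
            return float(value[sid])
        except KeyError:
            raise ConfigurationError(f"{name} missing for sample '{sid}'") from None

    quants = []
    for (sid, protein, peptide), grp in pairs.groupby(
            ["sample_id", "protein", "peptide"], sort=True):
        quants.append(quantify_peptide(
            grp,
            _per_sample(spike_fmol, sid, "spike_fmol"),
            _per_sample(protein_load_ug, sid, "protein_load_ug"),
            lloq=lloq_by_protein.get(protein)))
    return quants, unpaired


def determine_lloq(dilution_series: dict) -> float | None:
    """Lower limit of quantification from a labelled-peptide dilution series.

    ``dilution_series`` maps concentration level (fmol/μg) to the number of
    transitions detected at that level. Returns the lowest level with 3 or 4
    detected transitions, or None ("not quantifiable") when no level
    qualifies. A qualifying level sitting below a failing one (non-monotone
    series) triggers a warning but the lowest qualifying level is still
    returned.
    """
    if len(dilution_series) < 2:
        raise ConfigurationError("dilution series needs ≥ 2 levels")
    levels = sorted(dilution_series)
    qualifies = [dilution_series[lv] >= MIN_TRANSITIONS for lv in levels]
    if not any(qualifies):
        return None
    lowest = levels[qualifies.index(True)]
    if any(not q for lv, q in zip(levels, qualifies) if lv > lowest):
        warnings.warn(f"non-monotone dilution series: a level above the LLOQ "
                      f"({lowest}) fails the 3-transition rule", stacklevel=2)
    return lowest


# ---------------------------------------------------------------------------
# Expression matrix

NQ = "NQ"  # not quantified: protein not investigated in this dataset

@dataclass
class ExpressionMatrix:
    """Proteins × samples absolute expression with ULQ/NQ flags.

    ``values`` holds fmol/μg floats (NaN where not quantified); ``flags``
    marks each cell as exactly one of ``value`` / ``ULQ`` / ``NQ``; ``lloq``
    carries the per-protein bound rendered in ULQ cells; ``design`` maps
    sample → group.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    design: pd.Series
    lloq: dict = field(default_factory=dict)

    @property
    def proteins(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)

    @property
    def groups(self):
        seen = []
        for g in self.design:
            if g not in seen:
                seen.append(g)
        return seen

    def group_values(self, protein: str, group: str) -> np.ndarray:
        """Quantified values of one protein in one group (ULQ/NQ excluded)."""
        samples = self.design[self.design == group].index
        row = self.values.loc[protein, samples]
        mask = self.flags.loc[protein, samples] == "value"
        return row[mask].to_numpy(dtype=float)

    def render_cell(self, protein: str, sample: str) -> str:
        flag = self.flags.loc[protein, sample]
        if flag == "value":
            return repr(float(self.values.loc[protein, sample]))
        if flag == "ULQ":
            bound = self.lloq.get(protein)
            return f"ULQ<{bound:g}" if bound is not None else "ULQ<"
        return NQ

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            [[self.render_cell(p, s) for s in self.samples] for p in self.proteins],
            index=pd.Index(self.proteins, name="protein"), columns=self.samples)
        header = pd.DataFrame([list(self.design[self.samples])],
                              index=pd.Index(["__group__"], name="protein"),
                              columns=self.samples)
        pd.concat([header, out]).to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "design": {s: self.design[s] for s in self.samples},
            "lloq": {p: self.lloq.get(p) for p in self.proteins},
            "cells": {p: {s: {"flag": self.flags.loc[p, s],
                              "value": (None if math.isnan(self.values.loc[p, s])
                                        else float(self.values.loc[p, s]))}
                          for s in self.samples}
                      for p in self.proteins},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "ExpressionMatrix":
        raw = pd.read_csv(path, index_col=0, dtype=str)
        design = pd.Series(raw.loc["__group__"], name="group")
        body = raw.drop(index="__group__")
        values = pd.DataFrame(np.nan, index=body.index, columns=body.columns)
        flags = pd.DataFrame(NQ, index=body.index, columns=body.columns)
        lloq: dict = {}
        for p in body.index:
            for s in body.columns:
                cell = body.loc[p, s]
                if isinstance(cell, float) or cell == NQ or cell == "":
                    continue
                if cell.startswith("ULQ<"):
                    flags.loc[p, s] = "ULQ"
                    bound = cell[4:]
                    if bound:
                        lloq[p] = float(bound)
                else:
                    flags.loc[p, s] = "value"
                    values.loc[p, s] = float(cell)
        return cls(values=values.astype(float), flags=flags, design=design, lloq=lloq)


def build_expression_matrix(quants, design) -> ExpressionMatrix:
    """Assemble PeptideQuants into a proteins × samples matrix.

    ``design`` maps sample_id → group (dict or Series). The peptide→protein
    map must be 1:1 (single-surrogate-peptide design); two peptides mapped to
    one protein is a configuration error.
    """
    if not quants:
        raise ConfigurationError("no peptide quantifications to assemble")
    design = pd.Series(dict(design), name="group")
    pep_map: dict[str, str] = {}
    for q in quants:
        prev = pep_map.setdefault(q.protein, q.peptide)
        if prev != q.peptide:
            raise ConfigurationError(
                f"protein '{q.protein}' mapped to two peptides "
                f"('{prev}', '{q.peptide}'); the peptide-to-protein map must be 1:1")

    proteins = pd.Index(sorted(pep_map), name="protein")
    samples = [s for s in design.index]
    values = pd.DataFrame(np.nan, index=proteins, columns=samples, dtype=float)
    flags = pd.DataFrame(NQ, index=proteins, columns=samples)
    lloq: dict = {}
    for q in quants:
        if q.sample_id not in design.index:
            raise ConfigurationError(f"sample '{q.sample_id}' missing from design table")
        if q.quantified:
            values.loc[q.protein, q.sample_id] = q.expression
            flags.loc[q.protein, q.sample_id] = "value"
        else:
            flags.loc[q.protein, q.sample_id] = "ULQ"
        if q.lloq is not None:
            lloq[q.protein] = q.lloq
    return ExpressionMatrix(values=values, flags=flags, design=design, lloq=lloq)
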