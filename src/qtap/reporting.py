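"""Reporting surfaces: group-comparison tables, purity checks, cross-model flags.

Produces publication-shaped per-protein comparison rows (mean ± SD per
group, fold ratio, p-value, with "<bound (ULQ)" sentinels), a microvessel
purity assessment based on luminal/abluminal membrane markers, and twofold
cross-model comparison flags classifying differences between two animal
models as interspecies, model-specific or age-dependent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StatsSettings
from .errors import ConfigurationError
from .quantify import ExpressionMatrix
from .stats import (GroupSummary, TestResult, fold_ratio, round_sigfig,
                    rout_outliers, student_t_raw)

__all__ = [
    "GroupComparisonRow",
    "CrossModelFlag",
    "PurityReport",
    "summarize_groups",
    "render_comparison_table",
    "purity_assessment",
    "cross_model_flags",
    "classify_alteration",
]

NOT_COMPARABLE = "not-comparable"


@dataclass(frozen=True)
class GroupComparisonRow:
    """One protein's row of a two-group comparison table."""

    protein: str
    control: GroupSummary | None   # None when the group is ULQ/NQ
    treatment: GroupSummary | None
    ratio: float | None            # treatment/control, full precision
    test: TestResult | None        # None when not testable
    control_flag: str = "value"    # "value" | "ULQ" | "NQ"
    treatment_flag: str = "value"
    lloq: float | None = None
    gene: str | None = None

    @property
    def testable(self) -> bool:
        return self.test is not None


@dataclass(frozen=True)
class CrossModelFlag:
    """Between-model expression ratio flags for one protein."""

    protein: str
    ratio_disease: float | None  # model B / model A, disease groups
    ratio_control: float | None  # model B / model A, control groups
    flagged_disease: bool
    flagged_control: bool
    classification: str


@dataclass(frozen=True)
class PurityReport:
    """Marker-based enrichment report for an isolated-microvessel fraction."""

    luminal_marker: str
    abluminal_marker: str
    marker_group_means: dict            # marker -> {group: mean or None}
    enrichment_ratio: float             # microvessel/tissue, luminal marker
    enrichment_is_lower_bound: bool     # True when tissue side is ULQ
    luminal_between_group_test: TestResult | None
    abluminal_between_group_test: TestResult | None


def _summarize_protein(matrix: ExpressionMatrix, protein: str, group: str,
                       settings: StatsSettings):
    """Return (summary, kept values, flag, removed sample ids) for one cell group."""
    samples = matrix.design[matrix.design == group].index
    flags = matrix.flags.loc[protein, samples]
    quantified = flags == "value"
    if quantified.sum() == 0:
        flag = "ULQ" if (flags == "ULQ").any() else "NQ"
        return None, np.array([]), flag, []
    vals = matrix.values.loc[protein, samples][quantified].to_numpy(dtype=float)
    ids = list(samples[quantified.to_numpy()])
    removed: list = []
    if settings.rout_q and len(vals) >= 3:
        kept, flagged_idx = rout_outliers(vals, q=settings.rout_q)
        removed = [ids[i] for i in flagged_idx]
        vals = kept
    if len(vals) < 2:
        return None, vals, "value", removed
    return GroupSummary.from_values(group, vals), vals, "value", removed


def summarize_groups(matrix: ExpressionMatrix, control_group: str,
                     treatment_group: str,
                     settings: StatsSettings | None = None) -> list[GroupComparisonRow]:
    """Build per-protein comparison rows from an expression matrix.

    Per protein: mean ± SD per group over quantified cells (ULQ excluded),
    fold ratio treatment/control, and the unpaired pooled-variance t-test
    after robust outlier removal at ``settings.rout_q`` (disabled when None).
    A group that is entirely ULQ or NQ renders as a sentinel and suppresses
    ratio and p-value.
    """
    settings = settings or StatsSettings()
    groups = matrix.groups
    if len(groups) < 2:
        raise ConfigurationError(f"expression matrix has {len(groups)} group(s); need ≥ 2")
    for g in (control_group, treatment_group):
        if g not in groups:
            raise ConfigurationError(f"unknown group label '{g}' (have {groups})")

    rows = []
    for protein in matrix.proteins:
        s_c, v_c, f_c, rem_c = _summarize_protein(matrix, protein, control_group, settings)
        s_t, v_t, f_t, rem_t = _summarize_protein(matrix, protein, treatment_group, settings)
        ratio = None
        test = None
        if s_c is not None and s_t is not None:
            ratio = fold_ratio(s_t.mean, s_c.mean)
            test = student_t_raw(v_t, v_c, outliers_removed=tuple(rem_c + rem_t))
        rows.append(GroupComparisonRow(
            protein=protein, control=s_c, treatment=s_t, ratio=ratio, test=test,
            control_flag=f_c, treatment_flag=f_t, lloq=matrix.lloq.get(protein)))
    return rows


def _render_summary(summary: GroupSummary | None, flag: str,
                    lloq: float | None) -> str:
    if summary is not None:
        return f"{summary.mean:.3g} ± {summary.sd:.3g}"
    if flag == "ULQ":
        return f"<{lloq:g} (ULQ)" if lloq is not None else "ULQ"
    return "NQ"


def render_comparison_table(rows: list[GroupComparisonRow],
                            control_label: str = "control",
                            treatment_label: str = "treatment",
                            ratio_sigfigs: int = 2) -> pd.DataFrame:
    """Publication-shaped table: ratios at 2 significant figures, p at 1–3."""
    out = []
    for r in rows:
        out.append({
            "protein": r.protein,
            f"{control_label} mean ± SD": _render_summary(r.control, r.control_flag, r.lloq),
            f"{treatment_label} mean ± SD": _render_summary(r.treatment, r.treatment_flag, r.lloq),
            "ratio": ("" if r.ratio is None or math.isnan(r.ratio)
                      else f"{round_sigfig(r.ratio, ratio_sigfigs):g}"),
            "p_value": "" if r.test is None else f"{r.test.p_value:.2g}",
            "outliers_removed": ("" if r.test is None
                                 else ";".join(map(str, r.test.outliers_removed))),
        })
    return pd.DataFrame(out)


def rows_to_json(rows: list[GroupComparisonRow]) -> list[dict]:
    """Machine-readable rows with unrounded values."""
    payload = []
    for r in rows:
        payload.append({
            "protein": r.protein,
            "control": None if r.control is None else vars(r.control).copy(),
            "treatment": None if r.treatment is None else vars(r.treatment).copy(),
            "control_flag": r.control_flag,
            "treatment_flag": r.treatment_flag,
            "ratio": r.ratio,
            "p_value": None if r.test is None else r.test.p_value,
            "t_statistic": None if r.test is None else r.test.t_statistic,
            "df": None if r.test is None else r.test.df,
            "outliers_removed": [] if r.test is None else list(r.test.outliers_removed),
            "lloq": r.lloq,
        })
    return payload


def purity_assessment(microvessel: ExpressionMatrix, tissue: ExpressionMatrix,
                      luminal_marker: str, abluminal_marker: str) -> PurityReport:
    """Assess microvessel enrichment and fraction comparability via markers.

    The endothelial luminal-membrane marker (e.g. γ-glutamyltransferase)
    should be strongly enriched in isolated microvessels over whole cortical
    tissue; when the tissue side is ULQ the enrichment is reported as a lower
    bound against the ULQ bound. The abluminal plasma-membrane marker (e.g.
    Na+/K+-ATPase) checks that membrane-fraction recovery is comparable
    between the study groups.
    """
    for marker in (luminal_marker, abluminal_marker):
        if marker not in microvessel.proteins:
            raise ConfigurationError(f"marker '{marker}' absent from microvessel panel")
    if luminal_marker not in tissue.proteins:
        raise ConfigurationError(f"marker '{luminal_marker}' absent from tissue panel")

    groups = microvessel.groups
    means: dict = {}
    for marker in (luminal_marker, abluminal_marker):
        means[marker] = {}
        for g in groups:
            vals = microvessel.group_values(marker, g)
            means[marker][g] = float(np.mean(vals)) if len(vals) else None

    mv_all = np.concatenate([microvessel.group_values(luminal_marker, g) for g in groups])
    if mv_all.size == 0:
        raise ConfigurationError(f"marker '{luminal_marker}' is ULQ/NQ in every "
                                 f"microvessel sample; enrichment undefined")
    mv_mean = float(np.mean(mv_all))
    tissue_vals = np.concatenate([tissue.group_values(luminal_marker, g)
                                  for g in tissue.groups])
    if tissue_vals.size:
        enrichment = mv_mean / float(np.mean(tissue_vals))
        lower_bound = False
    else:
        bound = tissue.lloq.get(luminal_marker)
        if not bound:
            raise ConfigurationError(
                f"marker '{luminal_marker}' is ULQ in tissue but has no LLOQ bound")
        enrichment = mv_mean / bound
        lower_bound = True

    def _between_group(marker):
        a = microvessel.group_values(marker, groups[0])
        b = microvessel.group_values(marker, groups[1])
        if len(a) < 2 or len(b) < 2:
            return None
        return student_t_raw(a, b)

    return PurityReport(
        luminal_marker=luminal_marker, abluminal_marker=abluminal_marker,
        marker_group_means=means, enrichment_ratio=enrichment,
        enrichment_is_lower_bound=lower_bound,
        luminal_between_group_test=_between_group(luminal_marker),
        abluminal_between_group_test=_between_group(abluminal_marker))


def _model_ratio(row_b: GroupComparisonRow | None, row_a: GroupComparisonRow | None,
                 side: str) -> float | None:
    sa = getattr(row_a, side, None) if row_a else None
    sb = getattr(row_b, side, None) if row_b else None
    if sa is None or sb is None:
        return None
    r = fold_ratio(sb.mean, sa.mean)
    return None if math.isnan(r) else r


def cross_model_flags(rows_model_a: list[GroupComparisonRow],
                      rows_model_b: list[GroupComparisonRow],
                      threshold: float = 2.0,
                      models_age_differ: bool = False) -> list[CrossModelFlag]:
    """Flag proteins whose expression differs more than ``threshold``-fold
    between two models, separately on the disease and control sides.

    Ratios are model B over model A. A side with an ULQ/NQ group yields no
    ratio and the protein classifies as not-comparable.
    """
    if threshold <= 1:
        raise ConfigurationError(f"threshold must be > 1, got {threshold}")
    a_by = {r.protein: r for r in rows_model_a}
    b_by = {r.protein: r for r in rows_model_b}
    shared = [p for p in a_by if p in b_by]
    if not shared:
        warnings.warn("no shared proteins between the two models", stacklevel=2)
        return []

    flags = []
    for protein in shared:
        rd = _model_ratio(b_by[protein], a_by[protein], "treatment")
        rc = _model_ratio(b_by[protein], a_by[protein], "control")
        fd = rd is not None and (rd > threshold or rd < 1.0 / threshold)
        fc = rc is not None and (rc > threshold or rc < 1.0 / threshold)
        flag = CrossModelFlag(protein=protein, ratio_disease=rd, ratio_control=rc,
                              flagged_disease=fd, flagged_control=fc,
                              classification="")
        classification = classify_alteration(flag, threshold=threshold,
                                             models_age_differ=models_age_differ)
        flags.append(CrossModelFlag(protein=protein, ratio_disease=rd,
                                    ratio_control=rc, flagged_disease=fd,
                                    flagged_control=fc,
                                    classification=classification))
    return flags


def classify_alteration(flag: CrossModelFlag, threshold: float = 2.0,
                        models_age_differ: bool = False) -> str:
    """Classify a between-model expression difference.

    Both sides beyond the threshold in the same direction → an interspecies
    (or, when the compared control groups differ in age, age-dependent)
    difference rather than a disease-model effect; the disease side beyond
    the threshold while the control side is not — or the two sides moving in
    opposite directions — → a model-specific alteration; a side without a
    ratio (ULQ/NQ) → not-comparable; neither side beyond the threshold →
    "none".
    """
    rd, rc = flag.ratio_disease, flag.ratio_control
    if rd is None or rc is None:
        return NOT_COMPARABLE
    fd = rd > threshold or rd < 1.0 / threshold
    fc = rc > threshold or rc < 1.0 / threshold
    if fd and fc:
        same_direction = (rd > 1) == (rc > 1)
        if same_direction:
            return "age-dependent" if models_age_differ else "interspecies"
        return "model-specific"
    if fd or fc:
        return "model-specific"
    return "none"
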