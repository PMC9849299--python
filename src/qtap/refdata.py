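"""Published reference summaries for ABC/SLC transporter expression.

Group-level summary statistics (mean ± SD fmol/μg crude-membrane total
protein, group sizes, ULQ bounds) from published QTAP surveys of transporter
expression in isolated brain microvessels and prefrontal cortex of an
amyloid-pathology mouse model (5xFAD vs wild-type littermates, 8-month-old
females) and of a companion transgenic rat model (TgF344-AD vs wild-type).
These printed summaries are inputs for summary-statistic re-analysis
(fold ratios, pooled t-tests, power calculations) and for building
noiseless synthetic datasets anchored at realistic abundances; the raw
animal-level data behind them are not public.

``printed_ratio`` and ``printed_p`` reproduce the tables' own rounded
columns, for cross-checking recomputed statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import GroupSpec, ProteinSpec, SimConfig
from .stats import GroupSummary

__all__ = [
    "PublishedComparison",
    "MOUSE_MICROVESSELS",
    "RAT_MICROVESSELS",
    "MOUSE_CORTEX",
    "RAT_ABCG2_MICROVESSELS",
    "GAMMA_GTP",
    "NAK_ATPASE",
    "GAMMA_GTP_CORTEX_ULQ_BOUND",
    "AA_BRAIN_EFFECTS",
    "AA_PLASMA_EFFECTS",
    "sim_config_from_published",
]


@dataclass(frozen=True)
class PublishedComparison:
    """One published table row: control vs disease-model group summaries."""

    protein: str
    gene: str
    control: GroupSummary | None  # None when the group printed as ULQ
    disease: GroupSummary | None
    ulq_bound: float | None = None
    printed_ratio: float | None = None
    printed_p: str | None = None  # exactly as printed, e.g. "0.008" or "<0.01"


def _row(protein, gene, c, d, ulq=None, ratio=None, p=None,
         n_control=6, n_disease=6):
    control = None if c is None else GroupSummary("control", n_control, c[0], c[1])
    disease = None if d is None else GroupSummary("disease", n_disease, d[0], d[1])
    return PublishedComparison(protein, gene, control, disease,
                               ulq_bound=ulq, printed_ratio=ratio, printed_p=p)


GAMMA_GTP = "gamma-Gtp"       # endothelial luminal membrane marker
NAK_ATPASE = "Na,K-ATPase"    # abluminal plasma membrane marker
GAMMA_GTP_CORTEX_ULQ_BOUND = 0.03  # fmol/μg; marker ULQ in whole cortex

# Isolated brain microvessels, mouse: WT (n=6) vs 5xFAD (n=6)
MOUSE_MICROVESSELS = {r.protein: r for r in [
    _row("Abcb1", "Abcb1", (3.1, 1.7), (2.2, 1.0), ratio=0.71, p="0.3"),
    _row("Abcg2", "Abcg2", (1.1, 0.38), (1.1, 0.44), ratio=1.0, p="0.9"),
    _row("Abcc1", "Abcc1", (0.065, 0.028), (0.068, 0.037), ratio=1.1, p="0.8"),
    _row("Abcc4", "Abcc4", (0.13, 0.039), (0.16, 0.062), ratio=1.2, p="0.3"),
    _row("Abca1", "Abca1", (0.092, 0.052), (0.097, 0.041), ratio=1.1, p="0.8"),
    _row("ASCT1", "Slc1a4", (0.71, 0.48), (1.5, 0.36), ratio=2.1, p="0.01"),
    _row("GLUT1", "Slc2a1", (46.0, 22.0), (49.0, 21.0), ratio=1.1, p="0.8"),
    _row("4F2hc", "Slc3a2", (0.50, 0.16), (0.72, 0.17), ratio=1.4, p="0.05"),
    _row("CAT-1", "Slc7a1", None, None, ulq=0.15),
    _row("LAT1", "Slc7a5", (0.32, 0.14), (0.12, 0.05), ratio=0.38, p="0.008"),
    _row("MCT1", "Slc16a1", (0.11, 0.07), (0.097, 0.047), ratio=0.88, p="0.7"),
    _row("RFC", "Slc19a1", (0.088, 0.043), (0.099, 0.033), ratio=1.1, p="0.6"),
    _row("OATP1A4", "Slco1a4", (0.36, 0.19), (0.49, 0.16), ratio=1.3, p="0.2"),
    _row("OATP1C1", "Slco1c1", (0.14, 0.038), (0.14, 0.045), ratio=1.0, p="0.9"),
    _row("OCT1", "Slc22a1", None, None, ulq=0.15),
    _row("OAT3", "Slc22a8", (0.31, 0.17), (0.47, 0.28), ratio=1.5, p="0.2"),
    _row("FATP1", "Slc27a1", (0.13, 0.068), (0.086, 0.043), ratio=0.66, p="0.2"),
    _row("ENT1", "Slc29a1", (0.19, 0.10), (0.18, 0.13), ratio=0.95, p="0.8"),
    _row(GAMMA_GTP, "Ggt1", (2.9, 1.2), (2.5, 0.86), ratio=0.86, p="0.5"),
    _row(NAK_ATPASE, "Atp1a1", (29.0, 11.0), (26.0, 2.8), ratio=0.89, p="0.6"),
]}

# Isolated brain microvessels, rat: WT (n=6) vs TgF344-AD (n=6)
RAT_MICROVESSELS = {r.protein: r for r in [
    _row("Abcb1", "Abcb1", (1.6, 0.52), (2.2, 0.61), ratio=1.3, p="0.1"),
    _row("Abcg2", "Abcg2", (0.12, 0.040), (0.37, 0.18), ratio=3.1, p="0.01"),
    _row("Abcc1", "Abcc1", (0.021, 0.007), (0.041, 0.004), ratio=2.0, p="<0.01"),
    _row("Abcc4", "Abcc4", (0.046, 0.025), (0.052, 0.034), ratio=1.1, p="0.7"),
    _row("Abca1", "Abca1", (0.012, 0.009), (0.033, 0.022), ratio=2.8, p="0.09"),
    _row("ASCT1", "Slc1a4", (0.17, 0.10), (0.20, 0.18), ratio=1.2, p="0.7"),
    _row("GLUT1", "Slc2a1", (19.0, 7.6), (20.0, 6.5), ratio=1.1, p="0.7"),
    _row("4F2hc", "Slc3a2", (0.43, 0.22), (0.42, 0.24), ratio=1.0, p="0.9"),
    _row("CAT-1", "Slc7a1", (0.49, 0.21), (0.53, 0.12), ratio=1.1, p="0.7"),
    _row("LAT1", "Slc7a5", None, None, ulq=0.020),
    _row("MCT1", "Slc16a1", None, None, ulq=0.10),
    _row("RFC", "Slc19a1", None, None, ulq=0.15),
    _row("OATP1A4", "Slco1a4", None, None, ulq=0.015),
    _row("OATP1C1", "Slco1c1", (0.13, 0.040), (0.11, 0.080), ratio=0.85, p="0.7"),
    _row("OCT1", "Slc22a1", None, None, ulq=0.15),
    _row("OAT3", "Slc22a8", (0.086, 0.053), (0.089, 0.038), ratio=1.1, p="0.9"),
    _row("FATP1", "Slc27a1", (0.051, 0.038), (0.22, 0.13), ratio=4.3, p="0.01"),
    _row("ENT1", "Slc29a1", (0.027, 0.018), (0.020, 0.012), ratio=0.74, p="0.5"),
    _row(GAMMA_GTP, "Ggt1", (0.61, 0.12), (0.71, 0.11), ratio=1.1, p="0.2"),
    _row(NAK_ATPASE, "Atp1a1", (15.0, 6.8), (19.0, 4.1), ratio=1.3, p="0.2"),
]}

# Brain prefrontal cortex, mouse: WT (n=14) vs 5xFAD (n=12)
MOUSE_CORTEX = {r.protein: r for r in [
    _row("Abcb1", "Abcb1", (0.13, 0.061), (0.15, 0.052), ratio=1.1, p="0.7",
         n_control=14, n_disease=12),
    _row("Abcg2", "Abcg2", (0.46, 0.21), (0.51, 0.24), ratio=1.1, p="0.7",
         n_control=14, n_disease=12),
    _row("Abcc1", "Abcc1", (0.16, 0.033), (0.16, 0.044), ratio=1.0, p="0.8",
         n_control=14, n_disease=12),
    _row("Abcc4", "Abcc4", (0.019, 0.011), (0.026, 0.011), ratio=1.4, p="0.1",
         n_control=14, n_disease=12),
    _row("Abca1", "Abca1", (0.12, 0.077), (0.18, 0.13), ratio=1.5, p="0.3",
         n_control=14, n_disease=12),
    _row("ASCT1", "Slc1a4", (3.1, 1.6), (5.9, 2.5), ratio=1.9, p="0.01",
         n_control=14, n_disease=12),
    _row("GLUT1", "Slc2a1", (3.5, 1.6), (3.8, 1.3), ratio=1.1, p="0.6",
         n_control=14, n_disease=12),
    _row("4F2hc", "Slc3a2", (0.81, 0.31), (0.96, 0.38), ratio=1.2, p="0.4",
         n_control=14, n_disease=12),
    _row("CAT-1", "Slc7a1", None, None, ulq=0.15),
    _row("LAT1", "Slc7a5", (0.73, 0.26), (0.61, 0.18), ratio=0.84, p="0.3",
         n_control=14, n_disease=12),
    _row("MCT1", "Slc16a1", None, None, ulq=0.10),
    _row("RFC", "Slc19a1", None, None, ulq=0.15),
    _row("OATP1A4", "Slco1a4", None, None, ulq=0.015),
    _row("OATP1C1", "Slco1c1", None, None, ulq=0.015),
    _row("OCT1", "Slc22a1", None, None, ulq=0.15),
    _row("OAT3", "Slc22a8", None, None, ulq=0.15),
    _row("FATP1", "Slc27a1", (0.66, 0.39), (0.83, 0.41), ratio=1.3, p="0.4",
         n_control=14, n_disease=12),
    _row("ENT1", "Slc29a1", None, None, ulq=0.03),
    _row(NAK_ATPASE, "Atp1a1", (72.0, 11.0), (72.0, 16.0), ratio=1.0, p="0.9",
         n_control=14, n_disease=12),
]}

# The rat microvessel Abcg2 row anchors the study's sample-size calculation:
# a two-sided test at 5% significance and 80% power on these summaries gives
# 6 observations per group.
RAT_ABCG2_MICROVESSELS = RAT_MICROVESSELS["Abcg2"]

# Published percent-of-control amino-acid effects (treatment vs control mean),
# brain prefrontal cortex and plasma panels (n = 9/9). Values without a
# reported significant change are set to 0.
AA_BRAIN_EFFECTS = {"serine": 25.0, "alanine": 0.0, "phenylalanine": 13.0,
                    "histidine": 30.0, "leucine": 0.0, "isoleucine": 0.0,
                    "tyrosine": 0.0}
AA_PLASMA_EFFECTS = {"serine": 0.0, "alanine": 39.0, "phenylalanine": 16.0,
                     "histidine": 0.0, "leucine": 30.0, "isoleucine": 0.0,
                     "tyrosine": 0.0}


def sim_config_from_published(table: dict, control_label: str = "WT",
                              disease_label: str = "AD", seed: int = 0,
                              **overrides) -> SimConfig:
    """Build a SimConfig whose generating group means are a published table.

    Quantified rows become proteins with the printed group means as true
    abundances; rows printed as ULQ in both groups become zero-abundance
    proteins carrying their printed ULQ bound. Group sizes follow the table.
    """
    proteins = []
    n_c = n_d = 2
    for row in table.values():
        if row.control is not None and row.disease is not None:
            proteins.append(ProteinSpec(
                name=row.protein,
                abundance={control_label: row.control.mean,
                           disease_label: row.disease.mean},
                lloq=row.ulq_bound))
            n_c, n_d = row.control.n, row.disease.n
        else:
            proteins.append(ProteinSpec(
                name=row.protein,
                abundance={control_label: 0.0, disease_label: 0.0},
                lloq=row.ulq_bound))
    return SimConfig(
        seed=seed,
        groups=[GroupSpec(label=control_label, n_samples=n_c),
                GroupSpec(label=disease_label, n_samples=n_d)],
        proteins=proteins,
        **overrides)
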