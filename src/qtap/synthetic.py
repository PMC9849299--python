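"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (isotope-dilution quantification,
group statistics, amino-acid relative quantification, ΔΔCt fold expression)
is exercised against datasets produced here, because the measurement campaign
the package models has no public raw data. The generators emulate the
measurement *structure* — paired light/heavy transition areas with
multiplicative log-normal noise, hard detection dropout at low abundance,
analyte/internal-standard area pairs, and Ct values around a housekeeping
baseline — with every true quantity recorded in a ground-truth table.

Noise model: areas are positive and right-skewed, so both noise layers are
multiplicative log-normal with unit mean; a coefficient of variation CV maps
to the log-scale sigma via sigma² = ln(1 + CV²). Biological variation is one
abundance draw per (sample, protein); technical variation is one draw per
transition and channel. Detection is a hard area floor applied independently
per transition, which reproduces the "only two or one transition(s)"
quantification-failure mode at low abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .config import SimConfig, validation_to_configuration_error
from .errors import ConfigurationError

__all__ = [
    "generate_mrm_dataset",
    "generate_amino_acid_dataset",
    "generate_qpcr_dataset",
]

TRANSITION_COLUMNS = ["sample_id", "group", "protein", "peptide",
                      "transition_id", "label", "peak_area", "detected"]


def _validate(config) -> SimConfig:
    if isinstance(config, SimConfig):
        return config
    try:
        return SimConfig(**dict(config))
    except ValidationError as exc:
        raise validation_to_configuration_error(exc) from exc


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise; CV = 0 gives exact ones."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _sample_frame(groups) -> pd.DataFrame:
    rows = [(f"{g.label}_{i + 1:02d}", g.label)
            for g in groups for i in range(g.n_samples)]
    return pd.DataFrame(rows, columns=["sample_id", "group"])


def generate_mrm_dataset(config: SimConfig, seed: int | None = None):
    """Generate a transition-level MRM dataset plus its ground truth.

    For every sample and surrogate peptide, paired light (endogenous) and
    heavy (stable-isotope-labelled internal standard) records are emitted for
    each transition. Heavy areas reflect ``spike_fmol`` split across
    transitions; light areas reflect the sample's realized abundance times
    ``protein_load_ug``. Transitions whose area falls below
    ``detection_area_floor`` carry ``detected = False``.

    Returns
    -------
    (records, truth) : ``records`` is a DataFrame with columns
        ``sample_id, group, protein, peptide, transition_id, label,
        peak_area, detected``; ``truth`` holds one row per (sample, protein)
        with the realized (biology-included) true abundance in fmol/μg and
        the generating group mean.
    """
    cfg = _validate(config)
    if not cfg.proteins:
        raise ConfigurationError("proteins: at least one protein is required")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    samples = _sample_frame(cfg.groups)
    n_s = len(samples)
    proteins = [p.name for p in cfg.proteins]
    peptides = [p.peptide for p in cfg.proteins]
    n_p = len(proteins)
    n_t = cfg.n_transitions
    fr = np.asarray(cfg.transition_fractions)

    group_means = np.array([[p.abundance[g] for p in cfg.proteins]
                            for g in samples["group"]])  # (n_s, n_p)
    bio = _lognormal_factors(rng, cfg.biological_cv, (n_s, n_p))
    abund = group_means * bio  # realized fmol/μg per sample, protein

    tech = _lognormal_factors(rng, cfg.noise_cv, (n_s, n_p, n_t, 2))
    scale = cfg.response_factor
    light = (abund[:, :, None] * cfg.protein_load_ug * fr[None, None, :]
             * scale * tech[..., 0])
    heavy = cfg.spike_fmol * fr[None, None, :] * scale * tech[..., 1]

    areas = np.stack([light, heavy], axis=-1)  # (n_s, n_p, n_t, 2)
    detected = areas >= cfg.detection_area_floor

    n_rows = n_s * n_p * n_t * 2
    records = pd.DataFrame({
        "sample_id": np.repeat(samples["sample_id"].to_numpy(), n_p * n_t * 2),
        "group": np.repeat(samples["group"].to_numpy(), n_p * n_t * 2),
        "protein": np.tile(np.repeat(proteins, n_t * 2), n_s),
        "peptide": np.tile(np.repeat(peptides, n_t * 2), n_s),
        "transition_id": np.tile(np.repeat([f"T{k + 1}" for k in range(n_t)], 2), n_s * n_p),
        "label": np.tile(["light", "heavy"], n_rows // 2),
        "peak_area": areas.reshape(-1),
        "detected": detected.reshape(-1),
    })

    truth = pd.DataFrame({
        "sample_id": np.repeat(samples["sample_id"].to_numpy(), n_p),
        "group": np.repeat(samples["group"].to_numpy(), n_p),
        "protein": np.tile(proteins, n_s),
        "true_abundance_fmol_per_ug": abund.reshape(-1),
        "group_mean_fmol_per_ug": group_means.reshape(-1),
    })
    return records, truth


def generate_amino_acid_dataset(config: SimConfig, seed: int | None = None):
    """Generate analyte/internal-standard peak-area pairs per sample.

    The control group is centred at 100% and the treatment group at
    ``100 + effect%`` for each amino acid in ``aa_effects``; both the analyte
    and internal-standard areas carry independent multiplicative noise at
    ``noise_cv``.

    Returns ``(measurements, truth)``: measurements with columns
    ``sample_id, group, analyte, analyte_area, is_area, matrix, normalizer``;
    truth with the generating percent-of-control per (analyte, group).
    """
    cfg = _validate(config)
    if not cfg.aa_effects:
        raise ConfigurationError("aa_effects: at least one amino acid is required")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    control, treatment = cfg.group_labels[0], cfg.group_labels[1]
    n_c, n_t_ = cfg.aa_n_per_group
    samples = ([(f"{control}_{i + 1:02d}", control) for i in range(n_c)]
               + [(f"{treatment}_{i + 1:02d}", treatment) for i in range(n_t_)])
    analytes = list(cfg.aa_effects)
    is_base = 5.0e4  # internal-standard area scale, arbitrary units

    rows = []
    for sid, grp in samples:
        for aa in analytes:
            rel = 1.0 if grp == control else 1.0 + cfg.aa_effects[aa] / 100.0
            noise_a, noise_is = _lognormal_factors(rng, cfg.noise_cv, 2)
            analyte_area = rel * cfg.aa_normalizer * is_base * noise_a
            is_area = is_base * noise_is
            rows.append((sid, grp, aa, analyte_area, is_area,
                         cfg.aa_matrix, cfg.aa_normalizer))
    measurements = pd.DataFrame(rows, columns=["sample_id", "group", "analyte",
                                               "analyte_area", "is_area",
                                               "matrix", "normalizer"])
    truth = pd.DataFrame(
        [(aa, grp, 100.0 if grp == control else 100.0 + cfg.aa_effects[aa])
         for aa in analytes for grp in (control, treatment)],
        columns=["analyte", "group", "true_percent_of_control"])
    return measurements, truth


def generate_qpcr_dataset(config: SimConfig, seed: int | None = None):
    """Generate a Ct table with a housekeeping gene and known fold changes.

    Ct = baseline − log_efficiency(true fold) + Gaussian noise; the
    housekeeping gene has fold 1 in every group, so with shared efficiency
    the ΔΔCt method recovers ``qpcr_effects`` exactly in noiseless mode.

    Returns ``(ct_table, truth)``.
    """
    cfg = _validate(config)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    control, treatment = cfg.group_labels[0], cfg.group_labels[1]
    n_c, n_t_ = cfg.qpcr_n_per_group
    samples = ([(f"{control}_{i + 1:02d}", control) for i in range(n_c)]
               + [(f"{treatment}_{i + 1:02d}", treatment) for i in range(n_t_)])
    log_eff = np.log(cfg.primer_efficiency)

    rows = []
    for sid, grp in samples:
        hk_ct = cfg.housekeeping_baseline_ct + rng.normal(0.0, cfg.ct_noise_sd)
        rows.append((sid, grp, cfg.housekeeping_gene, hk_ct, True,
                     cfg.primer_efficiency))
        for gene, fold in cfg.qpcr_effects.items():
            true_fold = 1.0 if grp == control else fold
            ct = (cfg.qpcr_baseline_ct - np.log(true_fold) / log_eff
                  + rng.normal(0.0, cfg.ct_noise_sd))
            rows.append((sid, grp, gene, ct, False, cfg.primer_efficiency))
    ct_table = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct",
                                           "is_housekeeping", "efficiency"])
    genes = list(cfg.qpcr_effects) + [cfg.housekeeping_gene]
    truth = pd.DataFrame(
        [(g, grp, 1.0 if (grp == control or g == cfg.housekeeping_gene)
          else cfg.qpcr_effects[g])
         for g in genes for grp in (control, treatment)],
        columns=["gene", "group", "true_fold"])
    return ct_table, truth
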