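"""Generative and run configuration models.

``SimConfig`` is the full generative specification of a synthetic study:
true per-group transporter abundances (fmol/μg), the transition structure of
each surrogate peptide, the two noise layers (between-animal biological CV
and per-transition technical CV), internal-standard spike and protein load,
the detection floor that produces under-limit-of-quantification dropout, and
the companion amino-acid and qPCR effect tables. ``RunConfig`` wires file
paths and statistical settings for a full pipeline run.

Defaults emulate the study conditions the package models: n = 6 animals per
group for isolated brain microvessels, 50 μg digests with 10 fmol
stable-isotope-labelled peptide spikes, four transitions per peptide,
amino-acid panels of n = 9/9 with percent-of-control effects in the 13–39%
range, and qPCR panels of n = 6 control / 7 disease samples.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigurationError

__all__ = ["GroupSpec", "ProteinSpec", "SimConfig", "StatsSettings", "RunConfig",
           "validation_to_configuration_error"]


def validation_to_configuration_error(exc: ValidationError) -> ConfigurationError:
    """Flatten a pydantic ValidationError into a ConfigurationError naming fields."""
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return ConfigurationError("invalid configuration — " + "; ".join(parts))


class GroupSpec(BaseModel):
    label: str
    n_samples: int

    @model_validator(mode="after")
    def _check(self):
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be ≥ 2 for group '{self.label}'")
        return self


class ProteinSpec(BaseModel):
    """One target protein with a true abundance (fmol/μg) per group."""

    name: str
    abundance: dict[str, float]  # group label -> true mean abundance
    peptide: Optional[str] = None  # surrogate peptide id; defaults to "<name>_pep"
    lloq: Optional[float] = None  # reporting bound attached to ULQ cells

    @model_validator(mode="after")
    def _check(self):
        for g, a in self.abundance.items():
            if a < 0 or not math.isfinite(a):
                raise ValueError(f"abundance for protein '{self.name}', group '{g}' "
                                 f"must be finite and ≥ 0, got {a}")
        if self.peptide is None:
            object.__setattr__(self, "peptide", f"{self.name}_pep")
        return self


class SimConfig(BaseModel):
    """Full generative specification for one synthetic study."""

    seed: int = 0
    groups: list[GroupSpec] = Field(
        default_factory=lambda: [GroupSpec(label="WT", n_samples=6),
                                 GroupSpec(label="AD", n_samples=6)])
    proteins: list[ProteinSpec] = Field(default_factory=list)
    n_transitions: int = 4
    transition_fractions: Optional[list[float]] = None
    noise_cv: float = 0.1          # technical (per-transition) CV
    biological_cv: float = 0.3     # between-sample abundance CV
    spike_fmol: float = 10.0       # labelled-peptide amount per digest
    protein_load_ug: float = 50.0  # total protein per digest
    detection_area_floor: float = 1000.0  # area units
    response_factor: float = 1.0e4        # area units per fmol on column

    # amino-acid stage: percent-of-control effect per analyte (treatment group)
    aa_effects: dict[str, float] = Field(
        default_factory=lambda: {"serine": 25.0, "alanine": 0.0, "phenylalanine": 13.0,
                                 "histidine": 30.0, "leucine": 0.0, "isoleucine": 0.0,
                                 "tyrosine": 0.0})
    aa_n_per_group: tuple[int, int] = (9, 9)
    aa_matrix: str = "brain"
    aa_normalizer: float = 20.0  # mg tissue (brain) or μL plasma

    # qPCR stage: true fold change per gene (housekeeping gene always fold 1)
    qpcr_effects: dict[str, float] = Field(
        default_factory=lambda: {"Gfap": 4.0, "Aif1": 3.0, "Il1b": 2.5})
    qpcr_n_per_group: tuple[int, int] = (6, 7)
    housekeeping_gene: str = "Gapdh"
    primer_efficiency: float = 2.0  # amplification fold per cycle
    ct_noise_sd: float = 0.2        # cycles
    qpcr_baseline_ct: float = 24.0
    housekeeping_baseline_ct: float = 18.0

    @model_validator(mode="after")
    def _check(self):
        if self.n_transitions not in (3, 4):
            raise ValueError(f"n_transitions must be 3 or 4, got {self.n_transitions}")
        if self.transition_fractions is None:
            defaults = {3: [0.5, 0.3, 0.2], 4: [0.4, 0.3, 0.2, 0.1]}
            object.__setattr__(self, "transition_fractions", defaults[self.n_transitions])
        fr = self.transition_fractions
        if len(fr) != self.n_transitions:
            raise ValueError(f"transition_fractions must have n_transitions={self.n_transitions} "
                             f"entries, got {len(fr)}")
        if any(f <= 0 for f in fr):
            raise ValueError("transition_fractions must be strictly positive")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"transition_fractions must sum to 1 within 1e-9, got {sum(fr)}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be ≥ 0, got {self.noise_cv}")
        if self.biological_cv < 0:
            raise ValueError(f"biological_cv must be ≥ 0, got {self.biological_cv}")
        if self.spike_fmol <= 0:
            raise ValueError(f"spike_fmol must be > 0, got {self.spike_fmol}")
        if self.protein_load_ug <= 0:
            raise ValueError(f"protein_load_ug must be > 0, got {self.protein_load_ug}")
        if self.detection_area_floor < 0:
            raise ValueError(f"detection_area_floor must be ≥ 0, got {self.detection_area_floor}")
        if self.response_factor <= 0:
            raise ValueError(f"response_factor must be > 0, got {self.response_factor}")
        if not (1.0 < self.primer_efficiency <= 2.0):
            raise ValueError(f"primer_efficiency must be in (1, 2], got {self.primer_efficiency}")
        if self.ct_noise_sd < 0:
            raise ValueError(f"ct_noise_sd must be ≥ 0, got {self.ct_noise_sd}")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"groups: duplicate labels {labels}")
        for p in self.proteins:
            missing = [g for g in labels if g not in p.abundance]
            if missing:
                raise ValueError(f"proteins: '{p.name}' lacks abundance for group(s) {missing}")
        return self

    # -- convenience -------------------------------------------------------
    @property
    def group_labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def control_group(self) -> str:
        """First group is the control/calibrator by convention."""
        return self.groups[0].label

    @property
    def noiseless_lloq(self) -> float:
        """Implied quantification limit (fmol/μg) in noiseless mode.

        A peptide quantifies only when ≥ 3 transitions clear the area floor;
        with sorted fractions the third-largest is binding.
        """
        f3 = sorted(self.transition_fractions, reverse=True)[2]
        return self.detection_area_floor / (self.protein_load_ug * f3 * self.response_factor)


def make_sim_config(**kwargs) -> SimConfig:
    """Build a SimConfig, turning validation failures into ConfigurationError."""
    try:
        return SimConfig(**kwargs)
    except ValidationError as exc:
        raise validation_to_configuration_error(exc) from exc


class StatsSettings(BaseModel):
    """Statistical settings of the comparison layer."""

    alpha: float = 0.05
    rout_q: Optional[float] = 0.01  # None disables outlier removal
    ratio_sigfigs: int = 2
    twofold_threshold: float = 2.0

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rout_q is not None and not 0 <= self.rout_q <= 0.1:
            raise ValueError(f"rout_q must be in [0, 0.1], got {self.rout_q}")
        if self.twofold_threshold <= 1:
            raise ValueError(f"twofold_threshold must be > 1, got {self.twofold_threshold}")
        return self


class RunConfig(BaseModel):
    """File paths and settings for an end-to-end pipeline run."""

    transitions: str
    spike_load: Optional[str] = None  # CSV sample_id,spike_fmol,protein_load_ug
    design: Optional[str] = None      # CSV sample_id,group (else from transitions)
    spike_fmol: Optional[float] = None
    protein_load_ug: Optional[float] = None
    lloq: dict[str, float] = Field(default_factory=dict)
    control_group: str = "WT"
    treatment_group: str = "AD"
    stats: StatsSettings = Field(default_factory=StatsSettings)
    luminal_marker: Optional[str] = None
    abluminal_marker: Optional[str] = None
    tissue_transitions: Optional[str] = None  # for purity assessment
    amino_acids: Optional[str] = None
    qpcr: Optional[str] = None
    calibrator_group: Optional[str] = None
    seed: int = 0
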