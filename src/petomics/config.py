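"""Configuration objects for the synthetic cohort and the pipeline.

The defaults encode the study conditions the simulator emulates: a 30-patient
paired tumor/normal microarray cohort with a 6-patient metastatic subgroup,
dynamic PET acquired as 28 frames over 60 minutes, and a TCGA-like RNA-seq
cohort of 478 tumors / 41 normals with heavy right-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError


@dataclass
class SurvivalSimConfig:
    """Parameters of the TCGA-like survival cohort generator.

    Event times are exponential; the hazard of samples in the favorable
    (High-Group2) stratum is multiplied by ``planted_hr``, so the Cox model on
    the High-Group2 indicator should recover ``planted_hr``. Censoring is
    independent uniform on ``[0, max_followup]`` (days), thinned so that the
    realized censoring fraction approximates ``censor_rate``.
    """

    n_samples: int = 478
    n_normals: int = 41
    baseline_hazard: float = 5e-4  # events per day for the reference stratum
    planted_hr: float = 0.47
    censor_rate: float = 0.6
    max_followup: float = 3000.0  # days

    def validate(self) -> "SurvivalSimConfig":
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be at least 2")
        if self.n_normals < 0:
            raise ConfigurationError("n_normals must be non-negative")
        if self.planted_hr <= 0:
            raise ConfigurationError("planted_hr must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.max_followup <= 0:
            raise ConfigurationError("baseline_hazard and max_followup must be positive")
        return self


@dataclass
class CohortConfig:
    """Parameters of the paired expression + PET kinetics cohort generator.

    ``latent_loading`` is the coefficient of the shared per-patient tumor
    metabolism factor: it is added to the tumor expression of the
    ``n_linked_genes`` genes and drives ``k3`` (hence Ki, SUV, FD) through a
    monotone log-link, while k1, k2, k4 and VB stay independent of it.
    """

    n_patients: int = 30
    n_genes: int = 1000
    n_de_genes: int = 100
    de_effect: float = 2.0  # |log2 fold change| planted in tumor samples
    n_metastatic: int = 6
    n_linked_genes: int = 40
    latent_loading: float = 0.8
    noise_sd: float = 0.5  # log2-scale residual SD
    seed: int = 0
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)

    def validate(self) -> "CohortConfig":
        if min(self.n_patients, self.n_genes) < 1:
            raise ConfigurationError("n_patients and n_genes must be positive")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ConfigurationError("need 0 <= n_de_genes <= n_genes")
        if not 0 <= self.n_metastatic <= self.n_patients:
            raise ConfigurationError("need 0 <= n_metastatic <= n_patients")
        if not 0 <= self.n_linked_genes <= self.n_de_genes:
            raise ConfigurationError("need 0 <= n_linked_genes <= n_de_genes")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise ConfigurationError("latent_loading must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        self.survival.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        surv = d.pop("survival", {})
        cfg = cls(**d, survival=SurvivalSimConfig(**surv))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
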