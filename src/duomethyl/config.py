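"""Configuration objects for the synthetic cohort generator and the pipeline.

All knobs that matter scientifically live here: cohort size, how much of
methylation variance is additive-genetic (h2), how much of the X chromosome
is subject to inactivation, the latent batch/cell-composition structure, and
the QC / testing thresholds used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is out of its valid range."""


@dataclass
class H2Mixture:
    """Mixture distribution for per-site heritability.

    A point-mass-like component near zero (most CpGs have little additive
    genetic control) plus a spread component covering the long right tail
    seen in published mQTL heritability catalogues.
    """

    frac_low: float = 0.6
    low_range: tuple[float, float] = (0.0, 0.05)
    high_range: tuple[float, float] = (0.05, 0.95)

    def validate(self) -> None:
        if not 0.0 <= self.frac_low <= 1.0:
            raise ConfigError(f"h2 mixture frac_low must be in [0,1], got {self.frac_low}")
        for name, (lo, hi) in (("low_range", self.low_range), ("high_range", self.high_range)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"h2 mixture {name} must satisfy 0 <= lo <= hi <= 1, got ({lo}, {hi})")

    def draw(self, rng, n: int):
        import numpy as np

        low = rng.random(n) < self.frac_low
        out = np.empty(n)
        out[low] = rng.uniform(*self.low_range, size=int(low.sum()))
        out[~low] = rng.uniform(*self.high_range, size=int((~low).sum()))
        return out

    @staticmethod
    def point_mass(value: float) -> "H2Mixture":
        return H2Mixture(frac_low=1.0, low_range=(value, value), high_range=(value, value))


@dataclass
class CohortConfig:
    """Parameters of the paired mother-newborn methylome generator."""

    n_pairs: int = 200
    n_auto_sites: int = 4000
    n_x_sites: int = 1000
    frac_x_inactivated: float = 0.8
    h2_distribution: H2Mixture = field(default_factory=H2Mixture)
    frac_sex_differential: float = 0.01
    sex_effect_sd: float = 0.5
    n_latent_factors: int = 2
    latent_binary: bool = False
    share_latent_within_pair: bool = False
    latent_newborn_only: bool = False
    frac_loaded: float = 0.5
    loading_sd: float = 0.3
    fixed_loading: Optional[float] = None
    noise_sd: float = 0.5
    age_slope_sd: float = 0.005
    maternal_age_range: tuple[float, float] = (15.0, 46.0)
    frac_male: float = 0.545
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pairs", "n_auto_sites", "n_x_sites"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_latent_factors < 0:
            raise ConfigError(f"n_latent_factors must be >= 0, got {self.n_latent_factors}")
        for name in ("frac_x_inactivated", "frac_sex_differential", "frac_loaded", "frac_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.age_slope_sd < 0:
            raise ConfigError(f"age_slope_sd must be >= 0, got {self.age_slope_sd}")
        lo, hi = self.maternal_age_range
        if not lo < hi:
            raise ConfigError(f"maternal_age_range must be increasing, got {self.maternal_age_range}")
        if not isinstance(self.h2_distribution, H2Mixture):
            raise ConfigError("h2_distribution must be an H2Mixture")
        self.h2_distribution.validate()


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (paths, thresholds, stage toggles)."""

    out_dir: str = "duomethyl_run"
    # input paths; when simulate=True the cohort is generated instead
    simulate: bool = True
    maternal_path: Optional[str] = None
    neonatal_path: Optional[str] = None
    pairs_path: Optional[str] = None
    annotation_path: Optional[str] = None
    mask_path: Optional[str] = None
    gmt_path: Optional[str] = None
    replication_results_path: Optional[str] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # QC thresholds (defaults follow common EWAS practice)
    detection_threshold: float = 0.01
    detection_sample_fraction: float = 0.05
    max_missing_fraction: float = 0.02
    # analysis settings
    n_iter_permutation: int = 10
    n_sv: Optional[int] = None  # None = estimate by parallel analysis
    n_perm_sv: int = 10
    include_parity: bool = False
    fdr_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("detection_threshold", "detection_sample_fraction", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if self.n_iter_permutation < 1:
            raise ConfigError("n_iter_permutation must be >= 1")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ConfigError(f"fdr_threshold must be in (0,1), got {self.fdr_threshold}")
        self.cohort.validate()
        if not self.simulate:
            for name in ("maternal_path", "neonatal_path", "pairs_path", "annotation_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"{name} is required when simulate=False")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            h2 = cohort.pop("h2_distribution", {})
            if isinstance(h2, dict):
                h2 = {k: tuple(v) if isinstance(v, Sequence) and not isinstance(v, str) else v
                      for k, v in h2.items()}
                h2 = H2Mixture(**h2)
            if "maternal_age_range" in cohort:
                cohort["maternal_age_range"] = tuple(cohort["maternal_age_range"])
            cohort = CohortConfig(h2_distribution=h2, **cohort)
        cfg = RunConfig(cohort=cohort, **d)
        cfg.validate()
        return cfg

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
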