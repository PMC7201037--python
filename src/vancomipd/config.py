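"""Run-time configuration with documented defaults.

Precedence: built-in defaults < YAML config file < CLI flags.  Every knob that
the dosing engine exposes lives here so that a single object can be threaded
through the library and serialized for audit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

#: Dosing intervals (h) searched by the dose advisor.
DEFAULT_INTERVALS: tuple[float, ...] = (6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class TargetSpec:
    """Exposure target band for dose finding.

    metric is ``auc24_over_mic`` (steady-state AUC24/MIC, default band
    400-600) or ``trough`` (steady-state trough, mg/L).
    """

    metric: str = "auc24_over_mic"
    lower: float = 400.0
    upper: float = 600.0
    mic: float = 1.0

    def __post_init__(self):
        if self.metric not in ("auc24_over_mic", "trough"):
            raise ValueError(f"unknown target metric {self.metric!r}")
        if not self.lower < self.upper:
            raise ValueError("target band must satisfy lower < upper")
        if self.mic <= 0:
            raise ValueError("MIC must be positive")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class RunConfig:
    """All tunable engine settings.

    cv_to_omega: how an interindividual-variability CV% is mapped to the
        log-normal standard deviation omega.  ``"fraction"`` (default) uses
        omega = CV/100, the convention under which the supported models'
        variances were reported; ``"exact"`` uses
        omega = sqrt(ln(1 + (CV/100)^2)).
    pediatric_model: which model serves patients in the >=52-week
        postmenstrual-age tier; the two-compartment adult/adolescent model can
        be selected here for older children.
    creatinine_floor: serum creatinine (mg/dL) below which values are clamped
        before entering covariate equations.
    crcl_denormalize_bsa: if True, de-normalize Schwartz eGFR
        (ml/min/1.73 m^2) to absolute CrCl (ml/min) with Mosteller body
        surface area before feeding the two-compartment model; by default the
        normalized value is used directly.
    """

    model_override: str | None = None
    pediatric_model: str = "le_pediatric"
    cv_to_omega: str = "fraction"
    creatinine_floor: float = 0.1
    crcl_denormalize_bsa: bool = False
    mc_samples: int = 10_000
    mc_seed: int = 12345
    default_infusion_duration_h: float = 1.0
    intervals_h: tuple[float, ...] = DEFAULT_INTERVALS
    rounding_increment_neonate_mg: float = 1.0
    rounding_increment_child_mg: float = 25.0
    rounding_increment_heavy_mg: float = 50.0
    heavy_weight_threshold_kg: float = 40.0
    max_dose_mg: float = 4000.0
    target: TargetSpec = field(default_factory=TargetSpec)
    mic: float = 1.0

    def __post_init__(self):
        if self.cv_to_omega not in ("fraction", "exact"):
            raise ValueError("cv_to_omega must be 'fraction' or 'exact'")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        target = raw.pop("target", None)
        cfg = cls(**raw)
        if target is not None:
            cfg = replace(cfg, target=TargetSpec(**target))
        return cfg

    def rounding_increment(self, weight_kg: float, neonate: bool) -> float:
        if neonate:
            return self.rounding_increment_neonate_mg
        if weight_kg >= self.heavy_weight_threshold_kg:
            return self.rounding_increment_heavy_mg
        return self.rounding_increment_child_mg


DEFAULT_CONFIG = RunConfig()
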