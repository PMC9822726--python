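"""Study-scenario configuration for the synthetic data generator.

Two packaged presets mirror the two study designs the pipeline targets:

``mpr_run``
    A single observational runner ("model proband runner"): baseline, six
    laps, one recovery point, duplicate technical measurements. Planted
    effect profiles are generated from a four-factor latent model
    (anaerobic activity, oxygen release, TCA activity, energetic) whose
    pinned fold changes are the study-scale effects: lactate plateauing at
    4-fold, ketone bodies reaching 16-fold post-exercise, succinate peaking
    near 2-fold, glucose flat, the oxygen-release markers
    (2,3-bisphosphoglycerate, ribose-5-P, ribulose-5-P) peaking at the
    maximum-exertion lap.

``cohort``
    A 26-subject crossover trial (FiO2 0.209 vs 0.145), time points
    baseline/10/20/30 min plus two recovery points, a trimodal perceived
    exertion (RPE) outcome at the last exercise time point, group- and
    arm-dependent effect folds, and intensity-dependent early stopping.

Configurations are plain YAML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

MPR_DESIGN = "mpr_run"
COHORT_DESIGN = "cohort"

MPR_TIME_LABELS = ("baseline", "L1", "L2", "L3", "L4", "L5", "L6", "recovery")
COHORT_TIME_LABELS = ("baseline", "10min", "20min", "30min", "recovery1", "recovery2")
COHORT_EXERCISE_LABELS = ("10min", "20min", "30min")

NORMOXIA = "normoxia"
HYPOXIA = "hypoxia"

RPE_MIN, RPE_MAX = 1.0, 10.0


def arm_key(fio2: float) -> str:
    """Name an inspired-oxygen fraction: sea level vs simulated altitude."""
    return HYPOXIA if fio2 < 0.18 else NORMOXIA


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class TimePoint:
    label: str
    minutes: float


@dataclass
class ScenarioConfig:
    design: str
    n_subjects: int = 1
    replicates: int = 1
    time_points: list[TimePoint] = field(default_factory=list)
    arms: list[float] = field(default_factory=lambda: [0.209])
    rpe_model: dict[str, Any] = field(default_factory=dict)
    #: latent factor model (mpr design): bases {factor label -> per-time value},
    #: loadings {metabolite -> log-fold coefficient per factor, same order}
    factor_model: dict[str, Any] = field(default_factory=dict)
    #: explicit fold tables (cohort design):
    #: metabolite -> rpe group -> arm key -> per-time fold
    effect_profiles: dict[str, Any] = field(default_factory=dict)
    #: planted key-metabolite set of the latent structure
    key_metabolites: list[str] = field(default_factory=list)
    #: lap-to-lap biological variability (log-sd) at exercise time points,
    #: per metabolite; baseline and recovery stay at their planted folds
    lap_wobble: dict[str, float] = field(default_factory=dict)
    #: decoy species get random factor-mixture effect profiles (coefficient
    #: sd per basis) plus their own lap wobble
    decoy_coef_sd: float = 0.0
    decoy_wobble: float = 0.0
    replicate_cv: float = 0.08
    subject_cv: float = 0.0
    run_cv: float = 0.0
    rt_jitter_s: float = 0.3
    mass_jitter_cv: float = 0.02
    sn_ref: float = 600.0
    lod: float = 0.0
    block_plan: dict[str, int] = field(default_factory=lambda: {"max_block_size": 12})
    incomplete_model: dict[str, Any] = field(default_factory=dict)
    n_extra_metabolites: int = 0
    panel_seed: int = 0
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.time_points = [
            tp if isinstance(tp, TimePoint) else TimePoint(**tp) for tp in self.time_points
        ]
        self.validate()

    def validate(self) -> None:
        if self.design not in (MPR_DESIGN, COHORT_DESIGN):
            raise ConfigError(f"unknown design {self.design!r}")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        labels = tuple(tp.label for tp in self.time_points)
        expected = MPR_TIME_LABELS if self.design == MPR_DESIGN else COHORT_TIME_LABELS
        if labels != expected:
            raise ConfigError(f"{self.design} design requires time points {expected}, got {labels}")
        minutes = [tp.minutes for tp in self.time_points]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ConfigError("time points must have strictly increasing minutes")
        for v in self._iter_folds():
            if not v > 0:
                raise ConfigError(f"effect folds must be strictly positive, got {v}")
        traj = self.rpe_model.get("trajectory", [])
        centers = self.rpe_model.get("centers", [])
        for v in list(traj) + list(centers):
            if not RPE_MIN <= v <= RPE_MAX:
                raise ConfigError(f"RPE values must lie in [1, 10], got {v}")
        if self.block_plan.get("max_block_size", 12) < 1:
            raise ConfigError("max_block_size must be >= 1")

    def _iter_folds(self):
        for groups in self.effect_profiles.values():
            for arms in groups.values():
                for folds in arms.values():
                    yield from folds
        for folds in self.mpr_fold_profiles().values():
            yield from folds

    # ------------------------------------------------------------------
    def time_labels(self) -> list[str]:
        return [tp.label for tp in self.time_points]

    def baseline_label(self) -> str:
        return self.time_points[0].label

    def factor_labels(self) -> list[str]:
        return list(self.factor_model.get("bases", {}))

    def all_bases(self) -> dict[str, list[float]]:
        """Main factor bases plus auxiliary effect bases, in loading order."""
        return {**self.factor_model.get("bases", {}),
                **self.factor_model.get("extra_bases", {})}

    def mpr_fold_profiles(self) -> dict[str, list[float]]:
        """Fold-vs-baseline profiles implied by the latent factor model."""
        import numpy as np

        bases = self.all_bases()
        if not bases:
            return {}
        basis = np.array([bases[k] for k in bases], dtype=float)  # factors x time
        out = {}
        for met, coefs in self.factor_model.get("loadings", {}).items():
            logfold = np.asarray(coefs, dtype=float) @ basis
            out[met] = [float(f) for f in np.exp(logfold)]
        return out

    def cohort_fold(self, metabolite: str, group: str, fio2: float) -> list[float]:
        """Planted folds for a metabolite in one (RPE group, arm) cell."""
        prof = self.effect_profiles.get(metabolite)
        if prof is None:
            return [1.0] * len(self.time_points)
        by_arm = prof[group]
        return list(by_arm[arm_key(fio2)])

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["time_points"] = [dataclasses.asdict(tp) for tp in self.time_points]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def preset(cls, name: str) -> "ScenarioConfig":
        """Load a packaged preset (``mpr_run`` or ``cohort``)."""
        ref = resources.files("dropmet") / "presets" / f"{name}.yaml"
        if not ref.is_file():
            raise ConfigError(f"no packaged preset named {name!r}")
        return cls.from_dict(yaml.safe_load(ref.read_text()))
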