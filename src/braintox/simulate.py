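"""Virtual mouse cohorts with the study's longitudinal structure.

The generator emulates a two-strain partial-brain irradiation experiment:
a radiosensitive strain (C3H/He-like, doses 0/40/60/80 Gy) and a
radioresistant strain (C57BL/6-like, 0/45/65/85 Gy), three animals per
irradiated dose plus one sham-irradiated control per strain (10 mice per
strain).  Each mouse gets a pre-irradiation scan at week -1 and biweekly
contrast-enhanced MRI starting in week 1 or 2 (drawn at random per mouse);
after three months the scan interval widens to five weeks; follow-up ends
at six months.

CE lesion volumes follow the dose-volume response model: zero before the
latent onset time, then the growth law with multiplicative lognormal
measurement noise (additive Gaussian on log10 volume, matching the
log-scale fit).  A mouse is sacrificed (event=1) at the first scan whose
volume reaches the sacrifice threshold — a volume-based simplification of
the study's composite health score, calibrated so highest-dose animals
leave the experiment roughly 9-11 weeks after irradiation — and censored
at the follow-up horizon otherwise.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cohort import CohortTable, MouseTrajectory
from .model import C3H_HE, C57BL6, ModelParams, onset_time, predict_volume

__all__ = [
    "StrainSpec",
    "SimulationConfig",
    "build_schedule",
    "simulate_mouse",
    "simulate_cohort",
    "default_config",
]

#: Whole mouse brain volume (µl = mm³); simulated lesions are clipped here.
BRAIN_VOLUME_UL = 491.0


@dataclass(frozen=True)
class StrainSpec:
    """Dose layout and generating parameters for one strain."""

    strain_label: str
    params: ModelParams
    dose_levels: Tuple[float, ...]
    n_per_dose: int = 3
    n_control: int = 1

    def __post_init__(self) -> None:
        if self.n_per_dose < 1:
            raise ValueError("n_per_dose must be >= 1")
        if not self.params.has_growth or not self.params.has_onset:
            raise ValueError(f"{self.strain_label}: generating params must be complete")


@dataclass(frozen=True)
class SimulationConfig:
    """Study layout, scan schedule rules, noise and stopping thresholds.

    Defaults reproduce the study conditions: two strains with the reference
    parameters, biweekly scans from week 1 or 2 widening to 5-week
    intervals after week 13, 26-week horizon, sigma_log10 = 0.1
    measurement noise, 1 µl detection limit and 60 µl sacrifice threshold.
    """

    strain_specs: Tuple[StrainSpec, ...] = (
        StrainSpec("C3H/He", C3H_HE, (40.0, 60.0, 80.0)),
        StrainSpec("C57BL/6", C57BL6, (45.0, 65.0, 85.0)),
    )
    first_scan_choices: Tuple[int, ...] = (1, 2)
    biweekly_interval: float = 2.0
    late_interval: float = 5.0
    late_start: float = 13.0
    max_followup: float = 26.0
    sigma_log10: float = 0.1
    detection_threshold: float = 1.0
    sacrifice_threshold: float = 60.0
    brain_volume_cap: float = BRAIN_VOLUME_UL
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.max_followup > self.late_start > 0):
            raise ValueError("require max_followup > late_start > 0")
        if self.detection_threshold <= 0 or self.sacrifice_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.sacrifice_threshold <= self.detection_threshold:
            raise ValueError("sacrifice_threshold must exceed detection_threshold")
        if self.sigma_log10 < 0:
            raise ValueError("sigma_log10 must be >= 0")

    def to_json(self) -> str:
        cfg = {
            "strain_specs": [
                {
                    "strain_label": s.strain_label,
                    "params": {
                        "a": s.params.a, "b": s.params.b, "d0": s.params.d0,
                        "t1": s.params.t1, "t2": s.params.t2,
                    },
                    "dose_levels": list(s.dose_levels),
                    "n_per_dose": s.n_per_dose,
                    "n_control": s.n_control,
                }
                for s in self.strain_specs
            ],
            "first_scan_choices": list(self.first_scan_choices),
            "biweekly_interval": self.biweekly_interval,
            "late_interval": self.late_interval,
            "late_start": self.late_start,
            "max_followup": self.max_followup,
            "sigma_log10": self.sigma_log10,
            "detection_threshold": self.detection_threshold,
            "sacrifice_threshold": self.sacrifice_threshold,
            "brain_volume_cap": self.brain_volume_cap,
            "seed": self.seed,
        }
        return json.dumps(cfg, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        specs = tuple(
            StrainSpec(
                strain_label=s["strain_label"],
                params=ModelParams(strain_label=s["strain_label"], **s["params"]),
                dose_levels=tuple(s["dose_levels"]),
                n_per_dose=s.get("n_per_dose", 3),
                n_control=s.get("n_control", 1),
            )
            for s in raw.pop("strain_specs")
        )
        raw["first_scan_choices"] = tuple(raw.get("first_scan_choices", (1, 2)))
        return cls(strain_specs=specs, **raw)


def default_config(seed: int = 0, sigma_log10: float = 0.1) -> SimulationConfig:
    """Study-layout configuration with a chosen seed and noise level."""
    return SimulationConfig(seed=seed, sigma_log10=sigma_log10)


def build_schedule(config: SimulationConfig, rng: np.random.Generator) -> List[float]:
    """Scan weeks for one mouse: [-1, s0, s0+2, ...] with a late widening.

    ``s0`` is drawn from ``first_scan_choices``; spacing switches from the
    biweekly to the late interval once ``late_start`` is reached, and a
    terminal scan is placed at ``max_followup`` if the regular grid would
    overshoot it.
    """
    s0 = float(rng.choice(config.first_scan_choices))
    weeks = [-1.0]
    w = s0
    while w <= config.max_followup:
        weeks.append(w)
        w += config.biweekly_interval if w < config.late_start else config.late_interval
    if weeks[-1] < config.max_followup:
        weeks.append(config.max_followup)
    return weeks


def _mouse_rng(seed: int, mouse_id: str) -> np.random.Generator:
    # Stable per-mouse sub-stream: changing cohort composition must not
    # reshuffle the trajectories of existing mice.
    return np.random.default_rng([seed, zlib.crc32(mouse_id.encode("utf-8"))])


def simulate_mouse(
    mouse_id: str,
    strain_label: str,
    dose: float,
    params: ModelParams,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> MouseTrajectory:
    """Generate one animal's trajectory under the dose-volume response model.

    The latent onset is the model onset time (infinite for controls and for
    doses at or below the threshold dose, where the growth law predicts no
    lesion).  Scans before the latent onset read 0; from the onset on, the
    measured volume is the model prediction times ``10**eps`` with
    ``eps ~ N(0, sigma_log10²)``, reported as 0 while below the detection
    threshold.  The first scan at or above the sacrifice threshold is the
    terminal diagnostic scan (event=1); otherwise the mouse is censored at
    the end of follow-up.
    """
    schedule = build_schedule(config, rng)
    if dose > 0 and dose > params.d0:
        latent_onset = onset_time(dose, params)
    else:
        latent_onset = float("inf")

    weeks: List[float] = []
    volumes: List[float] = []
    observed_onset: Optional[float] = None
    event = 0
    for w in schedule:
        v = 0.0
        if w >= latent_onset and w >= 0:
            v = predict_volume(dose, w, params)
            if config.sigma_log10 > 0:
                v *= 10.0 ** rng.normal(0.0, config.sigma_log10)
            if v > config.brain_volume_cap:
                warnings.warn(
                    f"{mouse_id}: simulated CE volume {v:.1f} µl exceeds the "
                    f"brain volume cap {config.brain_volume_cap:g} µl; clipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                v = config.brain_volume_cap
            if v < config.detection_threshold:
                v = 0.0  # below the detection limit of the imaging protocol
        weeks.append(w)
        volumes.append(v)
        if observed_onset is None and v > 0:
            observed_onset = w
        if v >= config.sacrifice_threshold:
            event = 1
            break
    return MouseTrajectory(
        mouse_id=mouse_id,
        strain_label=strain_label,
        dose=dose,
        scan_weeks=weeks,
        volumes=volumes,
        observed_onset=observed_onset,
        last_week=weeks[-1],
        event=event,
    )


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Simulate the full multi-strain cohort; deterministic for a given seed.

    With the default layout this yields 10 mice per strain (3 per
    irradiated dose plus 1 control), 20 in total.
    """
    trajectories: List[MouseTrajectory] = []
    for spec in config.strain_specs:
        layout = [(0.0, spec.n_control)] + [(d, spec.n_per_dose) for d in spec.dose_levels]
        for dose, n in layout:
            for i in range(1, n + 1):
                mouse_id = f"{spec.strain_label}-{dose:g}Gy-{i}"
                rng = _mouse_rng(config.seed, mouse_id)
                trajectories.append(
                    simulate_mouse(mouse_id, spec.strain_label, dose, spec.params, config, rng)
                )
    return CohortTable(trajectories)
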