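"""Cohort container: longitudinal CE-volume scans plus survival outcomes.

A :class:`CohortTable` is the unit of fitting.  It stores one row per MRI
scan (mouse, strain, dose, scan week, CE volume in µl) together with one
survival row per mouse (last observed week and an event flag: 1 =
sacrificed for health deterioration, 0 = censored at follow-up end), and
knows how to extract the inputs of the fitting pipeline:

* onset observations — the first scan per mouse with positive CE volume;
* volume points — positive CE volumes at scans at or after the observed
  onset (pre-onset and zero readings never enter the growth fit; controls
  contribute no points);
* survival records for Kaplan-Meier / log-rank analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import pandas as pd

from .fitting import OnsetObservation, VolumePoint
from .survival import SurvivalRecord

__all__ = ["MouseTrajectory", "CohortTable"]

SCAN_COLUMNS = ["mouse_id", "strain", "dose_gy", "scan_week", "ce_volume_ul"]
SURVIVAL_COLUMNS = ["mouse_id", "strain", "dose_gy", "last_week", "event"]


@dataclass
class MouseTrajectory:
    """One animal's scan series and outcome.

    ``scan_weeks`` starts with the pre-irradiation scan at week -1 and ends
    at ``last_week`` (the sacrifice scan for ``event=1``, the follow-up
    horizon otherwise).  ``volumes`` are µl aligned with ``scan_weeks``;
    0 means no detectable contrast enhancement.
    """

    mouse_id: str
    strain_label: str
    dose: float
    scan_weeks: List[float] = field(default_factory=list)
    volumes: List[float] = field(default_factory=list)
    observed_onset: Optional[float] = None
    last_week: float = 0.0
    event: int = 0

    def __post_init__(self) -> None:
        if len(self.scan_weeks) != len(self.volumes):
            raise ValueError(f"{self.mouse_id}: scan_weeks and volumes must align")
        if any(v < 0 for v in self.volumes):
            raise ValueError(f"{self.mouse_id}: negative CE volume")
        if self.event not in (0, 1):
            raise ValueError(f"{self.mouse_id}: event flag must be 0 or 1")

    def onset_observation(self) -> Optional[OnsetObservation]:
        if self.observed_onset is None or self.dose <= 0:
            return None
        return OnsetObservation(self.mouse_id, self.dose, self.observed_onset)

    def volume_points(self) -> List[VolumePoint]:
        """Positive CE volumes at scans at or after the observed onset."""
        if self.observed_onset is None or self.dose <= 0:
            return []
        return [
            VolumePoint(self.mouse_id, self.dose, w, v)
            for w, v in zip(self.scan_weeks, self.volumes)
            if w >= self.observed_onset and v > 0
        ]

    def survival_record(self) -> SurvivalRecord:
        return SurvivalRecord(
            mouse_id=self.mouse_id,
            group_label=f"{self.strain_label}:{self.dose:g}",
            time=self.last_week,
            event=self.event,
        )


@dataclass
class CohortTable:
    """Collection of :class:`MouseTrajectory` records for one or both strains."""

    trajectories: List[MouseTrajectory] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def strains(self) -> List[str]:
        seen: List[str] = []
        for tr in self.trajectories:
            if tr.strain_label not in seen:
                seen.append(tr.strain_label)
        return seen

    def for_strain(self, strain_label: str) -> "CohortTable":
        return CohortTable([t for t in self.trajectories if t.strain_label == strain_label])

    def onset_observations(self) -> List[OnsetObservation]:
        return [o for t in self.trajectories if (o := t.onset_observation()) is not None]

    def volume_points(self) -> List[VolumePoint]:
        return [p for t in self.trajectories for p in t.volume_points()]

    def survival_records(self) -> List[SurvivalRecord]:
        return [t.survival_record() for t in self.trajectories]

    def scan_frame(self) -> pd.DataFrame:
        rows = [
            (t.mouse_id, t.strain_label, t.dose, w, v)
            for t in self.trajectories
            for w, v in zip(t.scan_weeks, t.volumes)
        ]
        return pd.DataFrame(rows, columns=SCAN_COLUMNS)

    def survival_frame(self) -> pd.DataFrame:
        rows = [
            (t.mouse_id, t.strain_label, t.dose, t.last_week, t.event)
            for t in self.trajectories
        ]
        return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)

    @classmethod
    def from_frames(
        cls, scans: pd.DataFrame, survival: Optional[pd.DataFrame] = None
    ) -> "CohortTable":
        """Rebuild trajectories from long-format scan and survival tables.

        The observed onset is recomputed as the first scan with positive
        volume; without a survival table every mouse is censored at its
        last scan.
        """
        trajectories = []
        surv_by_mouse = {}
        if survival is not None:
            surv_by_mouse = {r.mouse_id: r for r in survival.itertuples(index=False)}
        for mouse_id, grp in scans.groupby("mouse_id", sort=False):
            grp = grp.sort_values("scan_week")
            weeks = grp["scan_week"].tolist()
            vols = grp["ce_volume_ul"].tolist()
            onset = next((w for w, v in zip(weeks, vols) if v > 0), None)
            surv = surv_by_mouse.get(mouse_id)
            trajectories.append(
                MouseTrajectory(
                    mouse_id=str(mouse_id),
                    strain_label=str(grp["strain"].iloc[0]),
                    dose=float(grp["dose_gy"].iloc[0]),
                    scan_weeks=weeks,
                    volumes=vols,
                    observed_onset=onset,
                    last_week=float(surv.last_week) if surv is not None else float(weeks[-1]),
                    event=int(surv.event) if surv is not None else 0,
                )
            )
        return cls(trajectories)
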