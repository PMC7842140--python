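"""Fitting pipeline for the dose-volume response model.

Mirrors the two-stage protocol used to parameterise the model:

1. closed-form ordinary least squares of observed onset weeks on ln(dose)
   for the training strain, then out-of-sample validation of those onset
   parameters on the second strain;
2. global nonlinear least squares of the growth law
   ``log10 V = a (D - d0) t**b`` over all post-onset CE volume points of
   the training strain, followed by a one-parameter cross-strain transfer
   in which only the growth exponent ``b`` is refitted.

All volume fitting is done on the log10-volume scale, matching the model
statement; R² is reported on the fitted scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
from scipy.optimize import least_squares

from .model import ModelParams

__all__ = [
    "OnsetObservation",
    "VolumePoint",
    "FitResult",
    "r_squared",
    "fit_onset_model",
    "validate_onset_model",
    "fit_volume_model",
]

#: Parameters of the growth law that may be freed in fit_volume_model.
GROWTH_PARAMS = ("a", "b", "d0")

# Single deterministic start for the volume fit: with only three dose
# levels, a and d0 are weakly identified, so a fixed initialisation plus
# bounds keeps the result reproducible.
_DEFAULT_INIT = {"a": 0.01, "b": 0.5}
_OBJECTIVE_TOL = 1e-10


@dataclass(frozen=True)
class OnsetObservation:
    """First scan week with detectable contrast enhancement for one mouse."""

    mouse_id: str
    dose: float
    onset_week: float

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError(f"{self.mouse_id}: dose must be > 0, got {self.dose}")
        if self.onset_week < 0:
            raise ValueError(f"{self.mouse_id}: onset week must be >= 0, got {self.onset_week}")


@dataclass(frozen=True)
class VolumePoint:
    """One post-onset CE volume measurement (µl) entering the growth fit."""

    mouse_id: str
    dose: float
    t: float
    volume: float

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"{self.mouse_id}: CE volume must be > 0, got {self.volume}")
        if not self.t > 0:
            raise ValueError(f"{self.mouse_id}: follow-up time must be > 0, got {self.t}")


@dataclass
class FitResult:
    """Outcome of one fitting or validation step.

    ``residuals`` are observed minus predicted on the fitted scale
    (onset weeks for the onset model, log10 µl for the volume model).
    """

    params: ModelParams
    free_params: Set[str]
    r_squared: float
    n_points: int
    residuals: List[float] = field(default_factory=list)
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise ValueError(f"r_squared cannot exceed 1, got {self.r_squared}")
        if len(self.residuals) != self.n_points:
            raise ValueError("residuals length must equal n_points")
        if self.converged and self.n_points < len(self.free_params):
            raise ValueError("fewer points than free parameters")

    def to_dict(self) -> dict:
        p = self.params
        return {
            "strain": p.strain_label,
            "params": {"a": p.a, "b": p.b, "d0": p.d0, "t1": p.t1, "t2": p.t2},
            "free": sorted(self.free_params),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
        }


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SSres/SStot``.

    ``SStot`` uses the mean of ``observed``; may be negative for predictions
    worse than the mean, never exceeds 1.

    Raises
    ------
    ValueError
        On length mismatch, empty input, or zero variance in ``observed``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_onset_model(
    observations: Sequence[OnsetObservation], strain_label: str = ""
) -> FitResult:
    """Closed-form OLS of onset week on ln(dose): ``t_on = t1 + t2 ln D``.

    Unweighted, one observation per mouse.  Requires at least three
    observations spanning at least two distinct doses (otherwise the design
    is singular).  The returned parameters carry only ``t1``/``t2``.
    """
    obs = list(observations)
    if len(obs) < 3:
        raise ValueError(f"need >= 3 onset observations, got {len(obs)}")
    doses = np.array([o.dose for o in obs])
    if len(set(doses.tolist())) < 2:
        raise ValueError("singular design: onset fit needs >= 2 distinct doses")
    y = np.array([o.onset_week for o in obs])
    X = np.column_stack([np.ones_like(doses), np.log(doses)])
    (t1, t2), *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ np.array([t1, t2])
    params = ModelParams(t1=float(t1), t2=float(t2), strain_label=strain_label)
    return FitResult(
        params=params,
        free_params={"t1", "t2"},
        r_squared=r_squared(y, pred),
        n_points=len(obs),
        residuals=(y - pred).tolist(),
    )


def validate_onset_model(
    params: ModelParams, observations: Sequence[OnsetObservation]
) -> FitResult:
    """Out-of-sample check of fixed onset parameters on an independent cohort.

    No refitting: predictions come from the given ``t1``/``t2`` and R² is
    computed against the validation set's own mean (the standard
    out-of-sample definition).
    """
    if not params.has_onset:
        raise ValueError("params must carry onset parameters t1, t2")
    obs = list(observations)
    if not obs:
        raise ValueError("validation requires a non-empty observation list")
    y = np.array([o.onset_week for o in obs])
    pred = np.array([max(0.0, params.t1 + params.t2 * np.log(o.dose)) for o in obs])
    return FitResult(
        params=params,
        free_params=set(),
        r_squared=r_squared(y, pred),
        n_points=len(obs),
        residuals=(y - pred).tolist(),
    )


def fit_volume_model(
    points: Sequence[VolumePoint],
    free: Iterable[str] = GROWTH_PARAMS,
    fixed: Optional[Dict[str, float]] = None,
    init: Optional[Dict[str, float]] = None,
    strain_label: str = "",
) -> FitResult:
    """Global nonlinear least squares of the growth law on the log10 scale.

    Minimises ``sum (log10 V_obs - a (D - d0) t**b)**2`` over the parameters
    named in ``free`` (subset of ``{"a", "b", "d0"}``), holding those in
    ``fixed`` at the given values.  The cross-strain transfer fit is this
    operation with ``free={"b"}`` and ``a``/``d0`` fixed at the training
    strain's estimates.

    Bounds ``a in (0, 1]``, ``b in (0, 2]``, ``d0 in [0, min dose)`` and a
    deterministic start (``a=0.01, b=0.5, d0=min dose - 10``, overridable
    via ``init``) make the fit reproducible despite the weak joint
    identifiability of ``a`` and ``d0`` when only a few dose levels are
    present.  Optimiser non-convergence is returned as a flagged failure
    (``converged=False``), never silently.
    """
    pts = list(points)
    free = set(free)
    fixed = dict(fixed or {})
    init = dict(init or {})
    if not free:
        raise ValueError("at least one free parameter required")
    if not free <= set(GROWTH_PARAMS):
        raise ValueError(f"free parameters must be among {GROWTH_PARAMS}, got {sorted(free)}")
    if free & set(fixed):
        raise ValueError(f"parameters cannot be both free and fixed: {sorted(free & set(fixed))}")
    missing = set(GROWTH_PARAMS) - free - set(fixed)
    if missing:
        raise ValueError(f"parameters neither free nor fixed: {sorted(missing)}")
    if len(pts) < len(free):
        raise ValueError(f"need >= {len(free)} points for {len(free)} free parameters")

    dose = np.array([p.dose for p in pts])
    t = np.array([p.t for p in pts])
    logv = np.log10([p.volume for p in pts])
    min_dose = float(dose.min())

    defaults = dict(_DEFAULT_INIT, d0=max(0.0, min_dose - 10.0))
    lower = {"a": 1e-12, "b": 1e-12, "d0": 0.0}
    upper = {"a": 1.0, "b": 2.0, "d0": min_dose * (1 - 1e-9)}
    order = [name for name in GROWTH_PARAMS if name in free]
    x0 = np.array([np.clip(init.get(n, defaults[n]), lower[n], upper[n]) for n in order])

    def unpack(theta: np.ndarray) -> Dict[str, float]:
        full = dict(fixed)
        full.update(zip(order, theta))
        return full

    def resid(theta: np.ndarray) -> np.ndarray:
        p = unpack(theta)
        return logv - p["a"] * (dose - p["d0"]) * t ** p["b"]

    sol = least_squares(
        resid,
        x0,
        bounds=([lower[n] for n in order], [upper[n] for n in order]),
        method="trf",
        ftol=_OBJECTIVE_TOL,
        xtol=1e-12,
        gtol=1e-12,
    )
    est = {k: float(v) for k, v in unpack(sol.x).items()}
    params = ModelParams(
        a=est["a"], b=est["b"], d0=est["d0"],
        t1=fixed.get("t1"), t2=fixed.get("t2"),
        strain_label=strain_label,
    )
    residuals = resid(sol.x)
    if not sol.success:
        return FitResult(
            params=params, free_params=free, r_squared=-np.inf, n_points=len(pts),
            residuals=residuals.tolist(), converged=False,
            message=f"optimizer did not converge: {sol.message}",
        )
    return FitResult(
        params=params,
        free_params=free,
        r_squared=r_squared(logv, logv - residuals),
        n_points=len(pts),
        residuals=residuals.tolist(),
    )
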