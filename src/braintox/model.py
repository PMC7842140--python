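"""Dose-volume response model for radiation-induced blood-brain-barrier damage.

After high-dose, spatially confined irradiation of a brain subvolume, the
blood-brain barrier breaks down and MRI contrast agent leaks into the
tissue.  Two empirical relations describe the process as a function of the
prescribed dose ``D`` (Gy) and follow-up time ``t`` (weeks, week 0 =
irradiation day):

* the *onset time* of first contrast enhancement decreases logarithmically
  with dose,

  .. math:: t_{on}(D) = t_1 + t_2 \\ln(D/\\mathrm{Gy}), \\qquad t_2 < 0,

  clamped at 0 weeks (an onset cannot precede irradiation);

* for ``t >= t_on(D)`` the contrast-enhancing (CE) lesion volume grows as

  .. math:: \\log_{10}(V/\\mathrm{\\mu l}) = a\\,(D - D_0)\\,(t/\\mathrm{week})^b,

  i.e. linearly in dose above a threshold dose ``D_0`` and with a power of
  follow-up time.

This module evaluates the two relations and the analytic inverse of the
growth law.  Everything is pure computation; fitting lives in
:mod:`braintox.fitting` and cohort simulation in :mod:`braintox.simulate`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "ModelParams",
    "PreOnsetWarning",
    "onset_time",
    "predict_volume",
    "time_to_volume",
    "C3H_HE",
    "C57BL6",
]


class PreOnsetWarning(UserWarning):
    """Volume model evaluated before the predicted onset time.

    The growth law is only meaningful for ``t >= t_on(D)``; earlier
    evaluations are allowed (the function is defined) but flagged.
    """


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the dose-volume response model for one mouse strain.

    Fields may be ``None`` when a sub-model is not parameterised (an onset
    fit carries only ``t1``/``t2``).  Invariants are enforced on the fields
    that are set.

    Parameters
    ----------
    a : float, optional
        Growth-rate coefficient per Gy (Gy^-1); ``a > 0``.
    b : float, optional
        Time exponent of the growth law (dimensionless); ``b > 0``.
        Smaller ``b`` means slower lesion progression.
    d0 : float, optional
        Threshold dose (Gy) below which no CE volume growth is predicted;
        ``d0 >= 0``.
    t1 : float, optional
        Onset intercept (weeks): predicted onset at 1 Gy.
    t2 : float, optional
        Onset slope coefficient (weeks per ln-Gy); must be negative so that
        onset decreases with dose.
    strain_label : str
        Free-text label of the cohort the parameters describe.
    """

    a: Optional[float] = None
    b: Optional[float] = None
    d0: Optional[float] = None
    t1: Optional[float] = None
    t2: Optional[float] = None
    strain_label: str = ""

    def __post_init__(self) -> None:
        if self.a is not None and not self.a > 0:
            raise ValueError(f"growth coefficient a must be > 0, got {self.a}")
        if self.b is not None and not self.b > 0:
            raise ValueError(f"time exponent b must be > 0, got {self.b}")
        if self.d0 is not None and self.d0 < 0:
            raise ValueError(f"threshold dose d0 must be >= 0, got {self.d0}")
        if self.t2 is not None and not self.t2 < 0:
            raise ValueError(
                f"onset slope t2 must be negative (onset decreases with dose), got {self.t2}"
            )

    @property
    def has_onset(self) -> bool:
        return self.t1 is not None and self.t2 is not None

    @property
    def has_growth(self) -> bool:
        return self.a is not None and self.b is not None and self.d0 is not None

    def updated(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


#: Reference parameters for the radiosensitive strain (C3H/He).
C3H_HE = ModelParams(a=0.0155, b=0.40, d0=30.0, t1=55.75, t2=-12.5, strain_label="C3H/He")

#: Reference parameters for the radioresistant strain (C57BL/6); only the
#: growth exponent differs from the sensitive strain.
C57BL6 = ModelParams(a=0.0155, b=0.28, d0=30.0, t1=55.75, t2=-12.5, strain_label="C57BL/6")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def onset_time(dose: float, params: ModelParams) -> float:
    """Predicted onset time (weeks) of contrast enhancement at ``dose`` Gy.

    ``t_on = max(0, t1 + t2 ln(D/Gy))``; strictly decreasing in dose on the
    un-clamped branch since ``t2 < 0``.

    Raises
    ------
    ValueError
        If ``dose <= 0`` or ``params`` carries no onset parameters.
    """
    _require(dose > 0, f"dose must be positive, got {dose}")
    _require(params.has_onset, "params must carry onset parameters t1, t2")
    return max(0.0, params.t1 + params.t2 * math.log(dose))


def predict_volume(dose: float, t: float, params: ModelParams) -> float:
    """CE lesion volume (µl) at follow-up time ``t`` weeks after ``dose`` Gy.

    Evaluates ``10**(a (D - d0) t**b)``.  The growth law is meaningful only
    for ``t >= t_on(D)``; earlier times are evaluated but produce a
    :class:`PreOnsetWarning` when onset parameters are available.

    Raises
    ------
    ValueError
        If ``t < 0`` or ``params`` carries no growth parameters.
    """
    _require(t >= 0, f"follow-up time must be >= 0, got {t}")
    _require(params.has_growth, "params must carry growth parameters a, b, d0")
    if params.has_onset and dose > 0 and t < onset_time(dose, params):
        warnings.warn(
            f"volume model evaluated at t={t} weeks, before the predicted "
            f"onset {onset_time(dose, params):.3f} weeks at {dose} Gy",
            PreOnsetWarning,
            stacklevel=2,
        )
    return 10.0 ** (params.a * (dose - params.d0) * t**params.b)


def time_to_volume(target_volume: float, dose: float, params: ModelParams) -> float:
    """Time (weeks) at which the growth law reaches ``target_volume`` µl.

    Analytic inverse of :func:`predict_volume`:
    ``t = (log10(V) / (a (D - d0)))**(1/b)``.  Defined only above the
    threshold dose and for targets above 1 µl (where log10 V > 0).

    Raises
    ------
    ValueError
        If ``dose <= d0`` or ``target_volume <= 1`` µl (no solution).
    """
    _require(params.has_growth, "params must carry growth parameters a, b, d0")
    _require(dose > params.d0, f"no solution: dose {dose} Gy <= threshold dose {params.d0} Gy")
    _require(target_volume > 1.0, f"no solution: target volume {target_volume} µl <= 1 µl")
    return (math.log10(target_volume) / (params.a * (dose - params.d0))) ** (1.0 / params.b)
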