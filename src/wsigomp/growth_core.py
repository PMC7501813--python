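"""Core water-stress growth model.

The model couples a Gompertz growth curve to daily soil water content.
Projected shoot area (PSA, summed plant pixels, a proxy for shoot
biomass) on day ``d`` with standardized time ``t_d`` in [0, 1] is

    PSA(t_d) = PSA_max * exp(-exp(-r * (t_d - WSI_d ** alpha)))

where ``WSI_d`` is the water stress index computed from the fraction of
pot field capacity (FC),

    WSI = (FC - FC_crit) / (FC_opt - FC_crit),  clamped to [0, 1].

``WSI = 1`` means no stress, ``WSI = 0`` means growth-arresting stress.
The inflection of the curve occurs when ``t`` exceeds ``WSI ** alpha``;
the first day on which this difference is strictly positive is the time
of inflection (TOI), a derived ordinal phenotype.  With a constant WSI
``w`` the model reduces exactly to the classical Gompertz curve with
inflection ``t0 = w ** alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

CONTROL = "control"
DROUGHT = "drought"
TREATMENTS = (CONTROL, DROUGHT)

__all__ = [
    "CONTROL",
    "DROUGHT",
    "TREATMENTS",
    "WSIParams",
    "GrowthParams",
    "PlantTrajectory",
    "TOIRecord",
    "standardize_time",
    "compute_wsi",
    "gompertz_classic",
    "wsi_gomp_predict",
    "time_of_inflection",
    "compute_water_use",
]


@dataclass(frozen=True)
class WSIParams:
    """Field-capacity anchor points of the water stress index.

    ``fc_opt`` is the fraction of field capacity at which growth is
    optimal (saturated soil); ``fc_crit`` the fraction at which growth
    ceases.  Both are genotype-dependent in reality; the standard
    assumption used throughout is ``fc_opt=1.0``, ``fc_crit=0.1``.
    """

    fc_opt: float = 1.0
    fc_crit: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.fc_crit < self.fc_opt <= 1.0):
            raise ValueError(
                f"require 0 <= fc_crit < fc_opt <= 1, got "
                f"fc_crit={self.fc_crit}, fc_opt={self.fc_opt}"
            )


@dataclass
class GrowthParams:
    """Parameters of the water-stress Gompertz model for one genotype.

    psa_max : asymptotic shoot area (pixels).
    r       : absolute growth rate per unit standardized time.
    alpha   : genotype-specific exponent tuning how strongly WSI shifts
              the inflection of the curve.
    t0      : inflection time of the classical model (standardized time);
              unused by the WSI-coupled model.
    """

    psa_max: float
    r: float
    alpha: float = 1.0
    t0: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.psa_max > 0 and self.r > 0 and self.alpha > 0):
            raise ValueError(
                f"psa_max, r, alpha must all be > 0; got "
                f"({self.psa_max}, {self.r}, {self.alpha})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.psa_max, self.r, self.alpha], dtype=float)


@dataclass
class PlantTrajectory:
    """One plant's daily time series with its design labels.

    ``fc`` holds the fraction of field capacity used for WSI (for
    watered plants this is by default the pre-watering value; the
    post-watering series, when recorded, is in ``fc_post``).  ``wu`` is
    daily water use in grams; day 1 is undefined and stored as NaN.
    """

    accession: str
    experiment: str
    treatment: str
    psa: np.ndarray
    fc: np.ndarray
    wu: Optional[np.ndarray] = None
    pot_capacity: float = 1000.0
    fc_post: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.psa = np.asarray(self.psa, dtype=float)
        self.fc = np.asarray(self.fc, dtype=float)
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.psa.shape != self.fc.shape:
            raise ValueError("psa and fc must have equal length")
        if np.nanmin(self.psa) < 0:
            raise ValueError("psa must be nonnegative")
        if self.wu is not None:
            self.wu = np.asarray(self.wu, dtype=float)
            if self.wu.shape != self.psa.shape:
                raise ValueError("wu length must match psa")

    @property
    def n_days(self) -> int:
        return self.psa.shape[0]


@dataclass(frozen=True)
class TOIRecord:
    """Time of inflection for one accession x experiment x treatment."""

    accession: str
    experiment: str
    treatment: str
    toi_day: Optional[int]

    @property
    def censored(self) -> bool:
        return self.toi_day is None


def standardize_time(n_days: int) -> np.ndarray:
    """Map imaging days 1..D onto standardized time values in [0, 1].

    Day ``d`` maps to ``(d - 1) / (D - 1)`` so the endpoints are exactly
    0 and 1 with uniform daily spacing.
    """
    if n_days < 2:
        raise ValueError(f"need at least 2 days, got {n_days}")
    return np.linspace(0.0, 1.0, n_days)


def compute_wsi(fc: Sequence[float], params: WSIParams = WSIParams()) -> np.ndarray:
    """Water stress index from fractions of field capacity.

    ``(fc - fc_crit) / (fc_opt - fc_crit)``, clamped into [0, 1]: FC
    above the optimum maps to 1 (no stress) and FC below the critical
    point maps to 0 (full growth arrest).  Clamping keeps ``wsi**alpha``
    well defined for every positive ``alpha``.
    """
    fc = np.asarray(fc, dtype=float)
    if not np.all(np.isfinite(fc)) or np.any(fc < 0):
        raise ValueError("fc values must be finite and nonnegative")
    wsi = (fc - params.fc_crit) / (params.fc_opt - params.fc_crit)
    return np.clip(wsi, 0.0, 1.0)


def gompertz_classic(t: Sequence[float], params: GrowthParams) -> np.ndarray:
    """Classical Gompertz curve ``psa_max * exp(-exp(-r (t - t0)))``."""
    if params.t0 is None:
        raise ValueError("classical model requires t0")
    t = np.asarray(t, dtype=float)
    return params.psa_max * np.exp(-np.exp(-params.r * (t - params.t0)))


def wsi_gomp_predict(
    t: Sequence[float], wsi: Sequence[float], params: GrowthParams
) -> np.ndarray:
    """WSI-coupled Gompertz forward model.

    ``psa[d] = psa_max * exp(-exp(-r * (t[d] - wsi[d] ** alpha)))``.
    """
    t = np.asarray(t, dtype=float)
    wsi = np.asarray(wsi, dtype=float)
    if t.shape != wsi.shape:
        raise ValueError("t and wsi must have equal length")
    if np.any(wsi < 0) or np.any(wsi > 1):
        raise ValueError("wsi values must lie in [0, 1]")
    return params.psa_max * np.exp(-np.exp(-params.r * (t - wsi**params.alpha)))


def time_of_inflection(
    t: Sequence[float], wsi: Sequence[float], alpha: float
) -> Optional[int]:
    """First imaging day (1-based) with ``t - wsi**alpha`` strictly positive.

    Returns ``None`` (censored) when the difference never becomes
    positive — e.g. an unstressed plant with WSI pinned at 1 whose
    standardized time never exceeds ``1**alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    t = np.asarray(t, dtype=float)
    wsi = np.asarray(wsi, dtype=float)
    pos = np.nonzero(t - wsi**alpha > 0)[0]
    if pos.size == 0:
        return None
    return int(pos[0]) + 1


def compute_water_use(
    fc: Sequence[float],
    pot_capacity: float,
    fc_post: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Daily water use (g) from the day-over-day drop in pot water content.

    ``wu[d] = (fc[d-1] - fc[d]) * pot_capacity`` for unwatered pots.
    For watered pots the previous day's water content is taken after
    watering (``fc_post``) and the current day's before watering
    (``fc``), so the rewatering event itself is not counted as use.
    Day 1 has no previous day and is NaN.  Negative values (measurement
    noise) are kept as-is for the caller to flag.
    """
    fc = np.asarray(fc, dtype=float)
    prev = fc if fc_post is None else np.asarray(fc_post, dtype=float)
    if prev.shape != fc.shape:
        raise ValueError("fc_post must match fc in length")
    wu = np.empty_like(fc)
    wu[0] = np.nan
    wu[1:] = (prev[:-1] - fc[1:]) * pot_capacity
    return wu
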