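"""Per-trajectory least-squares fits of the water-stress Gompertz model.

Derivative-free (Nelder-Mead) minimization of the sum of squared
residuals between observed PSA and the forward model, optimized over
``(log psa_max, log r, log alpha)`` so positivity is enforced without
constraints.  Used for mean-trajectory fits and as initializer / oracle
for the genome-enabled fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .growth_core import GrowthParams, PlantTrajectory, compute_wsi, standardize_time, wsi_gomp_predict

__all__ = ["FitResult", "default_init", "fit_trajectory_nm", "fit_mean_trajectories"]


@dataclass
class FitResult:
    params: GrowthParams
    sse: float
    converged: bool
    n_evals: int


def default_init(psa: Sequence[float]) -> GrowthParams:
    """Rule-of-thumb starting point: asymptote 20% above the observed
    maximum, mid-range growth rate r=4 on the unit time scale, alpha=1."""
    psa = np.asarray(psa, dtype=float)
    top = np.nanmax(psa)
    if not (top > 0):
        raise ValueError("need at least one positive psa value")
    return GrowthParams(psa_max=1.2 * top, r=4.0, alpha=1.0)


def _objective(x, t, wsi, psa, log_loss):
    p = GrowthParams(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]))
    pred = wsi_gomp_predict(t, wsi, p)
    if log_loss:
        resid = np.log(pred + 1e-9) - np.log(psa + 1e-9)
    else:
        resid = pred - psa
    return float(resid @ resid)


def fit_trajectory_nm(
    psa: Sequence[float],
    wsi: Sequence[float],
    t: Optional[Sequence[float]] = None,
    init: Optional[GrowthParams] = None,
    log_loss: bool = False,
    tol: float = 1e-8,
    maxfev: int = 5000,
) -> FitResult:
    """Nelder-Mead fit of one trajectory.

    Missing days (NaN PSA) are dropped; at least 4 observed days are
    required (3 parameters + 1).  The returned objective never exceeds
    the objective at the init (best-seen point is reported).
    """
    psa = np.asarray(psa, dtype=float)
    wsi = np.asarray(wsi, dtype=float)
    if t is None:
        t = standardize_time(len(psa))
    t = np.asarray(t, dtype=float)
    keep = np.isfinite(psa)
    if keep.sum() < 4:
        raise ValueError("need at least 4 non-missing days to fit 3 parameters")
    psa_f, wsi_f, t_f = psa[keep], wsi[keep], t[keep]
    if np.nanmax(psa_f) <= 0:
        raise ValueError("trajectory is constant zero; unfittable")
    if init is None:
        init = default_init(psa_f)
    x0 = np.log(init.as_array())
    res = minimize(
        _objective,
        x0,
        args=(t_f, wsi_f, psa_f, log_loss),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxfev": maxfev},
    )
    f0 = _objective(x0, t_f, wsi_f, psa_f, log_loss)
    if res.fun <= f0:
        x, fun = res.x, float(res.fun)
    else:  # NM should never worsen, but guarantee monotone improvement
        x, fun = x0, f0
    params = GrowthParams(*np.exp(x))
    if not log_loss:
        sse = fun
    else:
        sse = float(np.sum((wsi_gomp_predict(t_f, wsi_f, params) - psa_f) ** 2))
    return FitResult(params=params, sse=sse, converged=bool(res.success), n_evals=int(res.nfev))


def fit_mean_trajectories(
    trajectories: List[PlantTrajectory],
    log_loss: bool = False,
) -> pd.DataFrame:
    """Fit the model to mean trajectories per experiment x treatment.

    PSA and FC are averaged across plants within each group, WSI is
    computed from the mean FC, and one Nelder-Mead fit is run per
    group.
    """
    rows = []
    groups: dict = {}
    for tr in trajectories:
        groups.setdefault((tr.experiment, tr.treatment), []).append(tr)
    for (experiment, treatment), trs in sorted(groups.items()):
        psa = np.nanmean([tr.psa for tr in trs], axis=0)
        fc = np.nanmean([tr.fc for tr in trs], axis=0)
        wsi = compute_wsi(fc)
        fit = fit_trajectory_nm(psa, wsi, log_loss=log_loss)
        rows.append(
            {
                "experiment": experiment,
                "treatment": treatment,
                "n_plants": len(trs),
                "psa_max": fit.params.psa_max,
                "r": fit.params.r,
                "alpha": fit.params.alpha,
                "sse": fit.sse,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
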