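"""Ordinal GWAS on time of inflection (TOI).

TOI — the first imaging day on which standardized time exceeds
``WSI**alpha`` — is a small integer, so marker associations are
estimated with a Bayesian LASSO probit model on the latent growth
liability:

    y_j ordinal,   l_j = x_j' b + z_j' a + e_j,   e_j ~ N(0, 1)
    y_j = c  iff  gamma_{c-1} < l_j <= gamma_c

with fixed experiment effects ``b`` under a diffuse Gaussian prior
(variance 1e10), marker effects ``a`` under a double-exponential prior
implemented as a scale mixture of normals with exponential mixing and
``lambda^2 ~ Gamma(s, r)`` (shape s = 1.1; rate r solved from a prior
R^2).  Identification: liability variance fixed at 1 and the first
threshold fixed at 0.  Sampling is Gibbs with latent-liability data
augmentation (truncated-normal draws) and uniform threshold updates.

Effects are reported ranked by |posterior mean|; no p-values are
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._samplers import beta_sweep, sample_wald
from .growth_core import PlantTrajectory, compute_wsi, standardize_time, time_of_inflection
from .synthetic_data import MarkerMatrix

__all__ = [
    "BLProbitConfig",
    "BLProbitResult",
    "derive_toi_table",
    "fit_ordinal_bl",
    "run_toi_gwas",
    "rank_top_markers",
]


def derive_toi_table(
    alpha_table: pd.DataFrame,
    trajectories: List[PlantTrajectory],
) -> pd.DataFrame:
    """One TOI per accession x experiment x treatment.

    ``alpha_table`` holds posterior-mean alpha per accession and
    treatment (columns: accession, treatment, alpha).  The observed WSI
    series of each accession in each experiment (FC averaged across
    replicate plants, then transformed) is scanned for the first day
    with ``t - WSI**alpha > 0``.  Censored records (never positive) are
    kept with ``toi_day`` = NaN and ``censored`` = True.
    """
    alpha_lookup = {
        (row.accession, row.treatment): row.alpha
        for row in alpha_table.itertuples(index=False)
    }
    groups: Dict[Tuple[str, str, str], list] = {}
    for tr in trajectories:
        groups.setdefault((tr.accession, tr.experiment, tr.treatment), []).append(tr.fc)
    rows = []
    for (acc, exp, treat), fcs in sorted(groups.items()):
        if (acc, treat) not in alpha_lookup:
            continue
        alpha = alpha_lookup[(acc, treat)]
        fc_mean = np.nanmean(fcs, axis=0)
        wsi = compute_wsi(fc_mean)
        t = standardize_time(len(wsi))
        toi = time_of_inflection(t, wsi, alpha)
        rows.append(
            {
                "accession": acc,
                "experiment": exp,
                "treatment": treat,
                "toi_day": np.nan if toi is None else toi,
                "censored": toi is None,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BLProbitConfig:
    """Chain and prior settings for the ordinal Bayesian LASSO."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    s: float = 1.1  # shape of the gamma prior on lambda^2
    prior_r2: float = 0.5  # prior R^2 used to solve for the rate
    fixed_effect_var: float = 1e10


@dataclass
class BLProbitResult:
    """Posterior summaries of the ordinal Bayesian LASSO fit."""

    a_mean: np.ndarray  # posterior mean marker effects
    b_mean: np.ndarray  # posterior mean fixed effects
    thresholds_mean: np.ndarray  # interior thresholds (first fixed at 0)
    categories: np.ndarray  # ordered original category labels
    lambda2_draws: np.ndarray
    acceptance_note: str = ""
    draws: Dict[str, np.ndarray] = field(default_factory=dict)


def _lambda2_rate(s: float, prior_r2: float, Z: np.ndarray) -> float:
    """Rate of the gamma prior on lambda^2 from a prior R^2.

    The prior mode of lambda^2 is matched to 2 (1 - R2) / R2 * MSx,
    where MSx is the sum of marker-column variances — larger prior R^2
    means weaker shrinkage.  mode = (s - 1)/rate for a Gamma(s, rate).
    """
    msx = float(np.sum(np.var(Z, axis=0)))
    if msx <= 0:
        msx = 1.0
    lam2 = 2.0 * (1.0 - prior_r2) / prior_r2 * msx
    return (s - 1.0) / lam2


def _truncnorm_draws(rng, mean, lo, hi):
    """Vectorized truncated-normal draws via the inverse CDF."""
    a = ndtr(lo - mean)
    b = ndtr(hi - mean)
    u = a + (b - a) * rng.random(mean.shape)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return mean + ndtri(u)


def fit_ordinal_bl(
    y: Sequence,
    X: np.ndarray,
    Z: np.ndarray,
    config: BLProbitConfig = BLProbitConfig(),
    seed=0,
) -> BLProbitResult:
    """Gibbs sampler for the ordinal probit Bayesian LASSO.

    ``y`` is the ordinal response (any orderable labels), ``X`` the
    fixed-effect design (n_obs x q, e.g. experiment indicators with
    intercept), ``Z`` the per-observation marker matrix (n_obs x m).
    Requires at least two observed categories.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=float)
    n_obs = len(y)
    if X.shape[0] != n_obs or Z.shape[0] != n_obs:
        raise ValueError("X and Z must have one row per observation")
    cats, y_idx = np.unique(y, return_inverse=True)
    C = len(cats)
    if C < 2:
        raise ValueError("degenerate response: need at least 2 ordinal categories")
    m_all = Z.shape[1]
    poly = Z.std(axis=0) > 0
    Z = Z[:, poly]
    m = Z.shape[1]
    q = X.shape[1]
    Zt = np.ascontiguousarray(Z.T)

    # thresholds gamma[0]=-inf, gamma[1]=0 (fixed), ..., gamma[C]=+inf
    gamma = np.empty(C + 1)
    gamma[0] = -np.inf
    gamma[1] = 0.0
    gamma[2:C] = np.arange(1, C - 1, dtype=float)
    gamma[C] = np.inf

    a = np.zeros(m)
    b = np.zeros(q)
    lam2 = 1.0
    rate = _lambda2_rate(config.s, config.prior_r2, Z)
    prior_prec_a = np.ones(m)
    XtX = X.T @ X
    fe_prec = XtX + np.eye(q) / config.fixed_effect_var

    # start liabilities at category midpoints
    mids = 0.5 * (np.where(np.isfinite(gamma[:-1]), gamma[:-1], gamma[1:] - 1.0)
                  + np.where(np.isfinite(gamma[1:]), gamma[1:], gamma[:-1] + 1.0))
    liab = mids[y_idx]

    keep_a = np.zeros(m)
    keep_b = np.zeros(q)
    keep_g = np.zeros(C - 1)
    lam2_draws = []
    n_kept = 0
    chol = np.linalg.cholesky(np.linalg.inv(fe_prec))
    for it in range(config.n_iter):
        mean = X @ b + Z @ a
        liab = _truncnorm_draws(rng, mean, gamma[y_idx], gamma[y_idx + 1])

        # interior thresholds other than the fixed gamma[1]=0
        for c in range(2, C):
            lo = liab[y_idx == c - 1].max()
            hi = liab[y_idx == c].min()
            gamma[c] = rng.uniform(max(lo, gamma[c - 1]), hi)

        # fixed effects: diffuse Gaussian prior
        resid_fe = liab - Z @ a
        b_mean = np.linalg.solve(fe_prec, X.T @ resid_fe)
        b = b_mean + chol @ rng.standard_normal(q)

        # marker effects: coordinate Gibbs with Laplace scale mixture
        resid = liab - X @ b - Z @ a
        beta_sweep(Zt, resid, a, prior_prec_a, 1.0, rng.standard_normal(m))

        a2 = np.maximum(a**2, 1e-20)
        prior_prec_a = np.maximum(sample_wald(rng, np.sqrt(lam2 / a2), lam2), 1e-12)
        u = 1.0 / prior_prec_a
        lam2 = rng.gamma(config.s + m, 1.0 / (rate + u.sum() / 2.0))

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep_a += a
            keep_b += b
            keep_g += gamma[1:C]
            lam2_draws.append(lam2)
            n_kept += 1

    S = max(n_kept, 1)
    a_full = np.zeros(m_all)
    a_full[poly] = keep_a / S
    return BLProbitResult(
        a_mean=a_full,
        b_mean=keep_b / S,
        thresholds_mean=keep_g / S,
        categories=cats,
        lambda2_draws=np.asarray(lam2_draws),
    )


def run_toi_gwas(
    toi_table: pd.DataFrame,
    markers: MarkerMatrix,
    treatment: str,
    config: BLProbitConfig = BLProbitConfig(),
    seed=0,
) -> Tuple[BLProbitResult, pd.DataFrame]:
    """Per-treatment TOI GWAS: build design matrices and fit.

    Censored TOI records are dropped (count logged via a warning);
    experiments enter as fixed effects (intercept + indicator
    contrasts).  Returns the sampler result plus an effects table
    (marker, chrom, pos, effect, abs_effect) ready for ranking or a
    Manhattan plot.
    """
    sub = toi_table[toi_table["treatment"] == treatment]
    n_censored = int(sub["censored"].sum())
    if n_censored:
        warnings.warn(f"{n_censored} censored TOI records dropped from GWAS")
    sub = sub[~sub["censored"]]
    marker_rows = {acc: i for i, acc in enumerate(markers.accession_ids)}
    sub = sub[sub["accession"].isin(marker_rows)]
    if sub.empty:
        raise ValueError("no uncensored TOI records with genotypes")
    y = sub["toi_day"].to_numpy()
    exps = sorted(sub["experiment"].unique())
    X = np.ones((len(sub), 1))
    if len(exps) > 1:
        dummies = np.stack(
            [(sub["experiment"] == e).to_numpy(float) for e in exps[1:]], axis=1
        )
        X = np.hstack([X, dummies])
    Z = markers.genotypes[[marker_rows[a] for a in sub["accession"]]].astype(float)
    result = fit_ordinal_bl(y, X, Z, config=config, seed=seed)
    effects = markers.marker_map().assign(
        effect=result.a_mean, abs_effect=np.abs(result.a_mean)
    )
    return result, effects


def rank_top_markers(effects: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k markers by |effect|, ties broken by (chrom, pos) ascending."""
    if not np.all(np.isfinite(effects["effect"])):
        raise ValueError("effects must be finite")
    if k > len(effects):
        warnings.warn(f"k={k} exceeds {len(effects)} markers; truncating")
        k = len(effects)
    ranked = effects.assign(abs_effect=effects["effect"].abs()).sort_values(
        ["abs_effect", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)
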