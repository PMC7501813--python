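"""Genome-enabled estimation of growth-model parameters.

The "integrated" hierarchical model: each accession's three growth
parameters (psa_max, r, alpha) generate its observed PSA trajectory
through the water-stress Gompertz forward model with Gaussian
observation noise, while at the second level each parameter vector is
regressed on genome-wide markers under an extended Bayesian LASSO
(EBL) prior,

    psa[plant, d] ~ N( f(t_d, WSI[plant, d]; theta_acc), 1 / tau0 )
    p_i           ~ N( mu_p + W_i beta_p, 1 / tau0p )          for each p
    beta_pi       ~ N( 0, 1 / (tau0p * tau_i^2) )
    tau_i^2       ~ InvGamma(1, delta^2 eta_i^2 / 2)
    eta_i^2       ~ Gamma(psi, theta),   delta^2 ~ Gamma(phi, omega)

(all Gamma distributions shape/rate).  Marginally the marker effects
are double-exponential with per-marker (eta_i^2) and global (delta^2)
shrinkage.  Inference is pure MCMC: conjugate Gibbs updates for the
whole regression hierarchy and a Metropolis-within-Gibbs random walk on
(log psa_max, log r, log alpha) per accession, with proposal scales
adapted during burn-in.  Treatments are fit separately, and accessions
with missing trajectory values are excluded up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._samplers import beta_sweep, effective_size, sample_wald, split_rhat
from .fitting import default_init, fit_trajectory_nm
from .growth_core import GrowthParams, PlantTrajectory, compute_wsi, standardize_time
from .synthetic_data import MarkerMatrix, PARAM_NAMES

__all__ = [
    "EBLHyper",
    "EBLState",
    "GenomeFitConfig",
    "PosteriorSummary",
    "ebl_gibbs_step",
    "ebl_linear_gibbs",
    "sample_growth_params",
    "fit_genome_enabled",
]

_PREC_FLOOR = 1e-12


@dataclass(frozen=True)
class EBLHyper:
    """Hyperparameters of the EBL shrinkage hierarchy (shape/rate).

    phi/omega govern the global shrinkage delta^2, psi/theta the
    per-marker shrinkage eta_i^2.  Defaults 0.1 everywhere: weakly
    informative, letting the data set the overall shrinkage level.
    a0/b0 are the (near-flat) Gamma priors on the residual precisions.
    """

    phi: float = 0.1
    omega: float = 0.1
    psi: float = 0.1
    theta: float = 0.1
    a0: float = 1e-3
    b0: float = 1e-3


@dataclass
class EBLState:
    """Mutable state of one parameter's marker regression.

    ``a0p``/``b0p`` are the shape/rate of the Gamma prior on the
    parameter-level residual precision ``tau0p``.  Because the response
    of this regression is itself latent, a near-flat prior lets the
    hierarchy collapse (the marker term can interpolate the response,
    driving the residual variance to zero); callers fitting latent
    responses should anchor it with a few pseudo-observations of a
    non-trivial residual variance (see :func:`fit_genome_enabled`).
    """

    mu: float
    beta: np.ndarray  # (m,)
    tau2: np.ndarray  # per-marker precision multipliers (m,)
    eta2: np.ndarray  # per-marker shrinkage (m,)
    delta2: float  # global shrinkage
    tau0p: float  # parameter-level residual precision
    a0p: float = 1e-3
    b0p: float = 1e-3

    @classmethod
    def initial(cls, m: int, mu: float = 0.0, tau0p: float = 1.0,
                a0p: float = 1e-3, b0p: float = 1e-3) -> "EBLState":
        # start from the strong-shrinkage (null) state: with a weak
        # start the marker term can absorb the whole response on the
        # first sweeps and the chain settles in an interpolating mode
        return cls(
            mu=mu,
            beta=np.zeros(m),
            tau2=np.full(m, float(max(m, 1))),
            eta2=np.ones(m),
            delta2=float(max(m, 1)),
            tau0p=tau0p,
            a0p=a0p,
            b0p=b0p,
        )


def ebl_gibbs_step(
    state: EBLState,
    p_vec: np.ndarray,
    Wt: np.ndarray,
    rng: np.random.Generator,
    hyper: EBLHyper = EBLHyper(),
    update_shrinkage: bool = True,
    update_mu: bool = True,
    update_tau0p: bool = True,
) -> EBLState:
    """One full sweep of conjugate updates for the marker regression.

    ``p_vec`` is the current parameter value per accession (length n),
    ``Wt`` the transposed marker matrix (m x n, C-contiguous floats).
    The optional flags freeze layers of the hierarchy, which is how the
    oracle-equivalence tests pin the marginal posterior down.  Updates
    are in place; the state is also returned for convenience.
    """
    m, n = Wt.shape
    resid = p_vec - state.mu - state.beta @ Wt
    prior_prec = np.maximum(state.tau0p * state.tau2, _PREC_FLOOR)
    beta_sweep(Wt, resid, state.beta, prior_prec, state.tau0p, rng.standard_normal(m))

    if update_shrinkage:
        b2 = np.maximum(state.beta**2, 1e-20)
        de = np.maximum(state.delta2 * state.eta2, _PREC_FLOOR)
        state.tau2 = sample_wald(rng, np.sqrt(de / (state.tau0p * b2)), de)
        state.tau2 = np.maximum(state.tau2, _PREC_FLOOR)
        u = 1.0 / state.tau2  # exponential mixing variable of the Laplace prior
        state.eta2 = rng.gamma(hyper.psi + 1.0, 1.0 / (hyper.theta + state.delta2 * u / 2.0))
        state.eta2 = np.maximum(state.eta2, _PREC_FLOOR)
        state.delta2 = max(
            rng.gamma(hyper.phi + m, 1.0 / (hyper.omega + np.sum(state.eta2 * u) / 2.0)),
            _PREC_FLOOR,
        )

    if update_mu:
        offset = p_vec - state.beta @ Wt
        state.mu = rng.normal(offset.mean(), 1.0 / np.sqrt(n * state.tau0p))

    if update_tau0p:
        resid = p_vec - state.mu - state.beta @ Wt
        shape = state.a0p + 0.5 * n + 0.5 * m
        rate = state.b0p + 0.5 * resid @ resid + 0.5 * np.sum(state.tau2 * state.beta**2)
        state.tau0p = max(rng.gamma(shape, 1.0 / rate), _PREC_FLOOR)
    return state


def ebl_linear_gibbs(
    y: np.ndarray,
    W: np.ndarray,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed=0,
    hyper: EBLHyper = EBLHyper(),
    fix_delta2: Optional[float] = None,
    fix_eta2: Optional[float] = None,
    update_tau0p: bool = True,
    tau0p: float = 1.0,
) -> Dict[str, np.ndarray]:
    """EBL Gibbs sampler for a plain linear model y = mu + W beta + e.

    Convenience wrapper around :func:`ebl_gibbs_step` for testing the
    regression hierarchy in isolation (and for users with precomputed
    parameter values).  ``fix_delta2`` / ``fix_eta2`` freeze the
    shrinkage layer at the given values.  Returns draws of beta and mu.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    Wt = np.ascontiguousarray(np.asarray(W, dtype=float).T)
    m = Wt.shape[0]
    state = EBLState.initial(m, mu=float(y.mean()), tau0p=tau0p)
    fixed_shrink = fix_delta2 is not None or fix_eta2 is not None
    if fix_delta2 is not None:
        state.delta2 = float(fix_delta2)
    if fix_eta2 is not None:
        state.eta2 = np.full(m, float(fix_eta2))
    beta_draws, mu_draws, tau0p_draws = [], [], []
    for it in range(n_iter):
        if fixed_shrink:
            # only the Laplace mixing variables tau2 move, not delta2/eta2
            b2 = np.maximum(state.beta**2, 1e-20)
            de = np.maximum(state.delta2 * state.eta2, _PREC_FLOOR)
            state.tau2 = np.maximum(
                sample_wald(rng, np.sqrt(de / (state.tau0p * b2)), de), _PREC_FLOOR
            )
            ebl_gibbs_step(
                state, y, Wt, rng, hyper, update_shrinkage=False, update_tau0p=update_tau0p
            )
        else:
            ebl_gibbs_step(state, y, Wt, rng, hyper, update_tau0p=update_tau0p)
        if it >= burn_in:
            beta_draws.append(state.beta.copy())
            mu_draws.append(state.mu)
            tau0p_draws.append(state.tau0p)
    return {
        "beta": np.array(beta_draws),
        "mu": np.array(mu_draws),
        "tau0p": np.array(tau0p_draws),
    }


def _forward(t: np.ndarray, wsi_pow: np.ndarray, params: np.ndarray, acc_idx: np.ndarray):
    """Vectorized forward model; params (n,3) natural scale.

    ``wsi_pow`` is wsi**alpha per plant (P, D), already raised to the
    current alpha, so callers control when the power is recomputed.
    """
    psa_max = params[acc_idx, 0][:, None]
    r = params[acc_idx, 1][:, None]
    return psa_max * np.exp(-np.exp(-r * (t[None, :] - wsi_pow)))


def _sse_per_accession(
    psa: np.ndarray,
    t: np.ndarray,
    wsi: np.ndarray,
    params: np.ndarray,
    acc_idx: np.ndarray,
    n_acc: int,
) -> np.ndarray:
    wsi_pow = wsi ** params[acc_idx, 2][:, None]
    resid = psa - _forward(t, wsi_pow, params, acc_idx)
    return np.bincount(acc_idx, weights=(resid**2).sum(axis=1), minlength=n_acc)


def sample_growth_params(
    psa: np.ndarray,
    wsi: np.ndarray,
    t: np.ndarray,
    current: GrowthParams,
    tau0: float,
    prior_mean: Sequence[float],
    prior_prec: Sequence[float],
    step: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[GrowthParams, bool]:
    """One Metropolis update of a single trajectory's parameters.

    Random walk on (log psa_max, log r, log alpha); target is the
    Gaussian trajectory likelihood times independent natural-scale
    Gaussian priors N(prior_mean_p, 1/prior_prec_p) (the marker-informed
    parameter model), with the log-scale Jacobian included.  Returns
    (new params, accepted).
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.log(current.as_array())
    prop = x + step * rng.standard_normal(3)
    pm = np.asarray(prior_mean, dtype=float)
    pp = np.asarray(prior_prec, dtype=float)

    def logpost(xv):
        theta = np.exp(xv)
        pred = theta[0] * np.exp(-np.exp(-theta[1] * (t - wsi ** theta[2])))
        ll = -0.5 * tau0 * np.sum((psa - pred) ** 2)
        lp = -0.5 * np.sum(pp * (theta - pm) ** 2)
        return ll + lp + xv.sum()  # + log-Jacobian of the log transform

    if np.log(rng.random()) < logpost(prop) - logpost(x):
        theta = np.exp(prop)
        return GrowthParams(*theta), True
    return current, False


@dataclass(frozen=True)
class GenomeFitConfig:
    """Chain settings for the integrated fit.

    Defaults (10k iterations, half burn-in, thin 5) are sized for a
    desk-scale panel of a few hundred accessions and markers; the
    shrinkage hyperparameters live in ``hyper``.
    """

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    hyper: EBLHyper = EBLHyper()
    n_mh_steps: int = 2
    target_accept: float = 0.3
    init_step: float = 0.05
    rhat_limit: float = 1.1
    # Anchor prior on each parameter-level residual precision: worth
    # ``anchor_weight * n`` pseudo-observations with residual variance
    # ``anchor_var`` (on the standardized parameter scale).  Prevents
    # the latent marker regression from interpolating its response and
    # collapsing the residual variance to zero.
    anchor_weight: float = 0.1
    anchor_var: float = 0.5


@dataclass
class PosteriorSummary:
    """Posterior summaries of the genome-enabled fit."""

    accession_params: pd.DataFrame  # mean/sd of psa_max, r, alpha per accession
    marker_effects: pd.DataFrame  # posterior mean beta per marker x parameter
    diagnostics: pd.DataFrame  # split-Rhat / ESS for key scalars
    acceptance_rate: float
    n_dropped: int
    converged: bool
    draws: Dict[str, np.ndarray] = field(default_factory=dict)


def _prepare(
    trajectories: List[PlantTrajectory],
    markers: MarkerMatrix,
    treatment: Optional[str],
):
    trs = [tr for tr in trajectories if treatment is None or tr.treatment == treatment]
    if not trs:
        raise ValueError("no trajectories for the requested treatment")
    treatments = {tr.treatment for tr in trs}
    if len(treatments) > 1:
        raise ValueError("fit one treatment at a time (pass treatment=...)")
    marker_rows = {a: i for i, a in enumerate(markers.accession_ids)}
    # paper-style QC: accessions with any missing value are excluded
    bad_acc = {tr.accession for tr in trs if not np.all(np.isfinite(tr.psa))}
    no_geno = {tr.accession for tr in trs if tr.accession not in marker_rows}
    drop = bad_acc | no_geno
    kept = [tr for tr in trs if tr.accession not in drop]
    if not kept:
        raise ValueError("no accessions left after missing-data exclusion")
    accs = sorted({tr.accession for tr in kept})
    acc_pos = {a: i for i, a in enumerate(accs)}
    psa = np.array([tr.psa for tr in kept])
    wsi = np.array([compute_wsi(tr.fc) for tr in kept])
    acc_idx = np.array([acc_pos[tr.accession] for tr in kept])
    W = markers.genotypes[[marker_rows[a] for a in accs]].astype(float)
    return kept, accs, psa, wsi, acc_idx, W, len(drop)


def fit_genome_enabled(
    trajectories: List[PlantTrajectory],
    markers: MarkerMatrix,
    config: GenomeFitConfig = GenomeFitConfig(),
    seed=0,
    treatment: Optional[str] = None,
    verbose: bool = False,
) -> PosteriorSummary:
    """Run the integrated MCMC for one treatment.

    Plants of the same accession share one parameter triple.  Chains
    are initialized at per-accession Nelder-Mead fits.  Returns
    posterior means/SDs per accession, posterior mean marker effects
    per parameter (the Manhattan-plot input), and basic chain
    diagnostics (split-R-hat and effective size of the three intercepts
    and the observation precision).
    """
    rng = np.random.default_rng(seed)
    kept, accs, psa, wsi, acc_idx, W, n_dropped = _prepare(trajectories, markers, treatment)
    n = len(accs)
    P, D = psa.shape
    t = standardize_time(D)
    # Sample in a column-centered parameterization: with a flat prior on
    # the intercept, (mu, beta) and (mu + wbar beta, beta) have identical
    # posteriors, and centering decorrelates them so the chain mixes.
    # Marker effects are untouched; the reported intercept is un-centered.
    # monomorphic markers carry no information and only destabilize the
    # shrinkage hierarchy; exclude them and report a zero effect
    poly = W.std(axis=0) > 0
    m_all = W.shape[1]
    W = W[:, poly]
    wbar = W.mean(axis=0)
    Wc = W - wbar
    Wt = np.ascontiguousarray(Wc.T)
    m = Wt.shape[0]

    # --- initialize at per-accession NM fits on accession-mean data
    params = np.empty((n, 3))
    for i in range(n):
        sel = acc_idx == i
        psa_mean = psa[sel].mean(axis=0)
        wsi_mean = wsi[sel].mean(axis=0)
        try:
            fit = fit_trajectory_nm(psa_mean, wsi_mean, t)
            params[i] = fit.params.as_array()
        except ValueError:
            params[i] = default_init(psa_mean).as_array()

    # The shrinkage hyperpriors are not scale invariant, so the marker
    # regression runs on a standardized response: each parameter vector
    # is divided by a fixed scale (SD of its initial fits) and effects
    # are mapped back to the natural scale on output.
    p_scale = np.maximum(params.std(axis=0), 1e-8)
    n0 = config.anchor_weight * n
    states = {
        p: EBLState.initial(
            m,
            mu=float((params[:, j] / p_scale[j]).mean()),
            tau0p=1.0,
            a0p=0.5 * n0,
            b0p=0.5 * n0 * config.anchor_var,
        )
        for j, p in enumerate(PARAM_NAMES)
    }
    sse0 = _sse_per_accession(psa, t, wsi, params, acc_idx, n).sum()
    tau0 = (P * D) / max(sse0, 1e-9)
    log_step = np.full((n, 3), np.log(config.init_step))
    accept_count = 0
    mh_total = 0

    n_keep = (config.n_iter - config.burn_in) // config.thin
    params_sum = np.zeros((n, 3))
    params_sq = np.zeros((n, 3))
    beta_sum = {p: np.zeros(m) for p in PARAM_NAMES}
    scalar_draws = {f"mu_{p}": [] for p in PARAM_NAMES}
    for p in PARAM_NAMES:
        scalar_draws[f"tau0p_{p}"] = []
    scalar_draws["tau0"] = []
    param_draws = np.empty((n_keep, n, 3))
    kept_draws = 0

    hyper = config.hyper
    for it in range(config.n_iter):
        # --- marker-regression hierarchy per growth parameter (on the
        # standardized response)
        for j, p in enumerate(PARAM_NAMES):
            ebl_gibbs_step(states[p], params[:, j] / p_scale[j], Wt, rng, hyper)

        prior_mean = np.column_stack(
            [p_scale[j] * (states[p].mu + Wc @ states[p].beta)
             for j, p in enumerate(PARAM_NAMES)]
        )
        prior_prec = np.array(
            [states[p].tau0p / p_scale[j] ** 2 for j, p in enumerate(PARAM_NAMES)]
        )

        # --- Metropolis-within-Gibbs on (log psa_max, log r, log alpha),
        # component-wise so each coordinate gets its own adapted step
        x = np.log(params)
        sse = _sse_per_accession(psa, t, wsi, params, acc_idx, n)
        for _ in range(config.n_mh_steps):
            for j in range(3):
                prop_x = x.copy()
                prop_x[:, j] += np.exp(log_step[:, j]) * rng.standard_normal(n)
                prop = np.exp(prop_x)
                sse_prop = _sse_per_accession(psa, t, wsi, prop, acc_idx, n)
                dprior = -0.5 * prior_prec[j] * (
                    (prop[:, j] - prior_mean[:, j]) ** 2
                    - (params[:, j] - prior_mean[:, j]) ** 2
                )
                dlp = (
                    -0.5 * tau0 * (sse_prop - sse)
                    + dprior
                    + (prop_x[:, j] - x[:, j])
                )
                acc = np.log(rng.random(n)) < dlp
                x[acc, j] = prop_x[acc, j]
                params[acc, j] = prop[acc, j]
                sse[acc] = sse_prop[acc]
                accept_count += int(acc.sum())
                mh_total += n
                if it < config.burn_in:
                    gamma = 1.0 / (1.0 + it) ** 0.6
                    log_step[:, j] += gamma * (acc.astype(float) - config.target_accept)
            if it < config.burn_in:
                np.clip(log_step, np.log(1e-5), np.log(1.0), out=log_step)

        # --- observation precision
        tau0 = max(
            rng.gamma(hyper.a0 + 0.5 * P * D, 1.0 / (hyper.b0 + 0.5 * sse.sum())),
            _PREC_FLOOR,
        )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            params_sum += params
            params_sq += params**2
            for j, p in enumerate(PARAM_NAMES):
                beta_sum[p] += p_scale[j] * states[p].beta
                # un-centered intercept of the raw coding, natural scale
                scalar_draws[f"mu_{p}"].append(
                    p_scale[j] * (states[p].mu - wbar @ states[p].beta)
                )
                # natural-scale parameter-level residual precision
                scalar_draws[f"tau0p_{p}"].append(states[p].tau0p / p_scale[j] ** 2)
            scalar_draws["tau0"].append(tau0)
            if kept_draws < n_keep:
                param_draws[kept_draws] = params
                kept_draws += 1
        if verbose and (it + 1) % 500 == 0:
            print(f"iter {it + 1}/{config.n_iter}  accept={accept_count / max(mh_total, 1):.2f}")

    S = max(len(scalar_draws["tau0"]), 1)
    mean = params_sum / S
    sd = np.sqrt(np.maximum(params_sq / S - mean**2, 0.0))
    accession_params = pd.DataFrame({"accession": accs})
    for j, p in enumerate(PARAM_NAMES):
        accession_params[f"{p}_mean"] = mean[:, j]
        accession_params[f"{p}_sd"] = sd[:, j]

    mm = markers.marker_map()
    effect_frames = []
    for p in PARAM_NAMES:
        f = mm.copy()
        f["parameter"] = p
        full = np.zeros(m_all)
        full[poly] = beta_sum[p] / S
        f["beta_mean"] = full
        f["abs_beta"] = np.abs(f["beta_mean"])
        effect_frames.append(f)
    marker_effects = pd.concat(effect_frames, ignore_index=True)

    diag_rows = []
    for name, d in scalar_draws.items():
        d = np.asarray(d)
        diag_rows.append(
            {"quantity": name, "rhat": split_rhat(d), "ess": effective_size(d)}
        )
    diagnostics = pd.DataFrame(diag_rows)
    converged = bool((diagnostics["rhat"].dropna() < config.rhat_limit).all())
    if not converged:
        warnings.warn("split-R-hat above limit; chain may not have converged")

    return PosteriorSummary(
        accession_params=accession_params,
        marker_effects=marker_effects,
        diagnostics=diagnostics,
        acceptance_rate=accept_count / max(mh_total, 1),
        n_dropped=n_dropped,
        converged=converged,
        draws={
            "params": param_draws[:kept_draws],
            **{k: np.asarray(v) for k, v in scalar_draws.items()},
        },
    )
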