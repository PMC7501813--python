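"""Low-level Gibbs-sweep kernels and chain diagnostics.

The coordinate-wise marker-effect updates are the hot loop of both the
hierarchical growth-model sampler and the ordinal GWAS sampler; they
are compiled with numba when available (pure-python fallback otherwise,
identical numerics).  All randomness is injected from outside as arrays
of standard normals so chains are reproducible from a single Generator.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def beta_sweep(Wt, resid, beta, prior_prec, tau0, z):
    """One coordinate sweep of Gaussian marker-effect updates.

    Linear model resid = y - mu - W beta (current state).  For marker i
    the full conditional is
        beta_i | rest ~ N( tau0 * w_i'(resid + w_i beta_i) / prec,  1/prec ),
        prec = tau0 * w_i'w_i + prior_prec_i
    with tau0 the residual precision.  ``Wt`` is (m, n) C-contiguous;
    ``z`` holds m standard normals.  Updates ``beta`` and ``resid`` in
    place.
    """
    m, n = Wt.shape
    for i in range(m):
        dot = 0.0
        ss = 0.0
        for k in range(n):
            w = Wt[i, k]
            dot += w * (resid[k] + w * beta[i])
            ss += w * w
        prec = tau0 * ss + prior_prec[i]
        mean = tau0 * dot / prec
        new = mean + z[i] / np.sqrt(prec)
        diff = beta[i] - new
        for k in range(n):
            resid[k] += Wt[i, k] * diff
        beta[i] = new


def sample_wald(rng, mean, shape):
    """Inverse-Gaussian draws, elementwise, guarding degenerate means."""
    mean = np.clip(mean, 1e-10, 1e10)
    shape = np.maximum(shape, 1e-12)
    return rng.wald(mean, shape)


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of a single chain (split into two halves)."""
    x = np.asarray(draws, dtype=float)
    x = x[: 2 * (len(x) // 2)]
    half = len(x) // 2
    if half < 2:
        return np.nan
    chains = np.stack([x[:half], x[half:]])
    w = chains.var(axis=1, ddof=1).mean()
    b = half * chains.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def effective_size(draws: np.ndarray, max_lag: int = 200) -> float:
    """Initial-positive-sequence estimator of the effective sample size."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for lag in range(1, min(max_lag, n - 1)):
        if rho[lag] < 0:
            break
        s += rho[lag]
    return float(n / (1.0 + 2.0 * s))
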