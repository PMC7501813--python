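"""Synthetic genotypes, genetic architectures and phenotyping runs.

Emulates an automated-greenhouse drought experiment on a rice diversity
panel: a marker panel coded -1/0/1, sparse marker effects on the three
growth-model parameters, a paired-pot design over several independent
experiments, a daily pot water balance (control pots rewatered to 90%
field capacity, drought pots drying down to a maintained 20% floor),
and multiplicative observation noise on projected shoot area.  Every
stage is deterministic given a seed, and ground truth (causal markers,
true per-accession parameters, injected artifacts) is returned so
downstream estimators can be scored against it.

Defaults mirror the emulated study: 378 accessions of which 54 are
replicated twice (432 pairs per experiment), 3 experiments, 21 imaging
days.  Marker-panel shape is desk-scale (hundreds of markers, not tens
of thousands); loci are independent (no linkage disequilibrium).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .growth_core import (
    CONTROL,
    DROUGHT,
    GrowthParams,
    PlantTrajectory,
    WSIParams,
    compute_water_use,
    compute_wsi,
    standardize_time,
    wsi_gomp_predict,
)

__all__ = [
    "MarkerMatrix",
    "TrueArchitecture",
    "ParamArchitecture",
    "DesignSpec",
    "DemandModel",
    "PARAM_NAMES",
    "simulate_genotypes",
    "simulate_true_effects",
    "simulate_water_balance",
    "simulate_psa_trajectories",
    "make_design",
    "inject_artifacts",
    "simulate_experiment",
    "true_params_for_treatment",
    "trajectories_to_frame",
]

PARAM_NAMES = ("psa_max", "r", "alpha")

# Generation scale per parameter: marker effects act on log(r) and
# log(alpha) so generated values are always positive; psa_max is
# generated on the natural scale with rejection of non-positive draws.
PARAM_SCALES = {"psa_max": "natural", "r": "log", "alpha": "log"}

# Population means and total genotypic+residual SDs on the generation
# scale.  psa_max is in the same (kilopixel-like) units as simulated PSA.
DEFAULT_MEANS = {"psa_max": 200.0, "r": 8.0, "alpha": 1.5}
DEFAULT_TOTAL_SD = {"psa_max": 50.0, "r": 0.12, "alpha": 0.20}


@dataclass
class MarkerMatrix:
    """n x m biallelic marker panel coded -1/0/1 with a marker map."""

    genotypes: np.ndarray
    accession_ids: List[str]
    marker_ids: List[str]
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if not np.isin(self.genotypes, (-1, 0, 1)).all():
            raise ValueError("genotypes must be coded -1/0/1")
        n, m = self.genotypes.shape
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists must match genotype dimensions")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chrom": self.chromosome,
                "pos": self.position_bp,
            }
        )

    def subset_accessions(self, ids: Sequence[str]) -> "MarkerMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [index[a] for a in ids]
        return MarkerMatrix(
            self.genotypes[rows],
            list(ids),
            self.marker_ids,
            self.chromosome,
            self.position_bp,
        )


@dataclass
class ParamArchitecture:
    """Sparse genetic architecture for one growth parameter."""

    mu: float
    beta: np.ndarray
    resid_sd: float
    causal_idx: np.ndarray
    scale: str  # "natural" or "log"


@dataclass
class TrueArchitecture:
    """Ground-truth architectures for all three growth parameters."""

    params: Dict[str, ParamArchitecture]

    def effects_frame(self, markers: MarkerMatrix) -> pd.DataFrame:
        rows = []
        for name, arch in self.params.items():
            for i in np.nonzero(arch.beta)[0]:
                rows.append(
                    {
                        "parameter": name,
                        "marker_id": markers.marker_ids[i],
                        "beta": arch.beta[i],
                        "scale": arch.scale,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DesignSpec:
    """Paired-pot experimental design.

    Each experiment holds ``n_accessions + n_replicated`` pairs of pots
    (one control, one drought per pair); a fixed subset of accessions is
    replicated twice within every experiment.
    """

    n_accessions: int = 378
    n_replicated: int = 54
    n_experiments: int = 3
    n_days: int = 21
    pot_capacity: float = 1000.0
    fc_start: float = 0.90
    fc_floor: float = 0.20
    control_target_fc: float = 0.90

    def __post_init__(self) -> None:
        if self.n_replicated > self.n_accessions:
            raise ValueError("n_replicated cannot exceed n_accessions")

    @property
    def pairs_per_experiment(self) -> int:
        return self.n_accessions + self.n_replicated


@dataclass(frozen=True)
class DemandModel:
    """Daily pot water loss (g): baseline evaporation + transpiration.

    ``loss[d] = e0 + c * psa[d-1]`` — bigger plants dry their pots
    faster, the coupling that makes vigour and drought exposure
    interact.
    """

    e0: float = 30.0
    c: float = 0.30

    def loss(self, psa_prev: float) -> float:
        return self.e0 + self.c * psa_prev


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: Tuple[float, float] = (0.1, 0.5),
    seed=0,
    n_chrom: int = 12,
) -> MarkerMatrix:
    """Independent biallelic markers at Hardy-Weinberg proportions.

    Per-marker allele frequency is uniform in ``maf_range``; genotypes
    are the sum of two Bernoulli draws recoded to -1/0/1.  Positions are
    spread over ``n_chrom`` chromosomes (rice has 12).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_range {maf_range}")
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = _rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    geno = (rng.random((n, m, 2)) < maf[None, :, None]).sum(axis=2) - 1
    chrom = 1 + (np.arange(m) % n_chrom)
    order = np.argsort(chrom, kind="stable")
    chrom = chrom[order]
    pos = np.concatenate(
        [
            np.sort(rng.integers(1, 43_000_000, size=(chrom == c).sum()))
            for c in range(1, n_chrom + 1)
        ]
    )
    return MarkerMatrix(
        genotypes=geno[:, order].astype(np.int8),
        accession_ids=[f"acc{i:04d}" for i in range(n)],
        marker_ids=[f"snp{i:05d}" for i in range(m)],
        chromosome=chrom,
        position_bp=pos,
    )


def simulate_true_effects(
    markers: MarkerMatrix,
    n_qtl: Dict[str, int] | int = 5,
    heritability: Dict[str, float] | float = 0.5,
    means: Optional[Dict[str, float]] = None,
    total_sd: Optional[Dict[str, float]] = None,
    seed=0,
    max_rejections: int = 1000,
) -> Tuple[TrueArchitecture, pd.DataFrame]:
    """Sparse marker effects and true per-accession growth parameters.

    On each parameter's generation scale the genotypic value is
    ``mu + W @ beta + eps``; ``beta`` is rescaled so the marker term
    explains exactly the requested heritability of the total variance
    in this sample, and ``eps`` carries the remainder.  Parameters on
    the log scale are exponentiated; natural-scale ``psa_max`` draws
    that come out non-positive have their residual redrawn (bounded
    rejection).

    Returns the architecture plus a DataFrame of true GrowthParams per
    accession.
    """
    rng = _rng(seed)
    means = dict(DEFAULT_MEANS if means is None else means)
    total_sd = dict(DEFAULT_TOTAL_SD if total_sd is None else total_sd)
    if not isinstance(n_qtl, dict):
        n_qtl = {p: int(n_qtl) for p in PARAM_NAMES}
    if not isinstance(heritability, dict):
        heritability = {p: float(heritability) for p in PARAM_NAMES}

    W = markers.genotypes.astype(float)
    n, m = W.shape
    archs: Dict[str, ParamArchitecture] = {}
    values: Dict[str, np.ndarray] = {}
    for p in PARAM_NAMES:
        h2 = heritability[p]
        if not (0 < h2 <= 1):
            raise ValueError(f"heritability for {p} must be in (0, 1]")
        k = n_qtl[p]
        if k > m:
            raise ValueError(f"n_qtl for {p} exceeds marker count")
        scale = PARAM_SCALES[p]
        sd_tot = total_sd[p]
        mu = np.log(means[p]) if scale == "log" else means[p]
        beta = np.zeros(m)
        causal = np.array([], dtype=int)
        if k > 0:
            causal = rng.choice(m, size=k, replace=False)
            # magnitudes bounded away from zero so every simulated QTL is
            # individually detectable (the regime recovery checks assume)
            raw = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
            beta[causal] = raw
            g = W @ beta
            sg = g.std()
            if sg == 0:  # monomorphic draw; nudge to target via resample
                raise RuntimeError("degenerate genotypic variance; change seed")
            beta *= np.sqrt(h2) * sd_tot / sg
        g = W @ beta
        resid_sd = np.sqrt(max(1.0 - h2, 0.0)) * sd_tot
        eps = rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else np.zeros(n)
        val = mu + g + eps
        if scale == "log":
            val = np.exp(val)
        else:
            bad = np.nonzero(val <= 0)[0]
            tries = 0
            while bad.size and tries < max_rejections:
                if resid_sd == 0:
                    break
                val[bad] = mu + g[bad] + rng.normal(0.0, resid_sd, size=bad.size)
                bad = np.nonzero(val <= 0)[0]
                tries += 1
            if bad.size:
                raise RuntimeError(
                    f"could not achieve positive {p} after {max_rejections} "
                    "rejection rounds; lower total_sd or raise the mean"
                )
        archs[p] = ParamArchitecture(
            mu=mu, beta=beta, resid_sd=resid_sd, causal_idx=np.sort(causal), scale=scale
        )
        values[p] = val

    truth = pd.DataFrame(
        {"accession": markers.accession_ids, **{p: values[p] for p in PARAM_NAMES}}
    )
    return TrueArchitecture(params=archs), truth


def simulate_water_balance(
    treatment: str,
    params: GrowthParams,
    design: DesignSpec = DesignSpec(),
    demand: DemandModel = DemandModel(),
    wsi_params: WSIParams = WSIParams(),
) -> Dict[str, np.ndarray]:
    """Daily pot water balance coupled to noiseless plant growth.

    Drought pots start at ``fc_start`` and lose ``demand.loss(psa)``
    grams per day until the floor is reached, after which FC is
    maintained at the floor.  Control pots are rewatered daily to the
    target; both the pre-watering FC (used for WSI and water use) and
    the post-watering FC are returned.  Plant size feeds back into
    demand through the noiseless growth model evaluated on the running
    WSI, so vigorous genotypes dry their pots faster.

    Returns dict with ``fc`` (pre-watering), ``fc_post``, ``wsi``,
    ``psa`` (noiseless) and ``wu``.
    """
    if treatment not in (CONTROL, DROUGHT):
        raise ValueError(f"unknown treatment {treatment!r}")
    D = design.n_days
    t = standardize_time(D)
    fc_pre = np.empty(D)
    fc_post = np.empty(D)
    psa = np.empty(D)
    wsi = np.empty(D)
    fc = design.fc_start
    for d in range(D):
        fc_pre[d] = fc
        wsi[d] = compute_wsi([fc], wsi_params)[0]
        psa[d] = wsi_gomp_predict(t[d : d + 1], wsi[d : d + 1], params)[0]
        if treatment == CONTROL:
            fc_post[d] = design.control_target_fc
        else:
            fc_post[d] = fc
        loss = demand.loss(psa[d])
        if loss > design.pot_capacity:
            warnings.warn("daily demand exceeds pot capacity; clipping")
            loss = design.pot_capacity
        fc_next = fc_post[d] - loss / design.pot_capacity
        if treatment == DROUGHT:
            fc_next = max(fc_next, design.fc_floor)
        fc = max(fc_next, 0.0)
    wu = compute_water_use(fc_pre, design.pot_capacity, fc_post=fc_post)
    return {"fc": fc_pre, "fc_post": fc_post, "wsi": wsi, "psa": psa, "wu": wu}


def simulate_psa_trajectories(
    params: GrowthParams,
    wsi: np.ndarray,
    noise_cv: float = 0.05,
    seed=0,
    n_plants: int = 1,
) -> np.ndarray:
    """Noisy observed PSA: forward model times lognormal noise.

    ``psa[d] = model(d) * exp(eta_d)`` with ``eta_d ~ N(0, sigma^2)``
    and ``sigma = sqrt(log(1 + cv^2))`` so the sample coefficient of
    variation matches ``noise_cv``.  ``noise_cv=0`` returns the exact
    forward model.  Output shape ``(n_plants, D)``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    t = standardize_time(len(wsi))
    clean = wsi_gomp_predict(t, wsi, params)
    if noise_cv == 0:
        return np.tile(clean, (n_plants, 1))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    eta = rng.normal(0.0, sigma, size=(n_plants, len(wsi)))
    return clean[None, :] * np.exp(eta)


def make_design(design: DesignSpec = DesignSpec(), seed=0) -> pd.DataFrame:
    """Plant roster: one row per pot (plant).

    Each experiment contains ``n_accessions + n_replicated`` pairs; each
    pair is one accession with one control and one drought pot.  The
    replicated subset is chosen once and repeated in every experiment;
    pair order within an experiment is randomized.
    """
    rng = _rng(seed)
    accessions = [f"acc{i:04d}" for i in range(design.n_accessions)]
    replicated = list(
        rng.choice(accessions, size=design.n_replicated, replace=False)
    )
    rows = []
    for e in range(design.n_experiments):
        pair_accs = accessions + replicated
        order = rng.permutation(len(pair_accs))
        for pair_no, j in enumerate(order):
            for treatment in (CONTROL, DROUGHT):
                rows.append(
                    {
                        "accession": pair_accs[j],
                        "experiment": f"exp{e + 1}",
                        "pair": pair_no,
                        "treatment": treatment,
                    }
                )
    roster = pd.DataFrame(rows)
    roster["plant_id"] = [f"plant{i:05d}" for i in range(len(roster))]
    return roster


def true_params_for_treatment(
    truth: pd.DataFrame, treatment: str, drought_psa_max_scale: float = 0.6
) -> pd.DataFrame:
    """Treatment-level true parameters from the accession truth table.

    Drought represses the achievable asymptote: the true drought
    ``psa_max`` is the control value times ``drought_psa_max_scale``;
    ``r`` and ``alpha`` are shared between treatments.
    """
    out = truth.copy()
    if treatment == DROUGHT:
        out["psa_max"] = out["psa_max"] * drought_psa_max_scale
    return out


def simulate_experiment(
    markers: MarkerMatrix,
    truth: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
    demand: DemandModel = DemandModel(),
    wsi_params: WSIParams = WSIParams(),
    noise_cv: float = 0.05,
    seed=0,
    roster: Optional[pd.DataFrame] = None,
    treatments: Sequence[str] = (CONTROL, DROUGHT),
    drought_psa_max_scale: float = 0.6,
) -> List[PlantTrajectory]:
    """Full phenotyping run: roster + water balance + noisy PSA.

    ``truth`` is the per-accession true-parameter table from
    :func:`simulate_true_effects`.  The water balance is genotype-
    specific (demand feeds back on plant size), and the drought arm
    grows toward a repressed asymptote (``drought_psa_max_scale`` times
    the control ``psa_max``; see :func:`true_params_for_treatment`).
    Only accessions present in ``truth`` are simulated.
    """
    rng = _rng(seed)
    if roster is None:
        d2 = DesignSpec(
            n_accessions=len(truth),
            n_replicated=min(design.n_replicated, len(truth)),
            n_experiments=design.n_experiments,
            n_days=design.n_days,
            pot_capacity=design.pot_capacity,
            fc_start=design.fc_start,
            fc_floor=design.fc_floor,
            control_target_fc=design.control_target_fc,
        )
        roster = make_design(d2, seed=rng.integers(2**31))
        id_map = dict(zip([f"acc{i:04d}" for i in range(len(truth))], truth["accession"]))
        roster = roster.assign(accession=roster["accession"].map(id_map))
    param_lookup = {
        treat: true_params_for_treatment(truth, treat, drought_psa_max_scale).set_index(
            "accession"
        )
        for treat in treatments
    }
    # water balance depends only on (accession, treatment); cache it
    balance_cache: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    out: List[PlantTrajectory] = []
    for row in roster.itertuples(index=False):
        if row.treatment not in treatments:
            continue
        key = (row.accession, row.treatment)
        pr = param_lookup[row.treatment].loc[row.accession]
        gp = GrowthParams(pr["psa_max"], pr["r"], pr["alpha"])
        if key not in balance_cache:
            balance_cache[key] = simulate_water_balance(
                row.treatment, gp, design=design, demand=demand, wsi_params=wsi_params
            )
        bal = balance_cache[key]
        psa = simulate_psa_trajectories(
            gp, bal["wsi"], noise_cv=noise_cv, seed=rng.integers(2**31)
        )[0]
        out.append(
            PlantTrajectory(
                accession=row.accession,
                experiment=row.experiment,
                treatment=row.treatment,
                psa=psa,
                fc=bal["fc"],
                wu=bal["wu"],
                pot_capacity=design.pot_capacity,
                fc_post=bal["fc_post"] if row.treatment == CONTROL else None,
            )
        )
    return out


def inject_artifacts(
    trajectories: List[PlantTrajectory],
    outlier_rate: float = 0.02,
    missing_rate: float = 0.01,
    displacement: float = 5.0,
    seed=0,
) -> Tuple[List[PlantTrajectory], pd.DataFrame]:
    """Corrupt a copy of the trajectories and return truth labels.

    Outlier plants get one day's PSA displaced ``displacement`` IQRs
    beyond the upper quartile of that day's cross-plant distribution
    (so a 1.5x-IQR fence flags them); missing plants get one day's PSA
    set to NaN.  Labels: plant index, day, kind in {outlier, missing}.
    """
    for rate in (outlier_rate, missing_rate):
        if not (0 <= rate < 1):
            raise ValueError("rates must be in [0, 1)")
    rng = _rng(seed)
    n = len(trajectories)
    D = trajectories[0].n_days if n else 0
    psa_mat = np.array([tr.psa for tr in trajectories])
    out = []
    labels = []
    is_outlier = rng.random(n) < outlier_rate
    is_missing = rng.random(n) < missing_rate
    for i, tr in enumerate(trajectories):
        psa = tr.psa.copy()
        if is_outlier[i]:
            d = int(rng.integers(D))
            col = psa_mat[:, d]
            q1, q3 = np.percentile(col, [25, 75])
            iqr = q3 - q1
            psa[d] = q3 + displacement * max(iqr, 1e-9)
            labels.append({"plant": i, "day": d + 1, "kind": "outlier"})
        if is_missing[i]:
            d = int(rng.integers(D))
            psa[d] = np.nan
            labels.append({"plant": i, "day": d + 1, "kind": "missing"})
        out.append(
            PlantTrajectory(
                accession=tr.accession,
                experiment=tr.experiment,
                treatment=tr.treatment,
                psa=psa,
                fc=tr.fc,
                wu=tr.wu,
                pot_capacity=tr.pot_capacity,
                fc_post=tr.fc_post,
            )
        )
    return out, pd.DataFrame(labels, columns=["plant", "day", "kind"])


def trajectories_to_frame(trajectories: List[PlantTrajectory]) -> pd.DataFrame:
    """Long-format phenotype table: one row per plant x day."""
    frames = []
    for i, tr in enumerate(trajectories):
        D = tr.n_days
        frames.append(
            pd.DataFrame(
                {
                    "accession": tr.accession,
                    "experiment": tr.experiment,
                    "treatment": tr.treatment,
                    "plant": i,
                    "day": np.arange(1, D + 1),
                    "psa": tr.psa,
                    "fc": tr.fc,
                    "wu": tr.wu if tr.wu is not None else np.nan,
                    "pot_capacity": tr.pot_capacity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
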