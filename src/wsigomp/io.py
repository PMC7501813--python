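"""Table readers/writers, run configuration, and the end-to-end pipeline.

All interchange is plain CSV: a long-format phenotype table (one row
per plant x day), a genotype table (accessions x markers, coded
-1/0/1) with a 3-column marker map, and per-stage result tables.
Output files carry a header comment with the seed and a hash of the
configuration so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .growth_core import PlantTrajectory, TREATMENTS, compute_wsi, standardize_time
from .synthetic_data import (
    DemandModel,
    DesignSpec,
    MarkerMatrix,
    inject_artifacts,
    make_design,
    simulate_experiment,
    simulate_genotypes,
    simulate_true_effects,
    trajectories_to_frame,
)

logger = logging.getLogger("wsigomp")

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_phenotypes",
    "write_phenotypes",
    "read_markers",
    "write_markers",
    "run_pipeline",
]

PHENOTYPE_COLUMNS = [
    "accession",
    "experiment",
    "treatment",
    "plant",
    "day",
    "psa",
    "fc",
    "wu",
    "pot_capacity",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; one seed drives all stages."""

    seed: int = 0
    out_dir: str = "wsigomp_run"
    # design / generator
    n_accessions: int = 60
    n_replicated: int = 8
    n_experiments: int = 2
    n_days: int = 21
    n_markers: int = 150
    n_qtl: int = 5
    heritability: float = 0.5
    noise_cv: float = 0.05
    outlier_rate: float = 0.02
    missing_rate: float = 0.01
    # samplers
    gf_n_iter: int = 1500
    gf_burn_in: int = 500
    gf_thin: int = 2
    gwas_n_iter: int = 1500
    gwas_burn_in: int = 500
    gwas_thin: int = 2
    phi: float = 0.1
    omega: float = 0.1
    psi: float = 0.1
    theta: float = 0.1
    prior_r2: float = 0.5
    # optional external inputs (otherwise simulated)
    phenotype_path: Optional[str] = None
    marker_path: Optional[str] = None
    marker_map_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: Optional[RunConfig] = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# seed={config.seed} config_hash={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def read_phenotypes(path) -> List[PlantTrajectory]:
    """Read the long-format phenotype CSV into per-plant trajectories.

    Required columns: accession, experiment, treatment, day, psa, fc;
    optional: plant, wu, pot_capacity.  Duplicate (accession,
    experiment, treatment, plant, day) rows and unknown treatment
    levels are schema errors.  Missing values stay NaN.
    """
    df = pd.read_csv(path, comment="#")
    required = ["accession", "experiment", "treatment", "day", "psa", "fc"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if df.empty:
        return []
    bad_treat = set(df["treatment"].unique()) - set(TREATMENTS)
    if bad_treat:
        raise SchemaError(f"unknown treatment level(s): {sorted(bad_treat)}")
    if "plant" not in df.columns:
        df["plant"] = (
            df["accession"].astype(str)
            + "/"
            + df["experiment"].astype(str)
            + "/"
            + df["treatment"].astype(str)
        )
    keys = ["accession", "experiment", "treatment", "plant", "day"]
    dups = df.duplicated(subset=keys)
    if dups.any():
        first = df[dups].iloc[0]
        raise SchemaError(
            f"duplicate record for {tuple(first[k] for k in keys)}"
        )
    out = []
    for (acc, exp, treat, _plant), grp in df.groupby(
        ["accession", "experiment", "treatment", "plant"], sort=True
    ):
        grp = grp.sort_values("day")
        cap = float(grp["pot_capacity"].iloc[0]) if "pot_capacity" in grp else 1000.0
        wu = grp["wu"].to_numpy(float) if "wu" in grp else None
        out.append(
            PlantTrajectory(
                accession=str(acc),
                experiment=str(exp),
                treatment=str(treat),
                psa=grp["psa"].to_numpy(float),
                fc=grp["fc"].to_numpy(float),
                wu=wu,
                pot_capacity=cap,
            )
        )
    return out


def write_phenotypes(
    trajectories: List[PlantTrajectory], path, config: Optional[RunConfig] = None
) -> None:
    _write_csv(trajectories_to_frame(trajectories), Path(path), config)


def read_markers(genotype_path, map_path=None) -> MarkerMatrix:
    """Read the genotype CSV (first column accession, then one column
    per marker, entries in {-1, 0, 1}) and an optional marker map CSV
    (marker_id, chrom, pos)."""
    df = pd.read_csv(genotype_path, comment="#")
    if df.shape[1] < 2:
        raise SchemaError("genotype table needs an accession column plus markers")
    acc_col = df.columns[0]
    geno = df.drop(columns=[acc_col])
    values = geno.to_numpy()
    ok = np.isin(values, (-1, 0, 1))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise SchemaError(
            f"invalid genotype code {values[r, c]!r} at accession "
            f"{df[acc_col].iloc[r]!r}, marker {geno.columns[c]!r}"
        )
    marker_ids = list(geno.columns)
    if map_path is not None:
        mm = pd.read_csv(map_path, comment="#")
        for col in ("marker_id", "chrom", "pos"):
            if col not in mm.columns:
                raise SchemaError(f"marker map missing column {col!r}")
        mm = mm.set_index("marker_id").reindex(marker_ids)
        if mm["chrom"].isna().any():
            lost = mm.index[mm["chrom"].isna()][0]
            raise SchemaError(f"marker {lost!r} absent from marker map")
        chrom = mm["chrom"].to_numpy()
        pos = mm["pos"].to_numpy()
    else:
        chrom = np.ones(len(marker_ids), dtype=int)
        pos = np.arange(1, len(marker_ids) + 1)
    return MarkerMatrix(
        genotypes=values.astype(np.int8),
        accession_ids=[str(a) for a in df[acc_col]],
        marker_ids=marker_ids,
        chromosome=chrom,
        position_bp=pos,
    )


def write_markers(markers: MarkerMatrix, genotype_path, map_path=None,
                  config: Optional[RunConfig] = None) -> None:
    df = pd.DataFrame(markers.genotypes, columns=markers.marker_ids)
    df.insert(0, "accession", markers.accession_ids)
    _write_csv(df, Path(genotype_path), config)
    if map_path is not None:
        _write_csv(markers.marker_map(), Path(map_path), config)


def match_markers_to_phenotypes(
    markers: MarkerMatrix, trajectories: List[PlantTrajectory]
) -> MarkerMatrix:
    """Drop marker rows for accessions absent from the phenotypes."""
    pheno_accs = {tr.accession for tr in trajectories}
    keep = [a for a in markers.accession_ids if a in pheno_accs]
    dropped = len(markers.accession_ids) - len(keep)
    if dropped:
        logger.info("dropped %d marker rows without phenotypes", dropped)
    return markers.subset_accessions(keep)


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> QC -> per-treatment genomic fit -> TOI -> GWAS -> stats.

    Every stage writes its CSV under ``config.out_dir`` plus a
    ``manifest.json`` recording the seed, settings and per-stage record
    counts.  Any stage failure aborts with the stage name; partial
    outputs are left in place.
    """
    from .genome_fit import EBLHyper, GenomeFitConfig, fit_genome_enabled
    from .gwas_toi import BLProbitConfig, derive_toi_table, rank_top_markers, run_toi_gwas
    from .pheno_stats import (
        derived_ratio_traits,
        evaluate_predictions,
        iqr_outlier_flags,
        timepoint_ttests,
    )
    from .growth_core import CONTROL, DROUGHT, GrowthParams, wsi_gomp_predict

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    stage = "simulate"
    try:
        t0 = time.time()
        if config.phenotype_path is not None:
            trajectories = read_phenotypes(config.phenotype_path)
            markers = read_markers(config.marker_path, config.marker_map_path)
            truth = None
        else:
            markers = simulate_genotypes(
                config.n_accessions, config.n_markers, seed=rng.integers(2**31)
            )
            arch, truth = simulate_true_effects(
                markers,
                n_qtl=config.n_qtl,
                heritability=config.heritability,
                seed=rng.integers(2**31),
            )
            design = DesignSpec(
                n_accessions=config.n_accessions,
                n_replicated=config.n_replicated,
                n_experiments=config.n_experiments,
                n_days=config.n_days,
            )
            trajectories = simulate_experiment(
                markers, truth, design=design, noise_cv=config.noise_cv,
                seed=rng.integers(2**31),
            )
            trajectories, labels = inject_artifacts(
                trajectories,
                outlier_rate=config.outlier_rate,
                missing_rate=config.missing_rate,
                seed=rng.integers(2**31),
            )
            _write_csv(truth, out / "true_params.csv", config)
            _write_csv(labels, out / "artifact_labels.csv", config)
            write_markers(markers, out / "genotypes.csv", out / "marker_map.csv", config)
        write_phenotypes(trajectories, out / "phenotypes.csv", config)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "n_plants": len(trajectories),
        }

        stage = "qc"
        t0 = time.time()
        psa_mat = np.array([tr.psa for tr in trajectories])
        flagged = np.zeros(len(trajectories), dtype=bool)
        for d in range(psa_mat.shape[1]):
            flagged |= iqr_outlier_flags(psa_mat[:, d])
        kept = [tr for tr, bad in zip(trajectories, flagged) if not bad]
        logger.info("%d plants removed by IQR rule", int(flagged.sum()))
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "n_flagged": int(flagged.sum()),
            "n_kept": len(kept),
        }

        stage = "fit_genomic"
        t0 = time.time()
        markers_j = match_markers_to_phenotypes(markers, kept)
        gf_config = GenomeFitConfig(
            n_iter=config.gf_n_iter,
            burn_in=config.gf_burn_in,
            thin=config.gf_thin,
            hyper=EBLHyper(config.phi, config.omega, config.psi, config.theta),
        )
        summaries = {}
        alpha_rows = []
        for treatment in (CONTROL, DROUGHT):
            summary = fit_genome_enabled(
                kept, markers_j, config=gf_config, seed=int(rng.integers(2**31)),
                treatment=treatment,
            )
            summaries[treatment] = summary
            tab = summary.accession_params.assign(treatment=treatment)
            _write_csv(tab, out / f"params_{treatment}.csv", config)
            _write_csv(
                summary.marker_effects.assign(treatment=treatment),
                out / f"marker_effects_{treatment}.csv",
                config,
            )
            alpha_rows.append(
                tab[["accession", "treatment", "alpha_mean"]].rename(
                    columns={"alpha_mean": "alpha"}
                )
            )
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "toi"
        t0 = time.time()
        alpha_table = pd.concat(alpha_rows, ignore_index=True)
        toi_table = derive_toi_table(alpha_table, kept)
        _write_csv(toi_table, out / "toi.csv", config)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "n_records": len(toi_table),
            "n_censored": int(toi_table["censored"].sum()),
        }

        stage = "gwas"
        t0 = time.time()
        gwas_config = BLProbitConfig(
            n_iter=config.gwas_n_iter,
            burn_in=config.gwas_burn_in,
            thin=config.gwas_thin,
            prior_r2=config.prior_r2,
        )
        for treatment in (CONTROL, DROUGHT):
            sub = toi_table[toi_table["treatment"] == treatment]
            if sub["censored"].all() or sub["toi_day"].nunique() < 2:
                logger.info("skipping %s TOI GWAS: degenerate response", treatment)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, effects = run_toi_gwas(
                    toi_table, markers_j, treatment,
                    config=gwas_config, seed=int(rng.integers(2**31)),
                )
            _write_csv(effects, out / f"toi_gwas_{treatment}.csv", config)
            _write_csv(rank_top_markers(effects, k=20), out / f"toi_top20_{treatment}.csv", config)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "stats"
        t0 = time.time()
        _write_csv(timepoint_ttests(kept, "fc"), out / "ttests_fc.csv", config)
        _write_csv(timepoint_ttests(kept, "psa"), out / "ttests_psa.csv", config)
        _write_csv(derived_ratio_traits(kept), out / "psa_dr.csv", config)
        # model evaluation: predicted vs observed PSA per treatment
        eval_frames = []
        for treatment in (CONTROL, DROUGHT):
            summary = summaries[treatment]
            pmap = summary.accession_params.set_index("accession")
            trs = [
                tr for tr in kept
                if tr.treatment == treatment and tr.accession in pmap.index
                and np.all(np.isfinite(tr.psa))
            ]
            if not trs:
                continue
            t_grid = standardize_time(trs[0].n_days)
            pred = np.array(
                [
                    wsi_gomp_predict(
                        t_grid,
                        compute_wsi(tr.fc),
                        GrowthParams(
                            pmap.loc[tr.accession, "psa_max_mean"],
                            pmap.loc[tr.accession, "r_mean"],
                            pmap.loc[tr.accession, "alpha_mean"],
                        ),
                    )
                    for tr in trs
                ]
            )
            obs = np.array([tr.psa for tr in trs])
            eval_frames.append(evaluate_predictions(pred, obs).assign(treatment=treatment))
        if eval_frames:
            _write_csv(pd.concat(eval_frames, ignore_index=True), out / "evaluation.csv", config)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:  # preserve partial outputs, name the stage
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
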