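"""End-to-end orchestration: simulate/load -> clean -> growth -> traits ->
production -> genetics -> report, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .feed import clean_daily
from .genetics import pedigree_A, reml_bivariate, reml_univariate
from .growth import curves_to_frame, fit_all_curves
from .production import build_production_table
from .resilience import build_resilience_table
from .simulate import SimConfig, simulate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# fixed effects per trait family: wean-to-finish traits are adjusted for
# batch and quarantine entry age; finishing traits for batch, finishing
# start age and pen
_MORTALITY_TRAITS = ("mortality", "trt", "trt180")
_FINISHING_TRAITS = ("rmse_fi", "rmse_dur", "qr_fi", "qr_dur", "fin_adg", "adfi", "fcr")

_DEFAULT_PAIRS = (
    ("qr_fi", "mortality"),
    ("qr_dur", "mortality"),
    ("rmse_fi", "trt180"),
    ("rmse_dur", "trt180"),
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either ``sim`` (simulate a cohort) or ``input_dir`` (load CSV tables)
    must be provided.
    """

    outdir: str = "run"
    sim: SimConfig | None = None
    input_dir: str | None = None
    tau: float = 0.05
    min_days: int = 60
    fi_cap: float = 5.0
    impute_window: int = 5
    loess_span: float = 0.75
    loess_degree: int = 2
    run_genetics: bool = True
    bivariate_pairs: tuple = _DEFAULT_PAIRS
    seed: int = 0

    def to_dict(self) -> dict:
        # outdir is excluded: where a run is written does not change what
        # it computes, and the config hash must track semantics only
        d = {
            "input_dir": self.input_dir,
            "tau": self.tau,
            "min_days": self.min_days,
            "fi_cap": self.fi_cap,
            "impute_window": self.impute_window,
            "loess_span": self.loess_span,
            "loess_degree": self.loess_degree,
            "run_genetics": self.run_genetics,
            "bivariate_pairs": [list(p) for p in self.bivariate_pairs],
            "seed": self.seed,
            "sim": self.sim.to_dict() if self.sim is not None else None,
        }
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    if cfg.sim is not None:
        cohort = simulate_cohort(cfg.sim)
        return (
            cohort.animals,
            cohort.daily,
            cohort.weights,
            cohort.treatments,
            cohort.carcass,
            cohort.pedigree,
        )
    indir = Path(cfg.input_dir)
    tables = {}
    for name in ("animals", "daily", "weights", "treatments", "carcass", "pedigree"):
        path = indir / f"{name}.csv"
        if not path.exists():
            stage = "feed_records" if name == "daily" else "inputs"
            raise PipelineError(stage, f"required input table missing: {path}")
        tables[name] = pd.read_csv(path, keep_default_na=True)
    return (
        tables["animals"],
        tables["daily"],
        tables["weights"],
        tables["treatments"],
        tables["carcass"],
        tables["pedigree"],
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Identical configuration produces byte-identical outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}

    animals, daily, weights, treatments, carcass, pedigree = _load_inputs(cfg)
    if cfg.sim is not None:
        animals.to_csv(out / "animals.csv", index=False)
        daily.to_csv(out / "daily.csv", index=False)
        weights.to_csv(out / "weights.csv", index=False)
        treatments.to_csv(out / "treatments.csv", index=False)
        carcass.to_csv(out / "carcass.csv", index=False)
        pedigree.to_csv(out / "pedigree.csv", index=False)

    try:
        cleaned, report = clean_daily(daily, cap=cfg.fi_cap, window=cfg.impute_window)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("feed_records", str(e)) from e
    cleaned.to_csv(out / "daily_clean.csv", index=False)
    with open(out / "cleaning.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    counts["daily_clean"] = len(cleaned)

    try:
        curves = fit_all_curves(weights, span=cfg.loess_span, degree=cfg.loess_degree)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("growth_model", str(e)) from e
    curves_to_frame(curves).to_csv(out / "daily_weights.csv", index=False)
    counts["growth_curves"] = len(curves)

    try:
        resilience, lines = build_resilience_table(
            cleaned, animals, treatments, tau=cfg.tau, min_days=cfg.min_days
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("resilience_traits", str(e)) from e
    resilience.round(6).to_csv(out / "resilience.csv", index=False)
    with open(out / "quantile_lines.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in lines.items()}, fh, indent=1, sort_keys=True)
    counts["resilience"] = len(resilience)

    try:
        production = build_production_table(cleaned, animals, curves, carcass)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("production_traits", str(e)) from e
    production.round(6).to_csv(out / "production.csv", index=False)
    counts["production"] = len(production)

    phenotypes = resilience.merge(
        animals[
            ["animal_id", "batch", "pen", "quarantine_entry_age", "finishing_start_age"]
        ],
        on="animal_id",
    ).merge(
        production[["animal_id", "fin_adg", "adfi", "fcr", "rfi"]], on="animal_id"
    )
    phenotypes.round(6).to_csv(out / "phenotypes.csv", index=False)

    if cfg.run_genetics:
        try:
            estimates = estimate_genetic_parameters(
                phenotypes, pedigree, cfg.bivariate_pairs
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("genetic_inference", str(e)) from e
        estimates.round(6).to_csv(out / "estimates.csv", index=False)
        counts["estimates"] = len(estimates)

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "row_counts": counts,
        "cleaning": report.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def estimate_genetic_parameters(
    phenotypes: pd.DataFrame, pedigree: pd.DataFrame, pairs=_DEFAULT_PAIRS
) -> pd.DataFrame:
    """Univariate h2 for every trait plus bivariate r_g for chosen pairs."""
    A = pedigree_A(pedigree)
    rows = []
    for trait in (*_MORTALITY_TRAITS, *_FINISHING_TRAITS):
        if trait not in phenotypes.columns or phenotypes[trait].notna().sum() < 50:
            continue
        if trait in _MORTALITY_TRAITS:
            fac, cov = ("batch",), ("quarantine_entry_age",)
        else:
            fac, cov = ("batch", "pen"), ("finishing_start_age",)
        est = reml_univariate(
            phenotypes, trait, A, fixed_factors=fac, fixed_covariates=cov
        )
        rows.append(
            {
                "model": "univariate",
                "trait1": trait,
                "trait2": "",
                "n": est.n,
                "sigma2_a": est.sigma2_a[0],
                "sigma2_e": est.sigma2_e[0],
                "sigma_a12": np.nan,
                "h2_1": est.h2[0],
                "h2_2": np.nan,
                "r_g": np.nan,
                "se_h2_1": est.se.get("h2", np.nan),
                "se_r_g": np.nan,
                "loglik": est.loglik,
                "converged": est.converged,
            }
        )
    for t1, t2 in pairs:
        if t1 not in phenotypes.columns or t2 not in phenotypes.columns:
            continue
        both = phenotypes[[t1, t2]].dropna()
        if len(both) < 50:
            continue
        est = reml_bivariate(
            phenotypes,
            (t1, t2),
            A,
            fixed_factors=("batch",),
            fixed_covariates=("finishing_start_age",),
        )
        rows.append(
            {
                "model": "bivariate",
                "trait1": t1,
                "trait2": t2,
                "n": est.n,
                "sigma2_a": est.sigma2_a[0],
                "sigma2_e": est.sigma2_e[0],
                "sigma_a12": est.sigma_a12,
                "h2_1": est.h2[0],
                "h2_2": est.h2[1],
                "r_g": est.r_g,
                "se_h2_1": est.se.get("h2_1", np.nan),
                "se_r_g": est.se.get("r_g", np.nan),
                "loglik": est.loglik,
                "converged": est.converged,
            }
        )
    return pd.DataFrame(rows)


def summary_report(rundir: str | Path, batches_per_cycle: int = 7) -> dict:
    """Summary tables for a completed run.

    ``cycles``: per-cycle counts, mortality % and resilience-trait means.
    ``heritability``: univariate h2 (SE) per trait and bivariate r_g (SE).
    """
    rundir = Path(rundir)
    res = pd.read_csv(rundir / "resilience.csv")
    animals = pd.read_csv(rundir / "animals.csv")
    d = res.merge(animals[["animal_id", "batch"]], on="animal_id")
    d["cycle"] = (d["batch"] - 1) // batches_per_cycle + 1
    cyc = (
        d.groupby("cycle")
        .agg(
            count=("animal_id", "size"),
            mortality_pct=("mortality", lambda v: 100.0 * v.mean()),
            trt=("trt", "mean"),
            trt180=("trt180", "mean"),
            rmse_fi=("rmse_fi", "mean"),
            rmse_dur=("rmse_dur", "mean"),
            qr_fi=("qr_fi", "mean"),
            qr_dur=("qr_dur", "mean"),
        )
        .reset_index()
    )
    out = {"cycles": cyc}
    est_path = rundir / "estimates.csv"
    if est_path.exists():
        est = pd.read_csv(est_path)
        uni = est[est["model"] == "univariate"][
            ["trait1", "n", "h2_1", "se_h2_1", "converged"]
        ].rename(columns={"trait1": "trait", "h2_1": "h2", "se_h2_1": "se"})
        biv = est[est["model"] == "bivariate"][
            ["trait1", "trait2", "n", "r_g", "se_r_g", "converged"]
        ].rename(columns={"se_r_g": "se"})
        out["heritability"] = uni.reset_index(drop=True)
        out["genetic_correlations"] = biv.reset_index(drop=True)
    return out
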