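"""Synthetic natural disease-challenge cohort generator.

Simulates wean-to-finish pig cohorts with the statistical structure the
resilience analysis assumes: batches entering a continuously challenged
facility, a half-sib pedigree carrying additive-genetic (co)variation in
latent susceptibility, appetite and growth, illness episodes that depress
feed intake and feeder duration, severity-triggered treatments and deaths,
sparse body weights, and carcass records for survivors.

All randomness flows from a single root seed; each animal draws from its
own substream keyed by (seed, animal index) so cohorts are reproducible
under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LATENT_TRAITS = ("susceptibility", "appetite", "growth")

_DEFAULT_H2 = {"susceptibility": 0.35, "appetite": 0.35, "growth": 0.35}

# genetic correlations among (susceptibility, appetite, growth):
# sick-prone pigs eat less and grow slower; appetite and growth align.
_DEFAULT_CORR = np.array(
    [
        [1.0, -0.30, -0.40],
        [-0.30, 1.0, 0.50],
        [-0.40, 0.50, 1.0],
    ]
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design and biology parameters for one simulated cohort.

    Defaults emulate a three-cycle natural-challenge experiment:
    21 batches of ~64 barrows, ~26% wean-to-finish mortality, daily feed
    intake averaging ~2.2 kg/day and rising with age, feeder duration on
    a ~13 min day-to-day variability scale.
    """

    n_batches: int = 21
    pigs_per_batch: int = 64
    n_sires: int = 112
    dams_per_sire: int = 3
    trait_h2: dict = field(default_factory=lambda: dict(_DEFAULT_H2))
    genetic_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    # feed intake baseline: fi = intercept + slope * (age - finishing start)
    baseline_fi_intercept: float = 1.51  # kg/day at finishing start
    baseline_fi_slope: float = 0.0145  # kg/day per day of age
    fi_noise_sd: float = 0.385  # kg, day-to-day residual on healthy days
    baseline_dur_mean: float = 70.0  # min/day at the feeder, mid-finishing
    dur_noise_sd: float = 10.5  # min, residual beyond the intake-driven part
    # illness episode process
    episode_rate: float = 2.0  # onsets per animal per 100 days at risk
    episode_depth_range: tuple = (0.2, 1.0)  # fractional FI reduction
    episode_length_range: tuple = (3, 15)  # days
    episode_depth_log_mu: float = math.log(0.35)
    episode_depth_log_sd: float = 0.5
    episode_susceptibility_scale: float = 0.4  # log-depth shift per latent SD
    # severity = depth * length (depth-days); thresholds calibrated so the
    # default cohort realizes ~26% mortality and ~2.4 treatments/180 days
    mortality_severity_threshold: float = 7.0
    treatment_severity_threshold: float = 1.85
    # growth
    gain_base: float = 0.20  # kg/day at weaning
    gain_max: float = 0.99  # kg/day asymptote for an average pig
    gain_ramp_days: float = 100.0
    weight_noise_sd: float = 1.0  # kg, scale weighing error
    # life-history ages (days)
    finishing_age_span: tuple = (70, 180)
    quarantine_entry_age: int = 21
    weigh_interval: int = 21
    pens_per_batch: int = 4
    # data-quality artefacts of electronic feeders
    spike_rate: float = 0.002  # fraction of days with an implausible FI spike
    missing_rate: float = 0.01  # fraction of days with a lost daily total
    # optional sinusoidal batch severity multiplier (amplitude; 0 = off)
    batch_seasonality: float = 0.0
    mask_sires: bool = False  # export a dam-only pedigree
    seed: int = 0

    def __post_init__(self):
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        if self.n_batches < 1 or self.pigs_per_batch < 1:
            raise ConfigError("cohort must contain at least one pig")
        if self.n_sires < 1 or self.dams_per_sire < 1:
            raise ConfigError("pedigree needs at least one sire and dam")
        for k, v in self.trait_h2.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"heritability of {k!r} outside [0, 1]: {v}")
        C = self.genetic_corr
        if C.shape != (len(LATENT_TRAITS),) * 2 or not np.allclose(C, C.T):
            raise ConfigError("genetic_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ConfigError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigError("genetic_corr is not positive semi-definite")
        lo, hi = self.episode_depth_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("episode_depth_range must lie within [0, 1]")
        a, b = self.finishing_age_span
        if not a < b:
            raise ConfigError("finishing_age_span must satisfy start < end")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genetic_corr"] = self.genetic_corr.tolist()
        return d


@dataclass
class SimulatedCohort:
    """One simulated cohort: records plus the generating truth."""

    animals: pd.DataFrame  # one row per pig: ids, batch/pen, life events
    daily: pd.DataFrame  # animal_id, age, fi, dur
    weights: pd.DataFrame  # animal_id, age, weight
    treatments: pd.DataFrame  # animal_id, age, reason
    carcass: pd.DataFrame  # survivors only
    pedigree: pd.DataFrame  # animal_id, sire_id, dam_id ('' = unknown)
    true_breeding_values: pd.DataFrame  # animal_id + latent-trait BVs
    config: SimConfig
    genotypes: pd.DataFrame | None = None  # animal x SNP dosage matrix

    def write(self, outdir: str | Path) -> None:
        """Write all tables as headered CSV plus the config as YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.animals.to_csv(outdir / "animals.csv", index=False)
        self.daily.to_csv(outdir / "daily.csv", index=False)
        self.weights.to_csv(outdir / "weights.csv", index=False)
        self.treatments.to_csv(outdir / "treatments.csv", index=False)
        self.carcass.to_csv(outdir / "carcass.csv", index=False)
        ped = self.pedigree
        if self.config.mask_sires:
            ped = ped.assign(sire_id="")
        ped.to_csv(outdir / "pedigree.csv", index=False)
        self.true_breeding_values.to_csv(outdir / "truth.csv", index=False)
        if self.genotypes is not None:
            self.genotypes.to_csv(outdir / "genotypes.csv")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)


def _bv_covariance(cfg: SimConfig) -> np.ndarray:
    s = np.sqrt([cfg.trait_h2[t] for t in LATENT_TRAITS])
    return cfg.genetic_corr * np.outer(s, s)


def _draw_pedigree_bvs(cfg: SimConfig, n_offspring: int, rng: np.random.Generator):
    """Half-sib family design: each sire mated to several dams.

    Returns (sire ids, dam ids, per-offspring sire/dam index, founder BVs,
    offspring BVs).  BVs follow the additive infinitesimal model: offspring
    BV = parent average + an independent Mendelian-sampling deviation with
    half the additive covariance.
    """
    G = _bv_covariance(cfg)
    L = np.linalg.cholesky(G + 1e-12 * np.eye(len(LATENT_TRAITS)))
    n_dams = cfg.n_sires * cfg.dams_per_sire
    bv_sires = rng.standard_normal((cfg.n_sires, 3)) @ L.T
    bv_dams = rng.standard_normal((n_dams, 3)) @ L.T
    dam_of = np.arange(n_dams)
    sire_of_dam = dam_of // cfg.dams_per_sire

    # litters fill the cohort round-robin; littermates stay together
    litter_size = int(math.ceil(n_offspring / n_dams))
    dam_idx = np.repeat(dam_of, litter_size)[:n_offspring]
    sire_idx = sire_of_dam[dam_idx]
    mend = rng.standard_normal((n_offspring, 3)) @ (L.T * math.sqrt(0.5))
    bv_off = 0.5 * (bv_sires[sire_idx] + bv_dams[dam_idx]) + mend
    return bv_sires, bv_dams, sire_idx, dam_idx, bv_off


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort under the configured challenge conditions.

    Identical config (including seed) yields a byte-identical cohort.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_batches * cfg.pigs_per_batch
    fin_start_nom, fin_end = cfg.finishing_age_span

    bv_sires, bv_dams, sire_idx, dam_idx, bv = _draw_pedigree_bvs(cfg, n, rng)
    # latent phenotype = BV + independent environmental deviation, unit total
    # variance per trait
    env_sd = np.sqrt([1.0 - cfg.trait_h2[t] for t in LATENT_TRAITS])
    latent = bv + rng.standard_normal((n, 3)) * env_sd
    susc, appet, growth = latent.T

    batch = np.repeat(np.arange(1, cfg.n_batches + 1), cfg.pigs_per_batch)
    pen = rng.integers(1, cfg.pens_per_batch + 1, size=n)
    seasonal = 1.0 + cfg.batch_seasonality * np.sin(
        2 * np.pi * (batch - 1) * 3 / 52.0  # batches every three weeks
    )

    depth_lo, depth_hi = cfg.episode_depth_range
    len_lo, len_hi = cfg.episode_length_range
    p_onset = cfg.episode_rate / 100.0

    animal_rows, daily_rows, weight_rows, trt_rows, carc_rows = [], [], [], [], []

    for i in range(n):
        arng = np.random.default_rng([cfg.seed, i])
        aid = f"P{i + 1:05d}"
        entry = cfg.quarantine_entry_age + int(arng.integers(-3, 4))
        fin_start = fin_start_nom + int(arng.integers(-5, 6))
        slaughter = fin_end

        # --- illness episodes over the whole at-risk window -------------
        # Per-day candidate draws are made unconditionally so that raising
        # episode_rate only adds onsets without perturbing existing ones.
        ages = np.arange(entry, slaughter + 1)
        nd = len(ages)
        u = arng.random(nd)
        raw_depth = np.exp(
            cfg.episode_depth_log_mu
            + cfg.episode_susceptibility_scale * susc[i]
            + cfg.episode_depth_log_sd * arng.standard_normal(nd)
        )
        depths = np.clip(raw_depth, depth_lo, depth_hi)
        lengths = arng.integers(len_lo, len_hi + 1, size=nd)
        onsets = np.nonzero(u < p_onset)[0]

        death_age = None
        reduction = np.zeros(nd)  # active fractional FI reduction by age
        for j in onsets:
            if death_age is not None and ages[j] >= death_age:
                break
            d, ln = depths[j], int(lengths[j])
            severity = d * ln * seasonal[i]
            # rectangular depth profile with 2-day onset/recovery ramps
            t = np.arange(ln)
            prof = d * np.minimum.reduce([np.ones(ln), (t + 1) / 2.0, (ln - t) / 2.0])
            hi = min(j + ln, nd)
            reduction[j:hi] = np.maximum(reduction[j:hi], prof[: hi - j])
            trt_age = min(int(ages[j]) + 1, slaughter)
            if severity > cfg.mortality_severity_threshold:
                da = int(ages[j]) + max(1, ln // 2)
                death_age = da if death_age is None else min(death_age, da)
                if severity > cfg.treatment_severity_threshold:
                    trt_rows.append((aid, trt_age, "clinical"))
            elif severity > cfg.treatment_severity_threshold:
                trt_rows.append((aid, trt_age, "clinical"))

        if death_age is not None and death_age > slaughter:
            death_age = None  # made it to slaughter despite a late episode
        last_alive = slaughter if death_age is None else min(death_age, slaughter)

        # --- daily feed intake and feeder duration ----------------------
        fi_int = cfg.baseline_fi_intercept + 0.25 * appet[i]
        fi_slope = cfg.baseline_fi_slope + 0.002 * growth[i]
        last_fi_day = last_alive if death_age is None else last_alive - 1
        if last_fi_day >= fin_start:
            fa = np.arange(fin_start, last_fi_day + 1)
            k = fa - entry  # index into reduction profile
            red = reduction[k]
            base = fi_int + fi_slope * (fa - fin_start)
            fi = base * (1.0 - red) + cfg.fi_noise_sd * arng.standard_normal(len(fa))
            fi = np.maximum(fi, 0.0)
            # duration follows the illness-reduced expected intake through an
            # animal-specific eating rate, with its own independent noise, so
            # off-feed episodes depress both channels while healthy-day noise
            # stays channel-specific (duration variance roughly flat in age)
            mid_fi = fi_int + fi_slope * (fin_end - fin_start_nom) / 2.0
            pop_mid = cfg.baseline_fi_intercept + cfg.baseline_fi_slope * (
                fin_end - fin_start_nom
            ) / 2.0
            dur_base = cfg.baseline_dur_mean * mid_fi / pop_mid
            dur = dur_base * (1.0 - red) + cfg.dur_noise_sd * arng.standard_normal(len(fa))
            dur = np.maximum(dur, 0.0)
            # recording artefacts: spikes and lost days
            art = arng.random(len(fa))
            spike = art < cfg.spike_rate
            lost = (art >= cfg.spike_rate) & (art < cfg.spike_rate + cfg.missing_rate)
            fi[spike] = 5.5 + 2.5 * arng.random(spike.sum())
            fi[lost] = np.nan
            dur[lost] = np.nan
            for a_, f_, d_ in zip(fa, fi, dur):
                daily_rows.append((aid, int(a_), f_, d_))

        # --- growth and sparse weights ----------------------------------
        all_ages = np.arange(entry, last_alive + 1)
        gmax = cfg.gain_max * (1.0 + 0.12 * growth[i])
        ramp = np.clip((all_ages - cfg.quarantine_entry_age) / cfg.gain_ramp_days, 0, 1)
        gain = cfg.gain_base + (gmax - cfg.gain_base) * ramp
        k = all_ages - entry
        gain = gain * (1.0 - 0.5 * reduction[: len(all_ages)][k])
        w0 = 6.5 + 0.5 * arng.standard_normal()
        true_w = w0 + np.concatenate([[0.0], np.cumsum(gain[:-1])])
        weigh_ages = np.arange(entry, last_alive + 1, cfg.weigh_interval)
        if weigh_ages[-1] != last_alive:
            weigh_ages = np.append(weigh_ages, last_alive)
        for wa in weigh_ages:
            obs = true_w[wa - entry] + cfg.weight_noise_sd * arng.standard_normal()
            weight_rows.append((aid, int(wa), round(max(obs, 1.0), 2)))

        live_wt = None
        if death_age is None:
            live_wt = true_w[-1] + cfg.weight_noise_sd * arng.standard_normal()
            drs = np.clip(0.78 + 0.015 * arng.standard_normal(), 0.68, 0.86)
            cbf = max(3.0, 17.96 + 1.5 * appet[i] + 3.3 * arng.standard_normal())
            cld = max(30.0, 60.7 + 6.0 * arng.standard_normal())
            carc_rows.append(
                (
                    aid,
                    round(drs * live_wt, 2),
                    round(cbf, 2),
                    round(cld, 2),
                    round(live_wt, 2),
                    round(cbf + 1.0 * arng.standard_normal(), 2),
                )
            )

        animal_rows.append(
            (
                aid,
                int(batch[i]),
                f"B{batch[i]:02d}-{pen[i]}",
                entry,
                fin_start,
                death_age if death_age is not None else "",
                slaughter if death_age is None else "",
                death_age is None,
                round(live_wt, 2) if live_wt is not None else "",
            )
        )

    animals = pd.DataFrame(
        animal_rows,
        columns=[
            "animal_id",
            "batch",
            "pen",
            "quarantine_entry_age",
            "finishing_start_age",
            "death_age",
            "slaughter_age",
            "slaughtered",
            "live_weight_at_slaughter",
        ],
    )
    daily = pd.DataFrame(daily_rows, columns=["animal_id", "age", "fi", "dur"])
    daily["fi"] = daily["fi"].round(4)
    daily["dur"] = daily["dur"].round(3)
    weights = pd.DataFrame(weight_rows, columns=["animal_id", "age", "weight"])
    treatments = pd.DataFrame(trt_rows, columns=["animal_id", "age", "reason"])
    carcass = pd.DataFrame(
        carc_rows,
        columns=["animal_id", "cwt", "cbf", "cld", "live_weight", "ultrasound_bf"],
    )
    sid = [f"S{j + 1:04d}" for j in range(cfg.n_sires)]
    did = [f"D{j + 1:04d}" for j in range(cfg.n_sires * cfg.dams_per_sire)]
    pedigree = pd.DataFrame(
        {
            "animal_id": sid + did + list(animals["animal_id"]),
            "sire_id": [""] * (len(sid) + len(did)) + [sid[j] for j in sire_idx],
            "dam_id": [""] * (len(sid) + len(did)) + [did[j] for j in dam_idx],
        }
    )
    tbv = pd.DataFrame(bv, columns=[f"bv_{t}" for t in LATENT_TRAITS])
    tbv.insert(0, "animal_id", animals["animal_id"])
    return SimulatedCohort(
        animals=animals,
        daily=daily,
        weights=weights,
        treatments=treatments,
        carcass=carcass,
        pedigree=pedigree,
        true_breeding_values=tbv,
        config=cfg,
    )


def simulate_genotypes(
    cohort: SimulatedCohort,
    n_snps: int,
    maf_range: tuple = (0.05, 0.5),
) -> SimulatedCohort:
    """Gene-drop SNP dosages through the cohort pedigree.

    Founder genotypes are drawn in Hardy-Weinberg proportions at allele
    frequencies uniform in ``maf_range``; each offspring receives one
    Mendelian allele per parent, so genomic relationships agree with
    pedigree relationships in expectation.  Returns the same cohort with
    its ``genotypes`` field set (animals x SNPs, dosages in {0, 1, 2}).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigError("maf_range must lie within (0, 0.5]")
    ped = cohort.pedigree
    ids = list(ped["animal_id"])
    if n_snps == 0:
        cohort.genotypes = pd.DataFrame(index=pd.Index(ids, name="animal_id"))
        return cohort
    rng = np.random.default_rng([cohort.config.seed, 987654321])
    p = rng.uniform(lo, hi, size=n_snps)
    idx = {a: k for k, a in enumerate(ids)}
    dos = np.zeros((len(ids), n_snps), dtype=np.int8)
    for k, (a, s, d) in enumerate(
        zip(ped["animal_id"], ped["sire_id"], ped["dam_id"])
    ):
        pat = (
            rng.binomial(1, p)
            if s == ""
            else rng.binomial(1, dos[idx[s], :] / 2.0)
        )
        mat = (
            rng.binomial(1, p)
            if d == ""
            else rng.binomial(1, dos[idx[d], :] / 2.0)
        )
        dos[k] = pat + mat
    cohort.genotypes = pd.DataFrame(
        dos,
        index=pd.Index(ids, name="animal_id"),
        columns=[f"SNP{j + 1:06d}" for j in range(n_snps)],
    )
    return cohort


def simulate_half_sib_trait(
    n_sires: int,
    offspring_per_sire: int,
    h2: float,
    seed: int = 0,
    h2_2: float | None = None,
    r_g: float = 0.0,
    r_e: float = 0.0,
):
    """Simulate one or two traits on a paternal half-sib design.

    Every offspring has its own unrelated dam, so paternal half-sibs share
    only the sire (additive relationship 1/4).  Phenotypic variance is 1
    per trait.  Returns ``(phenos, sire_index)`` where ``phenos`` has shape
    (n, 1) or (n, 2).  Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    n = n_sires * offspring_per_sire
    two = h2_2 is not None
    if not two:
        h2_2, r_g, r_e = h2, 0.0, 0.0
    Ga = np.array(
        [
            [h2, r_g * math.sqrt(h2 * h2_2)],
            [r_g * math.sqrt(h2 * h2_2), h2_2],
        ]
    )
    Re = np.array(
        [
            [1 - h2, r_e * math.sqrt((1 - h2) * (1 - h2_2))],
            [r_e * math.sqrt((1 - h2) * (1 - h2_2)), 1 - h2_2],
        ]
    )
    La = np.linalg.cholesky(Ga + 1e-12 * np.eye(2))
    Le = np.linalg.cholesky(Re + 1e-12 * np.eye(2))
    bv_s = rng.standard_normal((n_sires, 2)) @ La.T
    sire = np.repeat(np.arange(n_sires), offspring_per_sire)
    bv_d = rng.standard_normal((n, 2)) @ La.T  # each dam unique, unobserved
    mend = rng.standard_normal((n, 2)) @ (La.T * math.sqrt(0.5))
    bv = 0.5 * (bv_s[sire] + bv_d) + mend
    phen = bv + rng.standard_normal((n, 2)) @ Le.T
    if not two:
        phen = phen[:, :1]
    return phen, sire
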