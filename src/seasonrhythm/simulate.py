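"""Seeded synthetic data generators for every analysis stage.

Every generator is a pure function of (config, seed) and returns the data
together with a JSON-serializable truth dict holding the realized generating
parameters, so downstream fits can be checked by parameter recovery.

Presets encode the cohort scales of the analyses: a combined three-cohort
table (n=2,761) with a standardized cognition amplitude of 0.14 SD peaking
near the fall equinox and a winter/spring diagnosis odds ratio of 1.31; a
memory-clinic table (n=271) with a 0.50 SD amplitude; a CSF biomarker table
(n=321, 176 AD) with a rhythmic Abeta42 (0.30 SD pooled, attenuated in AD)
and non-rhythmic tau; an expression matrix (5,000 genes x 507 samples, 47
modules) with four planted rhythmic, cognition-loaded modules; and a TFBS
layout with planted (TF, module) enrichments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .exceptions import ConfigError
from .timeangles import PERIOD_DAYS, TWO_PI

logger = logging.getLogger(__name__)

BASE_YEAR = 2010


def _dates_from_days(day_offsets: np.ndarray, base_year: int = BASE_YEAR):
    base = pd.Timestamp(f"{base_year}-01-01")
    return base + pd.to_timedelta(np.floor(day_offsets).astype(int), unit="D")


def _sample_days(rng, n, distribution="uniform", month_weights=None,
                 period=PERIOD_DAYS):
    """Day offsets from Jan 1 in [0, 365)."""
    if distribution == "uniform":
        return rng.uniform(0.0, 365.0, n)
    if distribution == "month_weighted":
        if month_weights is None or len(month_weights) != 12:
            raise ConfigError("month_weighted requires 12 month weights")
        w = np.asarray(month_weights, dtype=float)
        w = w / w.sum()
        month = rng.choice(12, size=n, p=w)
        starts = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])
        lengths = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
        return starts[month] + rng.uniform(0, 1, n) * lengths[month]
    raise ConfigError(f"unknown date distribution {distribution!r}")


def _trunc_normal(rng, mean, sd, lower, upper, size):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_normal_var(mean, sd, lower, upper):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(sps.truncnorm.var(a, b, loc=mean, scale=sd))


# ===========================================================================
# cohort tables (cognition + diagnosis)

@dataclass
class CohortConfig:
    n: int = 2761
    outcome_mean: float = 0.26
    sd_total: float = 0.45
    amplitude: float = 0.063          # outcome units (0.14 SD at sd_total=0.45)
    acrophase_day: float = 266.0      # near the fall equinox
    beta_age: float = -0.02625        # per year => 2*amplitude/|beta_age| = 4.8 yr
    beta_sex: float = 0.05
    beta_edu: float = 0.02
    age_mean: float = 76.0
    age_sd: float = 7.0
    age_min: float = 60.0
    age_max: float = 105.0
    female_frac: float = 0.754
    edu_mean: float = 16.0
    edu_sd: float = 3.0
    cohorts: tuple = (("ROS", 0.405, 0.0), ("MAP", 0.404, 0.02),
                      ("MARS", 0.191, -0.07))
    # diagnosis model
    diagnosis_prevalence: float = 0.295
    season_log_or: float = math.log(1.31)
    diagnosis_mechanism: str = "categorical"   # or "cosine"
    diagnosis_cos_amplitude: float = 0.0
    diag_beta_age: float = 0.05
    dementia_frac_of_cases: float = 0.44       # 356/813
    # binary group (e.g. pathological AD)
    group_frac: float | None = 0.6
    group_level_offset: float = -0.2925        # outcome units
    group_amplitude_factor: float = 1.0
    # confounders
    seasonal_confounders: bool = False
    date_distribution: str = "uniform"
    month_weights: tuple | None = None
    base_year: int = BASE_YEAR


def _cohort_residual_sd(cfg: CohortConfig) -> float:
    var_age = cfg.beta_age ** 2 * _trunc_normal_var(cfg.age_mean, cfg.age_sd,
                                                    cfg.age_min, cfg.age_max)
    var_sex = cfg.beta_sex ** 2 * cfg.female_frac * (1 - cfg.female_frac)
    var_edu = cfg.beta_edu ** 2 * cfg.edu_sd ** 2
    fr = np.array([f for _, f, _ in cfg.cohorts], dtype=float)
    off = np.array([o for _, _, o in cfg.cohorts], dtype=float)
    fr = fr / fr.sum()
    var_cohort = float(np.sum(fr * off ** 2) - np.sum(fr * off) ** 2)
    var_group = 0.0
    if cfg.group_frac is not None:
        var_group = (cfg.group_level_offset ** 2
                     * cfg.group_frac * (1 - cfg.group_frac))
    var_season = cfg.amplitude ** 2 / 2.0
    if cfg.group_frac is not None and cfg.group_amplitude_factor != 1.0:
        a = cfg.amplitude
        f = cfg.group_amplitude_factor
        var_season = ((1 - cfg.group_frac) * a ** 2 + cfg.group_frac * (f * a) ** 2) / 2.0
    resid_var = (cfg.sd_total ** 2 - var_age - var_sex - var_edu - var_cohort
                 - var_group - var_season)
    if resid_var <= 0:
        raise ConfigError(
            f"infeasible variance decomposition: residual variance {resid_var:.4g}"
        )
    return math.sqrt(resid_var)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """One row per participant: date, outcome, covariates, diagnosis, group."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n
    sigma = _cohort_residual_sd(cfg)

    days = _sample_days(rng, n, cfg.date_distribution, cfg.month_weights)
    dates = _dates_from_days(days, cfg.base_year)
    theta = TWO_PI * days / PERIOD_DAYS
    phi = TWO_PI * (cfg.acrophase_day - 1.0) / PERIOD_DAYS

    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max, n)
    age_center = float(sps.truncnorm.mean(
        (cfg.age_min - cfg.age_mean) / cfg.age_sd,
        (cfg.age_max - cfg.age_mean) / cfg.age_sd,
        loc=cfg.age_mean, scale=cfg.age_sd))
    sex = rng.binomial(1, cfg.female_frac, n)           # 1 = female
    edu = np.clip(rng.normal(cfg.edu_mean, cfg.edu_sd, n), 5, 25)

    fr = np.array([f for _, f, _ in cfg.cohorts], dtype=float)
    fr = fr / fr.sum()
    cohort_idx = rng.choice(len(cfg.cohorts), size=n, p=fr)
    cohort = np.array([cfg.cohorts[i][0] for i in cohort_idx])
    cohort_off = np.array([cfg.cohorts[i][2] for i in cohort_idx])

    group = None
    amp = np.full(n, cfg.amplitude)
    group_term = 0.0
    if cfg.group_frac is not None:
        group = rng.binomial(1, cfg.group_frac, n)
        group_term = cfg.group_level_offset * (group - cfg.group_frac)
        amp = np.where(group == 1, cfg.amplitude * cfg.group_amplitude_factor,
                       cfg.amplitude)

    outcome = (
        cfg.outcome_mean
        + cfg.beta_age * (age - age_center)
        + cfg.beta_sex * (sex - cfg.female_frac)
        + cfg.beta_edu * (edu - cfg.edu_mean)
        + cohort_off
        + group_term
        + amp * np.cos(theta - phi)
        + rng.normal(0.0, sigma, n)
    )

    # diagnosis: calibrate the intercept on the realized covariates so the
    # marginal prevalence matches the configured one
    winter_spring = (dates.month <= 6).astype(float)
    lin = cfg.diag_beta_age * (age - age_center)
    if cfg.diagnosis_mechanism == "categorical":
        lin = lin + cfg.season_log_or * winter_spring
    elif cfg.diagnosis_mechanism == "cosine":
        lin = lin + cfg.diagnosis_cos_amplitude * np.cos(theta - phi - np.pi)
    else:
        raise ConfigError(f"unknown diagnosis mechanism {cfg.diagnosis_mechanism!r}")

    def prev(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lin))))) - cfg.diagnosis_prevalence

    alpha0 = brentq(prev, -20, 20)
    p_diag = 1.0 / (1.0 + np.exp(-(alpha0 + lin)))
    positive = rng.binomial(1, p_diag)
    dem = rng.binomial(1, cfg.dementia_frac_of_cases, n)
    diagnosis = np.where(positive == 1,
                         np.where(dem == 1, "dementia", "MCI"), "NCI")

    # confounders, independent of the outcome by default
    depress = rng.poisson(1.5, n).astype(float)
    if cfg.seasonal_confounders:
        depress = depress + 0.8 * np.cos(theta - phi - np.pi)
    sleep = np.clip(rng.normal(7.0, 1.2, n), 3, 12)
    activity = np.clip(rng.normal(3.0, 2.0, n), 0, None)
    tsh = np.clip(rng.lognormal(0.6, 0.5, n), 0.05, None)
    test_hour = rng.integers(8, 17, n)

    df = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "assess_date": dates,
        "test_hour": test_hour,
        "outcome": outcome,
        "age_years": age,
        "sex": sex,
        "education_years": edu,
        "cohort": cohort,
        "diagnosis": diagnosis,
        "depression": depress,
        "sleep_hours": sleep,
        "activity_hours": activity,
        "tsh": tsh,
    })
    if group is not None:
        df["group"] = group

    truth = {
        "config": _cfg_dict(cfg),
        "seed": seed,
        "residual_sd": sigma,
        "age_center": age_center,
        "amplitude": cfg.amplitude,
        "amplitude_std": cfg.amplitude / cfg.sd_total,
        "acrophase_day": cfg.acrophase_day,
        "season_or": math.exp(cfg.season_log_or),
        "diag_intercept": alpha0,
        "n_cases": int(positive.sum()),
        "realized_outcome_sd": float(np.std(outcome, ddof=1)),
    }
    return df, truth


# ===========================================================================
# CSF biomarker tables

@dataclass
class AnalyteSpec:
    mean_marginal: float
    sd_marginal: float
    amplitude_std: float       # pooled standardized amplitude (target)
    acrophase_day: float
    ad_offset: float           # AD minus non-AD mean shift
    ad_amplitude_factor: float = 1.0
    beta_age: float = 0.0
    beta_sex: float = 0.0


@dataclass
class CsfConfig:
    n: int = 321
    ad_frac: float = 176.0 / 321.0
    age_mean: float = 70.0
    age_sd: float = 8.0
    age_min: float = 45.0
    age_max: float = 95.0
    female_frac: float = 0.55
    analytes: dict = field(default_factory=lambda: {
        "abeta42": AnalyteSpec(754.0, 280.0, 0.30, 172.0, -270.0, 0.5,
                               beta_age=-2.0, beta_sex=30.0),
        "abeta40": AnalyteSpec(11835.0, 4856.0, 0.12, 172.0, 2000.0, 1.0,
                               beta_age=20.0),
        "tau": AnalyteSpec(469.0, 318.0, 0.0, 172.0, 220.0, 1.0, beta_age=3.0),
        "ptau": AnalyteSpec(71.0, 40.0, 0.0, 172.0, 29.0, 1.0, beta_age=0.4),
    })
    date_distribution: str = "uniform"
    base_year: int = BASE_YEAR


def generate_csf(config: CsfConfig | None = None,
                 seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """CSF analyte table (one lumbar puncture per participant) plus truth."""
    cfg = config or CsfConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n
    w_ad = cfg.ad_frac
    w_non = 1.0 - w_ad

    days = _sample_days(rng, n, cfg.date_distribution)
    dates = _dates_from_days(days, cfg.base_year)
    theta = TWO_PI * days / PERIOD_DAYS
    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max, n)
    age_center = float(sps.truncnorm.mean(
        (cfg.age_min - cfg.age_mean) / cfg.age_sd,
        (cfg.age_max - cfg.age_mean) / cfg.age_sd,
        loc=cfg.age_mean, scale=cfg.age_sd))
    sex = rng.binomial(1, cfg.female_frac, n)
    n_ad = int(round(n * w_ad))
    ad = np.zeros(n, dtype=int)
    ad[rng.choice(n, size=n_ad, replace=False)] = 1

    df = pd.DataFrame({
        "participant_id": [f"C{i:04d}" for i in range(n)],
        "lp_date": dates,
        "age_years": age,
        "sex": sex,
        "diagnosis": np.where(ad == 1, "AD", "nonAD"),
    })
    truth = {"config": _cfg_dict(cfg), "seed": seed, "n_ad": int(ad.sum()),
             "analytes": {}}

    var_age_pop = _trunc_normal_var(cfg.age_mean, cfg.age_sd, cfg.age_min,
                                    cfg.age_max)
    for name, spec in cfg.analytes.items():
        pooled_factor = w_non + w_ad * spec.ad_amplitude_factor
        amp_non = (spec.amplitude_std * spec.sd_marginal / pooled_factor
                   if spec.amplitude_std > 0 else 0.0)
        amp = np.where(ad == 1, amp_non * spec.ad_amplitude_factor, amp_non)
        between_var = w_ad * w_non * spec.ad_offset ** 2
        seasonal_var = (w_non * amp_non ** 2
                        + w_ad * (amp_non * spec.ad_amplitude_factor) ** 2) / 2.0
        var_age = spec.beta_age ** 2 * var_age_pop
        var_sex = spec.beta_sex ** 2 * cfg.female_frac * (1 - cfg.female_frac)
        resid_var = (spec.sd_marginal ** 2 - between_var - seasonal_var
                     - var_age - var_sex)
        if resid_var <= 0:
            raise ConfigError(f"infeasible variance decomposition for {name}")
        mean_non = spec.mean_marginal - w_ad * spec.ad_offset
        phi = TWO_PI * (spec.acrophase_day - 1.0) / PERIOD_DAYS
        values = (
            mean_non
            + spec.ad_offset * ad
            + spec.beta_age * (age - age_center)
            + spec.beta_sex * (sex - cfg.female_frac)
            + amp * np.cos(theta - phi)
            + rng.normal(0.0, math.sqrt(resid_var), n)
        )
        n_trunc = int((values < 0).sum())
        if n_trunc:
            logger.warning("truncating %d negative %s values at 0", n_trunc, name)
        df[name] = np.maximum(values, 0.0)
        truth["analytes"][name] = {
            "amplitude_nonAD": float(amp_non),
            "amplitude_pooled": float(amp_non * pooled_factor),
            "amplitude_std_pooled": spec.amplitude_std,
            "acrophase_day": spec.acrophase_day,
            "ad_offset": spec.ad_offset,
            "ad_amplitude_factor": spec.ad_amplitude_factor,
            "residual_sd": math.sqrt(resid_var),
            "n_truncated": n_trunc,
        }
    return df, truth


# ===========================================================================
# expression matrices

@dataclass
class PlantedModule:
    module_id: str
    size: int
    amplitude_std: float
    phase: str                 # "in" or "anti" relative to cognition
    cognition_loading: float = 0.25


@dataclass
class ExpressionConfig:
    n_genes: int = 5000
    n_samples: int = 507
    n_modules: int = 47
    module_size_range: tuple = (20, 120)
    planted: tuple = (
        PlantedModule("m6", 328, 0.44, "anti"),
        PlantedModule("m13", 353, 0.46, "in"),
        PlantedModule("m109", 390, 0.43, "anti"),
        PlantedModule("m122", 370, 0.46, "in"),
    )
    cognition_acrophase_day: float = 266.0
    # preset default 0.12: with stronger within-module correlation the
    # gene-label permutation null absorbs leaked planted rhythms and the
    # selection criterion becomes unattainable (see tests); configurable
    within_module_r: float = 0.12
    cognition_mean: float = 0.26
    cognition_noise_sd: float = 0.35
    n_batches: int = 8
    date_distribution: str = "uniform"
    base_year: int = BASE_YEAR


def generate_expression(config: ExpressionConfig | None = None,
                        seed: int | None = None):
    """Block-correlated gene x sample matrix with planted rhythmic modules.

    Returns (expr, assignments, meta, cognition, truth): raw-scale expression
    (gene means/scales vary so normalization matters), the gene -> module
    Series, per-sample metadata, the cognition-proximate-to-death vector, and
    the truth dict.
    """
    cfg = config or ExpressionConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.module_size_range
    if not (lo <= hi) or lo < 1:
        raise ConfigError(f"bad module size range {cfg.module_size_range}")
    for p in cfg.planted:
        if p.size < lo:
            raise ConfigError(f"planted module {p.module_id} smaller than bound {lo}")

    n_background = cfg.n_modules - len(cfg.planted)
    bg_sizes = rng.integers(lo, hi + 1, n_background)
    sizes = [p.size for p in cfg.planted] + list(bg_sizes)
    if sum(sizes) > cfg.n_genes:
        raise ConfigError(
            f"module genes ({sum(sizes)}) exceed n_genes ({cfg.n_genes})"
        )
    module_ids = ([p.module_id for p in cfg.planted]
                  + [f"m{200 + i}" for i in range(n_background)])

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    gene_perm = rng.permutation(cfg.n_genes)
    assign_map = {}
    pos = 0
    for mid, size in zip(module_ids, sizes):
        for j in gene_perm[pos:pos + size]:
            assign_map[genes[j]] = mid
        pos += size
    assignments = pd.Series(assign_map).sort_index()

    # sample metadata
    n = cfg.n_samples
    days = _sample_days(rng, n, cfg.date_distribution)
    dates = _dates_from_days(days, cfg.base_year)
    theta = TWO_PI * days / PERIOD_DAYS
    samples = [f"s{i:04d}" for i in range(n)]
    meta = pd.DataFrame({
        "death_date": dates,
        "death_hour": rng.integers(0, 24, n),
        "age_death": _trunc_normal(rng, 88.0, 6.0, 65.0, 108.0, n),
        "sex": rng.binomial(1, 0.65, n),
        "education_years": np.clip(rng.normal(16, 3, n), 5, 25),
        "pmi_hours": np.clip(rng.normal(7.0, 3.0, n), 1.0, None),
        "batch": [f"B{b}" for b in rng.integers(1, cfg.n_batches + 1, n)],
        "rin": np.clip(rng.normal(7.0, 1.0, n), 4.0, 10.0),
    }, index=pd.Index(samples, name="sample_id"))

    phi_cog = TWO_PI * (cfg.cognition_acrophase_day - 1.0) / PERIOD_DAYS
    factors = np.empty((cfg.n_modules, n))
    truth_modules = {}
    for k, mid in enumerate(module_ids):
        planted = next((p for p in cfg.planted if p.module_id == mid), None)
        if planted is not None:
            a = planted.amplitude_std
            phi = phi_cog if planted.phase == "in" else phi_cog + np.pi
            acro_day = (cfg.cognition_acrophase_day - 1.0
                        + (0.0 if planted.phase == "in" else PERIOD_DAYS / 2.0)
                        ) % PERIOD_DAYS + 1.0
        else:
            a, phi, acro_day = 0.0, 0.0, None
        if a ** 2 / 2.0 >= 1.0:
            raise ConfigError(f"module amplitude {a} leaves no residual variance")
        factors[k] = (a * np.cos(theta - phi)
                      + rng.normal(0.0, math.sqrt(1.0 - a ** 2 / 2.0), n))
        truth_modules[mid] = {
            "size": sizes[k], "amplitude_std": a,
            "acrophase_day": acro_day,
            "planted": planted is not None,
            "phase": planted.phase if planted else None,
            "cognition_loading": (
                (planted.cognition_loading if planted.phase == "in"
                 else -planted.cognition_loading) if planted else 0.0),
        }

    lam = math.sqrt(cfg.within_module_r)
    sig_e = math.sqrt(1.0 - cfg.within_module_r)
    values = rng.normal(0.0, sig_e, (cfg.n_genes, n))
    gene_module_idx = np.full(cfg.n_genes, -1)
    for j, g in enumerate(genes):
        mid = assign_map.get(g)
        if mid is not None:
            gene_module_idx[j] = module_ids.index(mid)
    in_module = gene_module_idx >= 0
    values[in_module] += lam * factors[gene_module_idx[in_module]]

    gene_mean = rng.normal(5.0, 2.0, cfg.n_genes)[:, None]
    gene_scale = rng.lognormal(0.0, 0.4, cfg.n_genes)[:, None]
    expr = pd.DataFrame(gene_mean + gene_scale * values,
                        index=pd.Index(genes, name="gene_id"),
                        columns=samples)

    cog = cfg.cognition_mean + rng.normal(0.0, cfg.cognition_noise_sd, n)
    for k, mid in enumerate(module_ids):
        cog = cog + truth_modules[mid]["cognition_loading"] * factors[k]
    cognition = pd.Series(cog, index=pd.Index(samples, name="sample_id"),
                          name="cognition")

    truth = {
        "config": _cfg_dict(cfg),
        "seed": seed,
        "modules": truth_modules,
        "cognition_acrophase_day": cfg.cognition_acrophase_day,
    }
    return expr, assignments, meta, cognition, truth


# ===========================================================================
# TFBS layouts

@dataclass
class TfbsConfig:
    n_genes: int = 5000
    n_tf: int = 161
    p0: float = 0.2
    planted: tuple = (("TF001", "m6", 1.0), ("TF002", "m13", 1.0),
                      ("TF003", "m109", 1.0), ("TF004", "m122", 1.0))
    gene_spacing: int = 10000
    gene_length: int = 2000
    window_bp: int = 2000
    chrom: str = "chrS"


def generate_tfbs(config: TfbsConfig | None = None, seed: int | None = None,
                  assignments: pd.Series | None = None):
    """Gene BED, TFBS BED, and the exact target indicator matrix.

    Interval placement is derived from the sampled indicator matrix (not vice
    versa): a TF gets one short interval within `window_bp` of a gene's TSS
    iff that gene is a sampled target, and gene spacing guarantees no
    cross-gene proximity, so `link_tfbs` recovers the indicators exactly.
    """
    cfg = config or TfbsConfig()
    rng = np.random.default_rng(seed)
    if cfg.n_tf < 1:
        raise ConfigError("n_tf must be >= 1")
    if cfg.gene_spacing < cfg.gene_length + 2 * cfg.window_bp + 200:
        raise ConfigError("gene_spacing too small for the window; genes would "
                          "share TFBS neighbourhoods")

    if assignments is None:
        # scale the four default module sizes to the gene universe
        sizes = {m: max(20, int(round(s * cfg.n_genes / 5000)))
                 for m, s in (("m6", 328), ("m13", 353), ("m109", 390),
                              ("m122", 370))}
        if sum(sizes.values()) > cfg.n_genes:
            raise ConfigError("n_genes too small for default module sizes")
        genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
        perm = rng.permutation(cfg.n_genes)
        assign_map, pos = {}, 0
        for mid, size in sizes.items():
            for j in perm[pos:pos + size]:
                assign_map[genes[j]] = mid
            pos += size
        assignments = pd.Series(assign_map)
        gene_ids = genes
    else:
        gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]

    tf_names = [f"TF{i + 1:03d}" for i in range(cfg.n_tf)]
    planted = {(tf, mod): lor for tf, mod, lor in cfg.planted}
    for tf, mod in planted:
        if tf not in tf_names:
            raise ConfigError(f"planted TF {tf!r} not in catalogue of {cfg.n_tf}")

    member = {mod: set(assignments.index[assignments == mod])
              for _, mod, _ in cfg.planted}

    base_logit = (math.log(cfg.p0 / (1 - cfg.p0)) if 0 < cfg.p0 < 1
                  else (-np.inf if cfg.p0 == 0 else np.inf))
    indicators = np.zeros((cfg.n_genes, cfg.n_tf), dtype=np.int8)
    for t, tf in enumerate(tf_names):
        logits = np.full(cfg.n_genes, base_logit)
        for (ptf, mod), lor in planted.items():
            if ptf != tf:
                continue
            in_mod = np.fromiter((g in member[mod] for g in gene_ids),
                                 dtype=bool, count=cfg.n_genes)
            logits = logits + lor * in_mod
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-logits))
        indicators[:, t] = rng.binomial(1, p)

    # gene layout: alternating strands on a single synthetic chromosome
    starts = np.arange(cfg.n_genes, dtype=np.int64) * cfg.gene_spacing + 3000
    ends = starts + cfg.gene_length
    strands = np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-")
    tss = np.where(strands == "+", starts, ends - 1)
    genes_bed = pd.DataFrame({
        "gene_id": gene_ids, "chrom": cfg.chrom,
        "start": starts, "end": ends, "strand": strands,
    })

    rows = []
    width = 50
    for t, tf in enumerate(tf_names):
        offset = 60 + (t % 25) * 70          # always < window_bp - width
        hit = np.flatnonzero(indicators[:, t])
        for j in hit:
            s = int(tss[j]) + offset
            rows.append((cfg.chrom, s, s + width, tf))
    tfbs_bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])

    targets = pd.DataFrame(indicators,
                           index=pd.Index(gene_ids, name="gene_id"),
                           columns=tf_names)
    truth = {
        "config": _cfg_dict(cfg),
        "seed": seed,
        "planted": [{"tf": tf, "module": mod, "log_or": lor}
                    for (tf, mod), lor in planted.items()],
        "target_counts": {tf: int(indicators[:, t].sum())
                          for t, tf in enumerate(tf_names)},
    }
    return genes_bed, tfbs_bed, targets, assignments, truth


# ===========================================================================
# presets

def _cfg_dict(cfg) -> dict:
    d = asdict(cfg)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return clean(d)


def preset_combined() -> CohortConfig:
    """Three pooled cohorts, n=2,761: 0.14 SD cognition amplitude, OR 1.31."""
    return CohortConfig()


def preset_mars() -> CohortConfig:
    """Single-cohort preset at the MARS scale (n=527, 0.105 SD amplitude)."""
    return CohortConfig(
        n=527, outcome_mean=0.19, sd_total=0.47,
        amplitude=0.105 * 0.47, acrophase_day=266.0,
        cohorts=(("MARS", 1.0, 0.0),),
    )


def preset_sds() -> CohortConfig:
    """Memory-clinic preset: n=271, DRS-scale outcome, 0.50 SD amplitude."""
    return CohortConfig(
        n=271, outcome_mean=115.0, sd_total=17.0,
        amplitude=0.50 * 17.0, acrophase_day=320.0,   # mid November
        beta_age=-0.45, beta_sex=1.0, beta_edu=0.4,
        age_mean=73.0, age_sd=9.0, age_min=45.0, age_max=95.0,
        female_frac=0.55, cohorts=(("SDS", 1.0, 0.0),),
        diagnosis_prevalence=0.99, group_frac=None,
        dementia_frac_of_cases=1.0,
    )


def preset_cnc() -> CsfConfig:
    """CSF biomarker preset: n=321, rhythmic Abeta42 attenuated in AD."""
    return CsfConfig()


def preset_expression() -> ExpressionConfig:
    """5,000 genes x 507 samples, 47 modules, 4 planted rhythmic modules."""
    return ExpressionConfig()


def preset_tfbs() -> TfbsConfig:
    """161-TF catalogue with four planted (TF, module) enrichments."""
    return TfbsConfig()


PRESETS = {
    "combined": preset_combined,
    "mars": preset_mars,
    "sds": preset_sds,
    "cnc": preset_cnc,
    "expression": preset_expression,
    "tfbs": preset_tfbs,
}


def null_cohort_config(n: int = 500) -> CohortConfig:
    """Preset with no seasonal structure anywhere (for calibration checks)."""
    return CohortConfig(n=n, amplitude=0.0, season_log_or=0.0, group_frac=None)
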