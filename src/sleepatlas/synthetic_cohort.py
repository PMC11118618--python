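"""Seeded synthetic cohorts emulating a stratified survey metabolomics study.

The generator produces three linked tables:

* a subject table with survey-design columns (stratum, PSU, sampling weight,
  metabolomics batch), demographic and lifestyle covariates, and sleep
  phenotypes from five domains (Duration, HR, Insomnia, SDB, Timing) on
  continuous, binary and circular (clock-time) scales;
* a metabolite abundance table with batch labels and structured missingness —
  left-censoring at a detection limit for xenobiotics, covariate-dependent
  (missing-at-random) dropout for endogenous metabolites;
* a truth table of planted phenotype -> metabolite effects for recovery
  testing.

Metabolite values are built as standard-normal latents plus planted effects
and exponentiated to a positive abundance scale before censoring, so that
downstream half-minimum imputation and rank normalization are meaningful.
Sampling weights can be made informative (correlated with age), and batch 2
can be given covariate shifts (e.g. an older batch-2 cohort), mirroring the
compositional differences the analysis must be robust to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

DOMAINS = ("Duration", "HR", "Insomnia", "SDB", "Timing")
SCALES = ("continuous", "binary", "circular")

MODEL1_COVARIATES = ["batch", "age", "sex", "center", "background", "bmi"]
MODEL2_COVARIATES = MODEL1_COVARIATES + [
    "alcohol",
    "smoking",
    "physical_activity",
    "diet_score",
]
#: covariates used by the imputation model (synthetic analogues of the
#: metabolic-environment panel: demographics, adiposity, glycemia, lipids)
IMPUTATION_COVARIATES = ["age", "sex", "bmi", "glucose", "insulin", "egfr", "triglycerides"]

CENTERS = ["Bronx", "Chicago", "Miami", "SanDiego"]
BACKGROUNDS = ["Mexican", "PuertoRican", "Cuban", "CentralAmerican", "Dominican", "SouthAmerican", "Other"]
THREE_LEVEL = ["never", "former", "current"]


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 1000
    n_strata: int = 8
    psus_per_stratum: int = 6
    weight_range: tuple = (0.5, 4.0)
    batch_fractions: tuple = (0.6, 0.4)
    seed: int = 0
    #: multiplicative tilt of weights by standardized age; 0 = non-informative
    informative_weight_slope: float = 0.0
    #: additive covariate shifts applied to batch-2 subjects, e.g. {"age": 9.5}
    batch2_covariate_shifts: dict = field(default_factory=dict)
    #: common correlation among latent phenotype drivers (optional, default none)
    phenotype_correlation: float = 0.0

    def __post_init__(self):
        if self.n_subjects < self.n_strata * self.psus_per_stratum:
            raise ConfigError("n_subjects must be >= n_strata * psus_per_stratum")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ConfigError("weights must be strictly positive with min <= max")
        f1, f2 = self.batch_fractions
        if not (0 < f1 < 1 and 0 < f2 < 1 and abs(f1 + f2 - 1) < 1e-9):
            raise ConfigError("batch_fractions must lie in (0,1) and sum to 1")
        if not (0 <= self.phenotype_correlation < 1):
            raise ConfigError("phenotype_correlation must be in [0, 1)")


@dataclass(frozen=True)
class PhenotypeSpec:
    """A sleep phenotype: name, domain, measurement scale, generator params.

    ``generation_params``: mean/sd for continuous, prevalence for binary,
    mean_time (hours on the 24 h clock) and concentration for circular.
    """

    name: str
    domain: str
    scale: str
    generation_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ConfigError(f"unknown domain {self.domain!r}")
        if self.scale not in SCALES:
            raise ConfigError(f"unknown scale {self.scale!r}")
        if self.domain == "Timing" and self.scale != "circular":
            raise ConfigError("Timing-domain phenotypes must be circular")
        if self.scale == "binary":
            prev = self.generation_params.get("prevalence", 0.5)
            if not 0 < prev < 1:
                raise ConfigError("binary prevalence must lie in (0,1)")


@dataclass(frozen=True)
class EffectSpec:
    """A planted phenotype -> metabolite effect of known size.

    ``linear_slope``: latent shifts by ``slope`` (in metabolite-SD units) per
    standardized unit of the exposure.  ``circular_sinusoid``: latent shifts by
    ``amplitude * cos(angle - acrophase)``.
    """

    phenotype: str
    metabolite: str
    effect_type: str = "linear_slope"
    slope: float = 0.0
    amplitude: float = 0.0
    acrophase: float = 0.0

    def __post_init__(self):
        if self.effect_type not in ("linear_slope", "circular_sinusoid"):
            raise ConfigError(f"unknown effect_type {self.effect_type!r}")
        if self.effect_type == "circular_sinusoid":
            if self.amplitude < 0:
                raise ConfigError("amplitude must be >= 0")
            if not 0 <= self.acrophase < 2 * math.pi:
                raise ConfigError("acrophase must lie in [0, 2*pi)")


@dataclass(frozen=True)
class MetaboliteGenSpec:
    """A metabolite's annotation and its missingness mechanism.

    Exactly one mechanism applies: xenobiotics are left-censored below the
    ``detection_limit_quantile`` of their abundance distribution; endogenous
    metabolites drop out at ``missing_rate`` on average, with log-odds tilted
    by ``missingness_covariate_slope`` times standardized BMI (MAR).
    """

    name: str
    superpathway: str = "Lipid"
    subpathway: str = "Unassigned"
    xenobiotic: bool = False
    detection_limit_quantile: float = 0.0
    missing_rate: float = 0.0
    missingness_covariate_slope: float = 0.0

    def __post_init__(self):
        if self.xenobiotic:
            if not 0 <= self.detection_limit_quantile <= 0.95:
                raise ConfigError("detection_limit_quantile must lie in [0, 0.95]")
        else:
            if not 0 <= self.missing_rate <= 0.95:
                raise ConfigError("missing_rate must lie in [0, 0.95]")


def circular_phenotype_draw(mean_time: float, concentration: float, n: int, seed=None):
    """Draw ``n`` clock-times (hours in [0, 24)) around ``mean_time``.

    Uses a von Mises distribution on the 24 h circle; ``concentration=0``
    yields uniform clock-times.  ``seed`` may be an int or a Generator.
    """
    if concentration < 0:
        raise ConfigError("concentration must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n == 0:
        return np.empty(0)
    mu = 2 * np.pi * (mean_time % 24.0) / 24.0
    if concentration == 0:
        ang = rng.uniform(0, 2 * np.pi, size=n)
    else:
        ang = rng.vonmises(mu, concentration, size=n)
    return (ang % (2 * np.pi)) * 24.0 / (2 * np.pi)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _mar_threshold(eta: np.ndarray, rate: float) -> float:
    """Intercept alpha with mean(sigmoid(alpha + eta)) == rate on this sample."""
    from scipy.optimize import brentq

    if rate <= 0:
        return -np.inf
    f = lambda a: np.mean(1.0 / (1.0 + np.exp(-(a + eta)))) - rate
    return brentq(f, -40, 40)


def generate_cohort(
    config: CohortConfig,
    phenotypes: list[PhenotypeSpec],
    metabolites: list[MetaboliteGenSpec],
    effects: list[EffectSpec] = (),
):
    """Generate (subject table, metabolite table, annotation, truth table).

    Identical ``config.seed`` gives bit-identical output.  Returns
    ``(subjects, metab, annotation, truth)`` as pandas DataFrames; ``metab``
    holds subject_id, batch and one abundance column per metabolite (NaN =
    missing).
    """
    pnames = [p.name for p in phenotypes]
    mnames = [m.name for m in metabolites]
    if len(set(pnames)) != len(pnames) or len(set(mnames)) != len(mnames):
        raise ConfigError("phenotype and metabolite names must be unique")
    pheno_by_name = {p.name: p for p in phenotypes}
    for e in effects:
        if e.phenotype not in pheno_by_name:
            raise ConfigError(f"effect references unknown phenotype {e.phenotype!r}")
        if e.metabolite not in set(mnames):
            raise ConfigError(f"effect references unknown metabolite {e.metabolite!r}")
        if e.effect_type == "circular_sinusoid" and pheno_by_name[e.phenotype].scale != "circular":
            raise ConfigError("circular_sinusoid effects require a circular phenotype")
        if e.effect_type == "linear_slope" and pheno_by_name[e.phenotype].scale == "circular":
            raise ConfigError("linear_slope effects require a non-circular phenotype")

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # --- design: strata, PSUs, weights, batch ---------------------------------
    n_psu_total = config.n_strata * config.psus_per_stratum
    psu_idx = np.concatenate([np.arange(n_psu_total), rng.integers(0, n_psu_total, n - n_psu_total)])
    rng.shuffle(psu_idx)
    stratum = psu_idx // config.psus_per_stratum + 1
    lo, hi = config.weight_range
    weight = rng.uniform(lo, hi, size=n)
    batch = np.where(rng.uniform(size=n) < config.batch_fractions[0], 1, 2)

    # --- covariates ------------------------------------------------------------
    shifts = dict(config.batch2_covariate_shifts)
    age = rng.normal(45.0, 13.0, n) + np.where(batch == 2, shifts.get("age", 0.0), 0.0)
    age = np.clip(age, 18, 90)
    sex = rng.binomial(1, 0.5, n)  # 1 = female
    center = rng.choice(CENTERS, size=n)
    background = rng.choice(BACKGROUNDS, size=n)
    bmi = rng.normal(29.0, 5.0, n) + np.where(batch == 2, shifts.get("bmi", 0.0), 0.0)
    bmi = np.clip(bmi, 16, 55)
    alcohol = rng.choice(THREE_LEVEL, size=n, p=[0.25, 0.3, 0.45])
    smoking = rng.choice(THREE_LEVEL, size=n, p=[0.6, 0.2, 0.2])
    physical_activity = rng.lognormal(5.0, 0.8, n)
    diet_score = rng.normal(48.0, 8.0, n)
    glucose = rng.normal(100.0, 20.0, n) + 0.8 * (bmi - bmi.mean())
    insulin = rng.lognormal(2.3, 0.5, n)
    egfr = np.clip(rng.normal(95.0, 15.0, n) - 0.5 * (age - age.mean()), 15, 150)
    triglycerides = rng.lognormal(4.7, 0.5, n)

    if config.informative_weight_slope != 0.0:
        weight = weight * np.exp(config.informative_weight_slope * _standardize(age))

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "stratum": stratum,
            "psu": psu_idx + 1,
            "weight": weight,
            "batch": batch,
            "age": age,
            "sex": sex,
            "center": center,
            "background": background,
            "bmi": bmi,
            "alcohol": alcohol,
            "smoking": smoking,
            "physical_activity": physical_activity,
            "diet_score": diet_score,
            "glucose": glucose,
            "insulin": insulin,
            "egfr": egfr,
            "triglycerides": triglycerides,
        }
    )

    # --- phenotypes ------------------------------------------------------------
    rho = config.phenotype_correlation
    shared = rng.normal(size=n)
    for p in phenotypes:
        gp = p.generation_params
        if p.scale == "circular":
            vals = circular_phenotype_draw(
                gp.get("mean_time", 23.0), gp.get("concentration", 3.0), n, seed=rng
            )
        else:
            z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.normal(size=n)
            if p.scale == "continuous":
                vals = gp.get("mean", 0.0) + gp.get("sd", 1.0) * z
            else:  # binary
                prev = gp.get("prevalence", 0.5)
                from scipy.stats import norm

                vals = (z < norm.ppf(prev)).astype(int)
        subjects[p.name] = vals

    # --- metabolites: latents + planted effects, exponentiate, censor ----------
    effects_by_met: dict[str, list[EffectSpec]] = {}
    for e in effects:
        effects_by_met.setdefault(e.metabolite, []).append(e)

    bmi_z = _standardize(bmi)
    metab = pd.DataFrame({"subject_id": subjects["subject_id"], "batch": batch})
    truth_rows = []
    for m in metabolites:
        latent = rng.normal(size=n)
        for e in effects_by_met.get(m.name, []):
            ph = subjects[e.phenotype].to_numpy(dtype=float)
            if e.effect_type == "linear_slope":
                latent = latent + e.slope * _standardize(ph)
            else:
                ang = 2 * np.pi * ph / 24.0
                latent = latent + e.amplitude * np.cos(ang - e.acrophase)
            truth_rows.append(
                {
                    "phenotype": e.phenotype,
                    "metabolite": e.metabolite,
                    "effect_type": e.effect_type,
                    "slope": e.slope,
                    "amplitude": e.amplitude,
                    "acrophase": e.acrophase,
                }
            )
        abundance = np.exp(latent)
        if m.xenobiotic:
            q = m.detection_limit_quantile
            if q > 0:
                lod = np.quantile(abundance, q)
                abundance = np.where(abundance < lod, np.nan, abundance)
        else:
            if m.missing_rate > 0:
                eta = m.missingness_covariate_slope * bmi_z
                alpha = _mar_threshold(eta, m.missing_rate)
                pmiss = 1.0 / (1.0 + np.exp(-(alpha + eta)))
                abundance = np.where(rng.uniform(size=n) < pmiss, np.nan, abundance)
        metab[m.name] = abundance

    annotation = pd.DataFrame(
        {
            "metabolite": mnames,
            "superpathway": [m.superpathway for m in metabolites],
            "subpathway": [m.subpathway for m in metabolites],
            "xenobiotic": [int(m.xenobiotic) for m in metabolites],
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["phenotype", "metabolite", "effect_type", "slope", "amplitude", "acrophase"],
    )
    return subjects, metab, annotation, truth


# ---------------------------------------------------------------------------
# Ready-made study-shaped registries (modest desk-scale defaults)
# ---------------------------------------------------------------------------

def example_phenotypes() -> list[PhenotypeSpec]:
    """Ten phenotypes spanning the five sleep domains and all three scales."""
    return [
        PhenotypeSpec("sleep_duration_avg", "Duration", "continuous", {"mean": 8.0, "sd": 1.5}),
        PhenotypeSpec("short_sleep", "Duration", "binary", {"prevalence": 0.25}),
        PhenotypeSpec("hr_mean_sleep", "HR", "continuous", {"mean": 62.0, "sd": 8.0}),
        PhenotypeSpec("hr_sd_sleep", "HR", "continuous", {"mean": 5.0, "sd": 2.0}),
        PhenotypeSpec("whiirs", "Insomnia", "continuous", {"mean": 7.0, "sd": 4.0}),
        PhenotypeSpec("sleeping_pills", "Insomnia", "binary", {"prevalence": 0.12}),
        PhenotypeSpec("rei", "SDB", "continuous", {"mean": 8.0, "sd": 10.0}),
        PhenotypeSpec("snoring", "SDB", "binary", {"prevalence": 0.35}),
        PhenotypeSpec("bedtime", "Timing", "circular", {"mean_time": 23.25, "concentration": 3.0}),
        PhenotypeSpec("sleep_midpoint", "Timing", "circular", {"mean_time": 3.0, "concentration": 2.5}),
    ]


def example_metabolites(n_metab: int = 40, xenobiotic_fraction: float = 0.1, seed: int = 0):
    """A small annotated metabolite panel with both missingness mechanisms."""
    rng = np.random.default_rng(seed)
    supers = ["Lipid", "Amino Acid", "Carbohydrate", "Cofactors and Vitamins", "Xenobiotics"]
    subs = {
        "Lipid": ["Sphingomyelins", "Primary Bile Acid Metabolism", "Lysophospholipid"],
        "Amino Acid": ["BCAA Metabolism", "Glycine Metabolism"],
        "Carbohydrate": ["Glycolysis", "Amino Sugar Metabolism"],
        "Cofactors and Vitamins": ["Nicotinate Metabolism", "Pantothenate Metabolism"],
        "Xenobiotics": ["Food Component", "Drug"],
    }
    out = []
    n_xeno = max(1, int(round(xenobiotic_fraction * n_metab)))
    for i in range(n_metab):
        xeno = i < n_xeno
        sp = "Xenobiotics" if xeno else supers[i % 4]
        sub = subs[sp][i % len(subs[sp])]
        if xeno:
            out.append(
                MetaboliteGenSpec(
                    name=f"met{i:03d}",
                    superpathway=sp,
                    subpathway=sub,
                    xenobiotic=True,
                    detection_limit_quantile=float(rng.uniform(0.05, 0.4)),
                )
            )
        else:
            out.append(
                MetaboliteGenSpec(
                    name=f"met{i:03d}",
                    superpathway=sp,
                    subpathway=sub,
                    xenobiotic=False,
                    missing_rate=float(rng.uniform(0.0, 0.25)),
                    missingness_covariate_slope=0.7,
                )
            )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_tables(outdir, subjects, metab, annotation, truth) -> dict:
    """Write the four generated tables as tab-delimited text; return paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    subjects.to_csv(paths["subjects"], sep="\t", index=False)
    metab.to_csv(paths["metabolites"], sep="\t", index=False)
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def load_generation_config(path):
    """Read a YAML generation config into typed specs.

    Expected keys: ``cohort`` (CohortConfig fields), ``phenotypes``,
    ``metabolites``, ``effects`` (lists of the corresponding spec fields).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohort_kwargs = dict(raw.get("cohort", {}))
    for key in ("weight_range", "batch_fractions"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    config = CohortConfig(**cohort_kwargs)
    phenotypes = [PhenotypeSpec(**p) for p in raw.get("phenotypes", [])] or example_phenotypes()
    mets = [MetaboliteGenSpec(**m) for m in raw.get("metabolites", [])] or example_metabolites()
    effects = [EffectSpec(**e) for e in raw.get("effects", [])]
    return config, phenotypes, mets, effects
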