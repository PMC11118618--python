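"""Phenotype x metabolite association scan across multiply-imputed datasets.

Each metabolite (already rank-normalized) is regressed, as the outcome, on a
sleep phenotype plus model covariates under the survey design:

* linear/binary phenotypes enter as a single predictor; the per-imputation
  coefficients are pooled by Rubin's rules with a Barnard–Rubin adjusted
  t reference;
* circular (clock-time) phenotypes are encoded as the sine and cosine of
  their angle (midnight = 0 radians) and tested with a 2-df multivariate Wald
  test per imputation; because the sine/cosine coefficient covariance cannot
  be pooled across imputations, the m Wald p-values are aggregated with the
  Cauchy combination test (ACAT), which tolerates dependence between the
  component tests.

Raw p-values are then Benjamini–Hochberg adjusted within each phenotype,
across all metabolites and both covariate models jointly; an FDR-adjusted
p < alpha under Model 1 defines a significant association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design_glm import SurveyDesign, fit_weighted_lm, wald_test
from .preprocess import HALF_MIN, ImputationSet, metabolite_columns
from .synthetic_cohort import MODEL1_COVARIATES, MODEL2_COVARIATES

P_CLAMP = 1e-15

MODEL_COVARIATES = {"Model1": MODEL1_COVARIATES, "Model2": MODEL2_COVARIATES}

RESULT_COLUMNS = [
    "phenotype",
    "domain",
    "metabolite",
    "superpathway",
    "subpathway",
    "model",
    "effect",
    "test_df",
    "p_raw",
    "p_fdr",
    "significant",
]


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# circular encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularEncoding:
    """Clock time as an angle on the 24 h circle (midnight maps to 0)."""

    angle: float
    sin_term: float
    cos_term: float


def encode_circular(clock_time) -> CircularEncoding | tuple:
    """Encode clock-time hours in [0, 24) as (angle, sin, cos).

    ``angle = 2*pi * minutes_since_midnight / 1440``; vector input returns a
    tuple of arrays ``(angle, sin, cos)``.
    """
    t = np.asarray(clock_time, dtype=float)
    if np.any(t < 0) or np.any(t >= 24):
        raise AssociationError("clock time must lie in [00:00, 24:00)")
    angle = 2 * np.pi * t / 24.0
    if t.ndim == 0:
        a = float(angle)
        return CircularEncoding(angle=a, sin_term=math.sin(a), cos_term=math.cos(a))
    return angle, np.sin(angle), np.cos(angle)


# ---------------------------------------------------------------------------
# Rubin pooling and ACAT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledEstimate:
    m: int
    beta_bar: float
    W_bar: float
    B: float
    T: float
    df_adj: float
    p: float

    @property
    def se(self) -> float:
        return math.sqrt(self.T)


def rubin_pool(betas, variances, complete_df: float) -> PooledEstimate:
    """Pool m point estimates and variances by Rubin's rules.

    Total variance ``T = W_bar + (1 + 1/m) B``; the reference is a t
    distribution with the Barnard–Rubin small-sample degrees of freedom,
    capped at ``complete_df`` (here, the survey design df).  ``m = 1``
    returns the single-imputation Wald result unchanged.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if b.shape != v.shape or b.ndim != 1 or b.size < 1:
        raise AssociationError("betas and variances must be equal-length vectors, m >= 1")
    if np.any(v <= 0):
        raise AssociationError("variances must be strictly positive")
    m = b.size
    beta_bar = float(b.mean())
    W = float(v.mean())
    if m == 1:
        B = 0.0
        T = W
        df = float(complete_df)
    else:
        B = float(b.var(ddof=1))
        T = W + (1 + 1 / m) * B
        if B == 0.0:
            df = float(complete_df)
        else:
            lam = (1 + 1 / m) * B / T
            df_old = (m - 1) / lam**2
            df_obs = (complete_df + 1) / (complete_df + 3) * complete_df * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        df = min(df, float(complete_df))
    tstat = beta_bar / math.sqrt(T)
    p = float(2 * stats.t.sf(abs(tstat), df))
    return PooledEstimate(m=m, beta_bar=beta_bar, W_bar=W, B=B, T=T, df_adj=df, p=p)


def acat_combine(p_values, weights=None) -> float:
    """Cauchy combination (ACAT) of possibly dependent p-values.

    ``T = sum_i w_i tan((0.5 - p_i) * pi)``, combined ``p = 0.5 - arctan(T)/pi``.
    Inputs are clamped to ``[1e-15, 1 - 1e-15]``; for extremely small
    components the tangent is replaced by its asymptote ``1/(p*pi)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise AssociationError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AssociationError("p-values must lie in [0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w < 0):
            raise AssociationError("weights must be nonnegative and match p_values")
        s = w.sum()
        if s <= 0:
            raise AssociationError("weights must not all be zero")
        w = w / s
    small = p < P_CLAMP
    pc = np.clip(p, P_CLAMP, 1 - P_CLAMP)
    # tan((0.5 - p) pi) == cot(p pi); reflect p > 1/2 so the argument stays in
    # (0, pi/2] where cot is well conditioned (1 - p is exact for p >= 1/2)
    q = np.where(pc <= 0.5, pc, 1.0 - pc)
    cot = np.cos(q * np.pi) / np.sin(q * np.pi)
    terms = np.where(pc <= 0.5, cot, -cot)
    terms[small] = 1.0 / (p[small].clip(min=1e-300) * np.pi)
    T = float(np.sum(w * terms))
    if T > 0:
        # 0.5 - atan(T)/pi == atan(1/T)/pi, without cancellation for large T
        combined = math.atan(1.0 / T) / math.pi
    else:
        combined = 0.5 - math.atan(T) / math.pi
    return float(min(max(combined, 0.0), 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise AssociationError("empty p-value group")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def build_design_matrix(subjects: pd.DataFrame, terms: list[str]):
    """Numeric model matrix with intercept; categoricals dummy-coded.

    Object/category columns (and ``batch``) are expanded into treatment
    (drop-first) indicator columns named ``col[level]``.
    """
    pieces = [pd.Series(1.0, index=subjects.index, name="(Intercept)")]
    for term in terms:
        if term not in subjects.columns:
            raise AssociationError(f"covariate {term!r} missing from subject table")
        col = subjects[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or term == "batch":
            dummies = pd.get_dummies(col.astype(str), prefix=term, prefix_sep="[", drop_first=True)
            dummies.columns = [c + "]" for c in dummies.columns]
            # empty levels are dropped implicitly (only observed levels emitted)
            pieces.append(dummies.astype(float))
        else:
            if col.nunique(dropna=False) <= 1:
                continue  # constant covariate (e.g. sex within a sex subgroup)
            pieces.append(col.astype(float))
    X = pd.concat(pieces, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def _design_from_subjects(subjects: pd.DataFrame) -> SurveyDesign:
    return SurveyDesign(
        subjects["stratum"].to_numpy(), subjects["psu"].to_numpy(), subjects["weight"].to_numpy()
    )


# ---------------------------------------------------------------------------
# single-pair tests
# ---------------------------------------------------------------------------

def _datasets_for(metabolite: str, imp: ImputationSet) -> list:
    """The per-imputation outcome columns; xenobiotics collapse to one copy."""
    if imp.method_tag.get(metabolite) == HALF_MIN:
        return [imp.datasets[0]]
    return imp.datasets


def test_linear(phenotype, metabolite, imp, subjects, design, model, covariates=None):
    """Pooled survey-weighted association of one metabolite with a linear or
    binary phenotype; returns a pre-FDR record dict."""
    covariates = MODEL_COVARIATES[model] if covariates is None else covariates
    ph = subjects[phenotype].to_numpy(dtype=float)
    if np.all(ph == ph[0]):
        raise AssociationError(f"phenotype {phenotype!r} is constant in this sample")
    Xcov, names = build_design_matrix(subjects, covariates)
    X = np.column_stack([Xcov[:, :1], ph, Xcov[:, 1:]])
    names = [names[0], phenotype] + names[1:]
    betas, variances = [], []
    for d in _datasets_for(metabolite, imp):
        y = d[metabolite].to_numpy(dtype=float)
        fit = fit_weighted_lm(y, X, design, names=names, model_label=model)
        betas.append(fit.beta[1])
        variances.append(fit.vcov[1, 1])
    pooled = rubin_pool(betas, variances, complete_df=design.design_df)
    return {
        "phenotype": phenotype,
        "metabolite": metabolite,
        "model": model,
        "effect": pooled.beta_bar,
        "test_df": 1,
        "p_raw": pooled.p,
        "pooled": pooled,
    }


def test_circular(phenotype, metabolite, imp, subjects, design, model, covariates=None):
    """ACAT-combined 2-df Wald test of a circular phenotype (sin + cos terms)."""
    covariates = MODEL_COVARIATES[model] if covariates is None else covariates
    ph = subjects[phenotype].to_numpy(dtype=float)
    if np.all(ph == ph[0]):
        raise AssociationError(f"circular phenotype {phenotype!r} has zero circular variance")
    _, s, c = encode_circular(ph)
    Xcov, names = build_design_matrix(subjects, covariates)
    X = np.column_stack([Xcov[:, :1], s, c, Xcov[:, 1:]])
    names = [names[0], f"{phenotype}:sin", f"{phenotype}:cos"] + names[1:]
    pvals = []
    for d in _datasets_for(metabolite, imp):
        y = d[metabolite].to_numpy(dtype=float)
        fit = fit_weighted_lm(y, X, design, names=names, model_label=model)
        pvals.append(wald_test(fit, [1, 2]).p)
    return {
        "phenotype": phenotype,
        "metabolite": metabolite,
        "model": model,
        "effect": np.nan,
        "test_df": 2,
        "p_raw": acat_combine(pvals),
    }


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def run_scan(
    subjects: pd.DataFrame,
    imp: ImputationSet,
    phenotypes,
    annotation: pd.DataFrame,
    models=("Model1", "Model2"),
    subgroup=None,
    alpha: float = 0.05,
    model_covariates: dict | None = None,
    fdr_per_model: bool = False,
) -> pd.DataFrame:
    """One record per (phenotype, metabolite, model), FDR-adjusted per phenotype.

    ``subgroup`` is an optional boolean mask or ``(column, value)`` pair (e.g.
    ``("sex", 1)``) restricting the scan to a subpopulation, with the survey
    design subset accordingly.  By default the BH adjustment pools each
    phenotype's p-values across all metabolites and all requested models, and
    a record is flagged significant iff its Model-1 FDR-adjusted p is below
    ``alpha``.  ``fdr_per_model=True`` switches to per-model grouping.
    """
    model_covariates = dict(MODEL_COVARIATES) if model_covariates is None else model_covariates
    for mod in models:
        for cov in model_covariates[mod]:
            if cov not in subjects.columns:
                raise AssociationError(f"model {mod} covariate {cov!r} missing from subjects")

    # align subject rows with the completed datasets (batch aggregation may
    # have reordered rows relative to the raw subject table)
    ids = imp.datasets[0]["subject_id"]
    if not ids.equals(subjects["subject_id"]):
        subjects = subjects.set_index("subject_id").loc[ids].reset_index()

    if subgroup is not None:
        if isinstance(subgroup, tuple):
            colname, value = subgroup
            mask = (subjects[colname] == value).to_numpy()
        else:
            mask = np.asarray(subgroup, dtype=bool)
        subjects = subjects.loc[mask].reset_index(drop=True)
        imp = ImputationSet(
            m=imp.m,
            datasets=[d.loc[mask].reset_index(drop=True) for d in imp.datasets],
            method_tag=dict(imp.method_tag),
        )
    design = _design_from_subjects(subjects)

    mets = metabolite_columns(imp.datasets[0])
    ann = annotation.set_index("metabolite")
    rows = []
    for spec in phenotypes:
        tester = test_circular if spec.scale == "circular" else test_linear
        for model in models:
            cov = model_covariates[model]
            for met in mets:
                rec = tester(spec.name, met, imp, subjects, design, model, covariates=cov)
                rec["domain"] = spec.domain
                rec["superpathway"] = ann.loc[met, "superpathway"] if met in ann.index else ""
                rec["subpathway"] = ann.loc[met, "subpathway"] if met in ann.index else ""
                rec.pop("pooled", None)
                rows.append(rec)
    results = pd.DataFrame(rows)

    # FDR within phenotype, across metabolites (x models unless per-model)
    group_cols = ["phenotype", "model"] if fdr_per_model else ["phenotype"]
    results["p_fdr"] = np.nan
    for _, idx in results.groupby(group_cols).groups.items():
        results.loc[idx, "p_fdr"] = bh_fdr(results.loc[idx, "p_raw"].to_numpy())
    results["significant"] = (results["model"] == "Model1") & (results["p_fdr"] < alpha)
    return results[RESULT_COLUMNS]


def write_results(results: pd.DataFrame, path, jsonl_path=None) -> None:
    """Emit the association table as TSV and optionally JSON-lines."""
    results.to_csv(path, sep="\t", index=False)
    if jsonl_path is not None:
        results.to_json(jsonl_path, orient="records", lines=True)
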