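"""Metabolite QC and imputation pipeline.

Policy, applied in this order:

1. drop any metabolite whose missing proportion exceeds a threshold
   (default 75%) in *either* batch;
2. xenobiotic metabolites: fill missing values with half the lowest observed
   value of that metabolite within the batch (left-censoring at the detection
   limit);
3. endogenous (non-xenobiotic) metabolites: fully conditional multiple
   imputation by predictive mean matching, run separately per batch, giving
   ``m`` completed datasets;
4. rank-based inverse-normal transform of every metabolite, within each batch
   and each completed dataset separately;
5. aggregate batches by pairing the i-th completed dataset of each batch.

The imputation here is a self-contained fully-conditional-specification
sampler with predictive mean matching (each missing value is replaced by the
observed value of a randomly chosen donor among the ``k`` nearest by linear
predictor), written in-package so that seeding, donor-pool size and sweep
count are explicit and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

ID_COLUMNS = ("subject_id", "batch")

HALF_MIN = "half_min"
MULTIPLE_IMPUTATION = "multiple_imputation"


class PreprocessError(ValueError):
    pass


def metabolite_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def validate_metabolite_table(table: pd.DataFrame) -> None:
    """Check the abundance-table contract: one batch per subject, values >= 0."""
    for col in ID_COLUMNS:
        if col not in table.columns:
            raise PreprocessError(f"metabolite table lacks required column {col!r}")
    per_subject = table.groupby("subject_id")["batch"].nunique()
    if (per_subject > 1).any():
        raise PreprocessError("a subject appears in more than one batch")
    vals = table[metabolite_columns(table)].to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size and observed.min() < 0:
        raise PreprocessError("abundances must be nonnegative where observed")


@dataclass
class ImputationSet:
    """``m`` completed metabolite tables plus per-metabolite method tags."""

    m: int
    datasets: list  # list of DataFrames, identical shape and columns
    method_tag: dict = field(default_factory=dict)  # metabolite -> method

    def __post_init__(self):
        if self.m != len(self.datasets):
            raise PreprocessError("m must equal the number of completed datasets")
        cols = list(self.datasets[0].columns)
        for d in self.datasets[1:]:
            if list(d.columns) != cols:
                raise PreprocessError("completed datasets must share identical columns")
        for d in self.datasets:
            if d[metabolite_columns(d)].isna().any().any():
                raise PreprocessError("completed datasets must contain no missing values")

    def write(self, outdir) -> dict:
        """Serialize as ``m`` parallel TSV files plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, d in enumerate(self.datasets, start=1):
            p = outdir / f"imputed_{i}.tsv"
            d.to_csv(p, sep="\t", index=False)
            paths.append(p.name)
        manifest = {"m": self.m, "datasets": paths, "method_tag": self.method_tag}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest

    @classmethod
    def read(cls, outdir) -> "ImputationSet":
        outdir = Path(outdir)
        with open(outdir / "manifest.json") as fh:
            manifest = json.load(fh)
        datasets = [pd.read_csv(outdir / p, sep="\t") for p in manifest["datasets"]]
        return cls(m=manifest["m"], datasets=datasets, method_tag=manifest["method_tag"])


def filter_missingness(table: pd.DataFrame, threshold: float = 0.75):
    """Drop metabolites missing in more than ``threshold`` of either batch.

    The rule is strict: a metabolite missing in exactly ``threshold`` of both
    batches is retained.  Returns the filtered table and an exclusion list of
    ``(metabolite, batch, missing_proportion)`` records.
    """
    if not 0 < threshold <= 1:
        raise PreprocessError("threshold must lie in (0, 1]")
    mets = metabolite_columns(table)
    excluded = []
    drop = set()
    for b, grp in table.groupby("batch"):
        if len(grp) == 0:
            raise PreprocessError(f"batch {b} is empty")
        miss = grp[mets].isna().mean()
        for met, frac in miss.items():
            if frac > threshold:
                drop.add(met)
                excluded.append({"metabolite": met, "batch": b, "missing": float(frac)})
    kept = table.drop(columns=sorted(drop))
    return kept, excluded


def impute_half_min(table: pd.DataFrame, xenobiotic_ids) -> pd.DataFrame:
    """Fill missing xenobiotic values with half the batch minimum observed.

    Applied within each batch independently; observed values are untouched.
    """
    out = table.copy()
    for met in xenobiotic_ids:
        if met not in out.columns:
            continue
        for b, idx in out.groupby("batch").groups.items():
            col = out.loc[idx, met]
            if col.notna().sum() == 0:
                raise PreprocessError(
                    f"xenobiotic {met!r} fully missing in batch {b}; should have been filtered"
                )
            fill = 0.5 * col.min()
            out.loc[idx, met] = col.fillna(fill)
    return out


def _fcs_pmm_single_batch(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    m: int,
    n_iter: int,
    k: int,
    seed,
) -> list:
    """FCS with predictive mean matching on one batch; returns m completions."""
    if covariates.isna().any().any():
        raise PreprocessError(
            "imputation covariates contain missing values; include them in the "
            "iteration scheme or complete them upstream"
        )
    mets = list(values.columns)
    V = values.to_numpy(dtype=float)
    C = covariates.to_numpy(dtype=float)
    miss_mask = np.isnan(V)
    needs = [j for j in range(V.shape[1]) if miss_mask[:, j].any()]
    if not needs:
        return [values.copy() for _ in range(m)]

    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(m)]
    completions = []
    for rng in streams:
        X = V.copy()
        # initialize by random draws from each variable's observed support
        for j in needs:
            obs = X[~miss_mask[:, j], j]
            X[miss_mask[:, j], j] = rng.choice(obs, size=miss_mask[:, j].sum())
        for _ in range(n_iter):
            for j in needs:
                others = [c for c in range(X.shape[1]) if c != j]
                P = np.column_stack([np.ones(X.shape[0]), C, X[:, others]])
                obs_rows = ~miss_mask[:, j]
                Po, yo = P[obs_rows], X[obs_rows, j]
                beta, *_ = np.linalg.lstsq(Po, yo, rcond=None)
                # proper imputation: draw (sigma^2, beta) from their
                # approximate posterior; match missing cases (predicted with
                # the drawn beta) to observed cases (predicted with beta-hat)
                resid = yo - Po @ beta
                dof = max(len(yo) - P.shape[1], 1)
                sigma2 = resid @ resid / rng.chisquare(dof)
                PtP = Po.T @ Po
                PtP.flat[:: PtP.shape[0] + 1] += 1e-8 * max(np.trace(PtP), 1.0) / PtP.shape[0]
                L = np.linalg.cholesky(np.linalg.inv(PtP))
                beta_star = beta + np.sqrt(sigma2) * (L @ rng.standard_normal(P.shape[1]))
                obs_pred = Po @ beta
                miss_pred = P[miss_mask[:, j]] @ beta_star
                for row, pi in zip(np.flatnonzero(miss_mask[:, j]), miss_pred):
                    dist = np.abs(obs_pred - pi)
                    pool = np.argsort(dist, kind="stable")[: min(k, len(dist))]
                    X[row, j] = yo[pool[rng.integers(0, len(pool))]]
        completions.append(pd.DataFrame(X, columns=mets, index=values.index))
    return completions


def impute_fcs(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    m: int = 5,
    n_iter: int = 10,
    k: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Multiply impute non-xenobiotic metabolites, separately per batch.

    ``covariates`` is indexed like ``table`` and must be fully observed and
    numeric (encode categoricals upstream).  Every imputed value is an
    observed value of its variable (predictive mean matching with a
    ``k``-nearest donor pool); the ``m`` completions use independent random
    streams spawned from ``seed``.
    """
    mets = metabolite_columns(table)
    completions_by_batch = {}
    for b, grp in table.groupby("batch"):
        cov_b = covariates.loc[grp.index]
        completions_by_batch[b] = _fcs_pmm_single_batch(
            grp[mets], cov_b, m=m, n_iter=n_iter, k=k, seed=(seed, int(b))
        )
    datasets = []
    for i in range(m):
        filled = table.copy()
        for b, grp in table.groupby("batch"):
            filled.loc[grp.index, mets] = completions_by_batch[b][i]
        datasets.append(filled)
    tags = {met: MULTIPLE_IMPUTATION for met in mets}
    return ImputationSet(m=m, datasets=datasets, method_tag=tags)


def rank_inverse_normal(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with offset ``c`` (Blom default).

    Maps value of rank ``r`` among ``n`` to ``Phi^{-1}((r - c) / (n - 2c + 1))``;
    ties receive average ranks.  A constant vector is an error (the transform
    is undefined up to sign).
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise PreprocessError("rank normalization requires complete data")
    if x.size and np.all(x == x[0]):
        raise PreprocessError("constant vector cannot be rank normalized")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - c) / (x.size - 2 * c + 1))


def rank_normalize_set(imp: ImputationSet, c: float = 3.0 / 8.0) -> ImputationSet:
    """Rank-normalize every metabolite within each batch of each dataset."""
    out = []
    for d in imp.datasets:
        d = d.copy()
        for _, idx in d.groupby("batch").groups.items():
            for met in metabolite_columns(d):
                d.loc[idx, met] = rank_inverse_normal(d.loc[idx, met], c=c)
        out.append(d)
    return ImputationSet(m=imp.m, datasets=out, method_tag=dict(imp.method_tag))


def aggregate_batches(sets_by_batch: dict) -> ImputationSet:
    """Row-concatenate the i-th dataset of every batch, for each i."""
    sets = list(sets_by_batch.values())
    if not sets:
        raise PreprocessError("no batches to aggregate")
    m = sets[0].m
    cols = list(sets[0].datasets[0].columns)
    for s in sets[1:]:
        if s.m != m:
            raise PreprocessError("all batches must share the same m")
        if list(s.datasets[0].columns) != cols:
            raise PreprocessError("column sets/order differ between batches; no silent reorder")
    tags = dict(sets[0].method_tag)
    for s in sets[1:]:
        tags.update(s.method_tag)
    datasets = [
        pd.concat([s.datasets[i] for s in sets], axis=0, ignore_index=True) for i in range(m)
    ]
    return ImputationSet(m=m, datasets=datasets, method_tag=tags)


def preprocess_pipeline(
    table: pd.DataFrame,
    annotation: pd.DataFrame,
    covariates: pd.DataFrame,
    m: int = 5,
    n_iter: int = 10,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.75,
    rank_offset: float = 3.0 / 8.0,
):
    """Run the full policy: filter -> half-min -> FCS -> rank-normalize -> aggregate.

    Returns ``(ImputationSet, log)`` where the aggregated set pairs the i-th
    completion of every batch and ``log`` records stage counts.  The input
    must be a raw (nonnegative) abundance table; feeding already
    rank-normalized data raises, as the pipeline is not idempotent.
    """
    validate_metabolite_table(table)  # rejects negatives, i.e. re-processing

    filtered, excluded = filter_missingness(table, threshold=threshold)
    mets = metabolite_columns(filtered)
    xeno = set(annotation.loc[annotation["xenobiotic"].astype(bool), "metabolite"]) & set(mets)
    endo = [c for c in mets if c not in xeno]

    half = impute_half_min(filtered, sorted(xeno))

    sets_by_batch = {}
    for b, grp in half.groupby("batch"):
        endo_tbl = grp[list(ID_COLUMNS) + endo]
        cov_b = covariates.loc[grp.index]
        imp = impute_fcs(endo_tbl, cov_b, m=m, n_iter=n_iter, k=k, seed=seed)
        # reattach the (single-imputation) xenobiotic columns in original order
        datasets = []
        for d in imp.datasets:
            full = grp.copy()
            full.loc[:, endo] = d[endo].to_numpy()
            datasets.append(full.reset_index(drop=True))
        tags = {met: (HALF_MIN if met in xeno else MULTIPLE_IMPUTATION) for met in mets}
        batch_set = ImputationSet(m=m, datasets=datasets, method_tag=tags)
        sets_by_batch[b] = rank_normalize_set(batch_set, c=rank_offset)

    aggregated = aggregate_batches(sets_by_batch)
    log = {
        "n_input_metabolites": len(metabolite_columns(table)),
        "n_excluded": len({e["metabolite"] for e in excluded}),
        "excluded": excluded,
        "n_retained": len(mets),
        "n_xenobiotic": len(xeno),
        "m": m,
        "seed": seed,
    }
    return aggregated, log
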