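"""Atlas-level summaries of the association scan.

Counts and percentages of significant metabolites per phenotype with
domain-level medians and ranges, the most-connected metabolites (top fraction
by number of distinct phenotype associations), and Dice similarity
coefficients between significance sets, DSC = 2|X ∩ Y| / (|X| + |Y|).
Significance throughout means an FDR-adjusted Model-1 p below the scan's
alpha, as flagged in the association table.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SummaryError(ValueError):
    pass


def _significant(results: pd.DataFrame) -> pd.DataFrame:
    if "significant" not in results.columns:
        raise SummaryError("results lack significance flags")
    return results.loc[results["significant"].astype(bool)]


def significance_sets(results: pd.DataFrame, level: str = "phenotype") -> dict:
    """Map each phenotype (or domain: union over its phenotypes) to its set of
    significantly associated metabolites."""
    if level not in ("phenotype", "domain"):
        raise SummaryError(f"unknown level {level!r}")
    sig = _significant(results)
    owners = results[level].unique()
    out = {o: set() for o in owners}
    for owner, grp in sig.groupby(level):
        out[owner] = set(grp["metabolite"])
    return out


def count_table(results: pd.DataFrame):
    """Per-phenotype counts/percentages of significant metabolites, plus
    per-domain medians and ranges of those counts."""
    n_metab = results["metabolite"].nunique()
    sig = _significant(results)
    per_phen = (
        results[["phenotype", "domain"]]
        .drop_duplicates()
        .set_index("phenotype")
        .sort_index()
    )
    counts = sig.groupby("phenotype")["metabolite"].nunique()
    per_phen["n_significant"] = counts.reindex(per_phen.index).fillna(0).astype(int)
    per_phen["pct_significant"] = (
        100.0 * per_phen["n_significant"] / n_metab if n_metab else 0.0
    )
    per_domain = (
        per_phen.groupby("domain")["n_significant"]
        .agg(median="median", min="min", max="max", total="sum")
        .reset_index()
    )
    return per_phen.reset_index(), per_domain


def top_connected(results: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Rank metabolites by number of distinct significantly associated
    phenotypes and return the top ``ceil(fraction * n_connected)``.

    Only metabolites with at least one association are eligible; ties are
    broken lexicographically by metabolite identifier for reproducibility.
    Per-domain association counts are included.
    """
    if not 0 < fraction <= 1:
        raise SummaryError("fraction must lie in (0, 1]")
    sig = _significant(results)
    if sig.empty:
        return pd.DataFrame(columns=["metabolite", "n_phenotypes"])
    per_met = sig.groupby("metabolite")["phenotype"].nunique().rename("n_phenotypes")
    by_domain = (
        sig.groupby(["metabolite", "domain"])["phenotype"].nunique().unstack(fill_value=0)
    )
    tab = pd.concat([per_met, by_domain], axis=1).reset_index()
    tab = tab.sort_values(["n_phenotypes", "metabolite"], ascending=[False, True], kind="stable")
    k = math.ceil(fraction * len(tab))
    return tab.head(k).reset_index(drop=True)


def dice(X: set, Y: set) -> float:
    """Dice similarity coefficient 2|X∩Y|/(|X|+|Y|); undefined for two empties."""
    if len(X) == 0 and len(Y) == 0:
        raise SummaryError("DSC undefined for two empty sets")
    return 2.0 * len(X & Y) / (len(X) + len(Y))


def dsc_matrix(results: pd.DataFrame, level: str = "domain") -> pd.DataFrame:
    """Symmetric matrix of pairwise Dice coefficients between significance sets.

    Cells whose pair of sets is degenerate (both empty) are left missing and
    logged rather than raising.
    """
    sets = significance_sets(results, level=level)
    owners = sorted(sets)
    if sum(1 for o in owners if sets[o]) < 2:
        raise SummaryError("need at least two owners with nonempty significance sets")
    mat = pd.DataFrame(np.nan, index=owners, columns=owners, dtype=float)
    for i, a in enumerate(owners):
        for b in owners[i:]:
            if a == b:
                mat.loc[a, a] = 1.0 if sets[a] else np.nan
                continue
            try:
                val = dice(sets[a], sets[b])
            except SummaryError:
                logger.warning("DSC undefined for pair (%s, %s): both sets empty", a, b)
                continue
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat


def write_summaries(outdir, results: pd.DataFrame) -> dict:
    """Write count tables, top-connected list and DSC matrices as TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_phen, per_domain = count_table(results)
    per_phen.to_csv(outdir / "counts_per_phenotype.tsv", sep="\t", index=False)
    per_domain.to_csv(outdir / "counts_per_domain.tsv", sep="\t", index=False)
    top = top_connected(results)
    top.to_csv(outdir / "top_connected.tsv", sep="\t", index=False)
    written = {
        "counts_per_phenotype": str(outdir / "counts_per_phenotype.tsv"),
        "counts_per_domain": str(outdir / "counts_per_domain.tsv"),
        "top_connected": str(outdir / "top_connected.tsv"),
    }
    try:
        mat = dsc_matrix(results, level="domain")
        mat.to_csv(outdir / "dsc_domains.tsv", sep="\t")
        written["dsc_domains"] = str(outdir / "dsc_domains.tsv")
    except SummaryError as exc:
        logger.warning("domain DSC matrix not written: %s", exc)
    return written
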