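"""Design-based weighted linear regression for stratified cluster samples.

Implements the Gaussian survey-regression engine used throughout the atlas:
weighted least squares point estimates with a Taylor-linearized (sandwich)
variance estimator that respects a stratified two-stage design (strata
containing primary sampling units, PSUs, with unequal subject weights), plus
uni- and multivariate Wald tests referred to an F distribution on the design
degrees of freedom.

The variance estimator forms, for each PSU, the weighted score total
``z_hc = sum_i w_i x_i e_i`` over its subjects, centers the totals within each
stratum, applies the small-sample factor ``n_h / (n_h - 1)`` over the
stratum's ``n_h`` PSUs, and pre/post-multiplies the summed outer products by
the inverse weighted information ``(X' W X)^{-1}``.  The design degrees of
freedom are ``(# PSUs) - (# strata)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """Raised for invalid survey designs or rank-deficient model matrices."""


@dataclass(frozen=True, eq=False)
class SurveyDesign:
    """Per-subject stratum / PSU / weight triple.

    Parameters
    ----------
    stratum : array-like of labels, one per subject.
    psu : array-like of labels, one per subject.  A PSU label must occur in
        exactly one stratum; every stratum must contain at least two PSUs
        (single-PSU strata make the variance contribution undefined and are a
        hard error here, not silently recentered).
    weight : positive sampling weight per subject.
    """

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __init__(self, stratum, psu, weight):
        object.__setattr__(self, "stratum", np.asarray(stratum))
        object.__setattr__(self, "psu", np.asarray(psu))
        object.__setattr__(self, "weight", np.asarray(weight, dtype=float))
        self._validate()

    def _validate(self) -> None:
        n = len(self.stratum)
        if len(self.psu) != n or len(self.weight) != n:
            raise DesignError("stratum, psu and weight must have equal length")
        if n == 0:
            raise DesignError("empty design")
        if not np.all(np.isfinite(self.weight)) or np.any(self.weight <= 0):
            raise DesignError("weights must be strictly positive and finite")
        # each PSU belongs to exactly one stratum
        df = pd.DataFrame({"stratum": self.stratum, "psu": self.psu})
        per_psu = df.groupby("psu", sort=False)["stratum"].nunique()
        bad = per_psu[per_psu > 1]
        if len(bad):
            raise DesignError(f"PSU(s) {list(bad.index)} appear in more than one stratum")
        psus_per_stratum = df.drop_duplicates().groupby("stratum", sort=False)["psu"].nunique()
        lonely = psus_per_stratum[psus_per_stratum < 2]
        if len(lonely):
            raise DesignError(
                f"stratum(s) {list(lonely.index)} contain a single PSU; "
                "design-based variance requires >= 2 PSUs per stratum"
            )

    @property
    def n(self) -> int:
        return len(self.weight)

    @property
    def n_psus(self) -> int:
        return len(pd.unique(self.psu))

    @property
    def n_strata(self) -> int:
        return len(pd.unique(self.stratum))

    @property
    def design_df(self) -> int:
        """Design degrees of freedom: total PSUs minus total strata."""
        return self.n_psus - self.n_strata

    def _groups(self):
        """Cached PSU/stratum index structure for fast score aggregation.

        Returns ``(sort_idx, starts, strata_psu_lists)``: a stable ordering of
        subjects by PSU, the start offsets of each PSU block in that ordering,
        and, per stratum, the positions of its PSUs in the block sequence.
        """
        cached = getattr(self, "_groups_cache", None)
        if cached is not None:
            return cached
        psu_codes, psu_uniques = pd.factorize(self.psu, sort=False)
        sort_idx = np.argsort(psu_codes, kind="stable")
        sorted_codes = psu_codes[sort_idx]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(sorted_codes)) + 1])
        # stratum of each PSU (each PSU lives in exactly one stratum)
        first_subject = sort_idx[starts]
        psu_stratum = self.stratum[first_subject]
        strata_psu_lists = [
            np.flatnonzero(psu_stratum == s) for s in pd.unique(psu_stratum)
        ]
        cached = (sort_idx, starts, strata_psu_lists)
        object.__setattr__(self, "_groups_cache", cached)
        return cached

    def subset(self, mask) -> "SurveyDesign":
        """Design restricted to a boolean subject mask (for subgroup analyses)."""
        mask = np.asarray(mask, dtype=bool)
        return SurveyDesign(self.stratum[mask], self.psu[mask], self.weight[mask])


@dataclass
class FitResult:
    """Fitted survey-weighted linear model."""

    beta: np.ndarray
    vcov: np.ndarray
    design_df: int
    n: int
    names: list = field(default_factory=list)
    model_label: str | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def to_record(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "vcov": self.vcov.tolist(),
            "design_df": int(self.design_df),
            "n": int(self.n),
            "names": list(self.names),
            "model_label": self.model_label,
        }


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df1: int
    df2: int
    p: float


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:])
        labels = [names[j] if names else str(j) for j in dropped]
        raise DesignError(f"model matrix is rank deficient; collinear column(s): {labels}")


def fit_weighted_lm(
    y,
    X,
    design: SurveyDesign,
    names: list | None = None,
    model_label: str | None = None,
) -> FitResult:
    """Weighted least squares with stratified-cluster linearized variance.

    ``beta`` solves the weighted normal equations ``X'WX beta = X'Wy``; the
    covariance is the stratified-cluster sandwich described in the module
    docstring.  Scaling all weights by a positive constant changes neither
    ``beta`` nor ``vcov``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or design.n != X.shape[0]:
        raise DesignError("y, X and design must be row-aligned")
    if names is not None and len(names) != X.shape[1]:
        raise DesignError("names length must match number of columns of X")
    _check_rank(X, names)

    w = design.weight
    Xw = X * w[:, None]
    A = X.T @ Xw                       # weighted information X'WX
    beta = np.linalg.solve(A, Xw.T @ y)
    resid = y - X @ beta
    scores = Xw * resid[:, None]       # per-subject weighted score w_i * e_i * x_i

    # PSU score totals, centered within stratum
    sort_idx, starts, strata_psu_lists = design._groups()
    Z = np.add.reduceat(scores[sort_idx], starts, axis=0)
    G = np.zeros((X.shape[1], X.shape[1]))
    for psus in strata_psu_lists:
        Zh = Z[psus]
        n_h = Zh.shape[0]
        Zc = Zh - Zh.mean(axis=0)
        G += (n_h / (n_h - 1)) * (Zc.T @ Zc)

    Ainv = np.linalg.inv(A)
    vcov = Ainv @ G @ Ainv
    vcov = (vcov + vcov.T) / 2.0
    return FitResult(
        beta=beta,
        vcov=vcov,
        design_df=design.design_df,
        n=design.n,
        names=list(names) if names is not None else [],
        model_label=model_label,
    )


def wald_test(fit: FitResult, coef_indices) -> WaldResult:
    """Multivariate Wald test of ``beta[S] = 0`` on the design F reference.

    The statistic ``(beta_S' V_S^{-1} beta_S) / q`` with ``q = |S|`` is
    referred to ``F(q, design_df - q + 1)``.  For ``q = 1`` this reduces to
    the square of the usual design-based t statistic.
    """
    idx = np.atleast_1d(np.asarray(coef_indices, dtype=int))
    if idx.size == 0:
        raise DesignError("coef_indices must be nonempty")
    if np.any(idx < 0) or np.any(idx >= len(fit.beta)):
        raise DesignError("coef_indices out of range")
    q = idx.size
    df2 = fit.design_df - q + 1
    if df2 < 1:
        raise DesignError(f"denominator degrees of freedom {df2} < 1")
    b = fit.beta[idx]
    V = fit.vcov[np.ix_(idx, idx)]
    # reject numerically singular submatrices rather than pseudo-inverting
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise DesignError("singular covariance submatrix in Wald test")
    stat = float(b @ np.linalg.solve(V, b)) / q
    p = float(stats.f.sf(stat, q, df2))
    # beta_S exactly zero gives statistic 0, p = 1
    return WaldResult(statistic=stat, df1=q, df2=df2, p=min(max(p, 0.0), 1.0))
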