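"""Canonical correlation analysis between key lipids and matched tissue
proteins, with Wilks' lambda and Hotelling-Lawley trace inference and
per-protein outcome associations.

The canonical weights are obtained from the generalized symmetric
eigenproblem ``Sxy Syy^-1 Syx a = r^2 Sxx a`` (within-set covariances
ridge-regularized when near-singular); variates are scaled to unit variance.
The Wilks test of overall association is reported both as a permutation p
(rows of the protein block permuted) and as Rao's F approximation; per-CV
dimensionality uses the sequential HLT F approximation on the trailing
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .association import adjusted_logistic, bh_fdr, SeparationError

__all__ = ["CCAResult", "cca_fit", "wilks_test", "hlt_per_cv",
           "protein_gc_association"]


@dataclass
class CCAResult:
    correlations: np.ndarray  # r_1 >= r_2 >= ... >= 0
    x_weights: pd.DataFrame  # standardized-variable weights, lipids x CV
    y_weights: pd.DataFrame
    x_scores: pd.DataFrame  # canonical variates (unit variance)
    y_scores: pd.DataFrame
    wilks_lambda: float
    n: int
    ridge_used: bool = False
    x_sd: pd.Series | None = None
    y_sd: pd.Series | None = None

    @property
    def n_cv(self) -> int:
        return len(self.correlations)


def _std(df: pd.DataFrame) -> tuple[np.ndarray, pd.Series]:
    X = np.asarray(df, float)
    mu, sd = X.mean(0), X.std(0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance column in CCA input")
    return (X - mu) / sd, pd.Series(sd, index=df.columns)


def _canonical_correlations(Xs: np.ndarray, Ys: np.ndarray,
                            ridge: float | None = None) -> np.ndarray:
    """Canonical correlations via the generalized eigenproblem (no weights)."""
    n = len(Xs)
    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    if ridge:
        Sxx = Sxx + ridge * np.eye(len(Sxx)) * np.trace(Sxx) / len(Sxx)
        Syy = Syy + ridge * np.eye(len(Syy)) * np.trace(Syy) / len(Syy)
    M = Sxy @ linalg.solve(Syy, Sxy.T, assume_a="pos")
    ev = linalg.eigh(M, Sxx, eigvals_only=True)
    r2 = np.clip(np.sort(ev)[::-1], 0.0, 1.0)
    s = min(Xs.shape[1], Ys.shape[1])
    return np.sqrt(r2[:s])


def cca_fit(X: pd.DataFrame, Y: pd.DataFrame, ridge: str | float = "auto") -> CCAResult:
    """Canonical correlation analysis of two standardized blocks.

    ``ridge='auto'`` adds eps = 1e-6 * mean diagonal to a within-set
    covariance only if it is numerically near-singular (and warns); a float
    forces that relative ridge. Weight signs are fixed so the largest-magnitude
    lipid weight of each CV is positive.
    """
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same subjects")
    n = len(X)
    Xs, x_sd = _std(X)
    Ys, y_sd = _std(Y)
    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    ridge_used = False
    if ridge == "auto":
        eps = 0.0
        if min(np.linalg.cond(Sxx) ** -1, np.linalg.cond(Syy) ** -1) < 1e-10:
            eps = 1e-6
            ridge_used = True
            warnings.warn("near-singular within-set covariance; ridge applied")
    else:
        eps = float(ridge)
        ridge_used = eps > 0
    if eps:
        Sxx = Sxx + eps * np.eye(len(Sxx)) * np.trace(Sxx) / len(Sxx)
        Syy = Syy + eps * np.eye(len(Syy)) * np.trace(Syy) / len(Syy)

    M = Sxy @ linalg.solve(Syy, Sxy.T, assume_a="pos")
    ev, A = linalg.eigh(M, Sxx)
    order = np.argsort(ev)[::-1]
    s = min(X.shape[1], Y.shape[1])
    ev = np.clip(ev[order][:s], 0.0, 1.0)
    r = np.sqrt(ev)
    A = A[:, order][:, :s]  # generalized eigvecs: A' Sxx A = I (unit-variance variates)
    B = linalg.solve(Syy, Sxy.T, assume_a="pos") @ A
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(r[None, :] > 1e-12, B / r[None, :], B)
    # enforce unit variance of Y variates even when r ~ 0
    bnorm = np.sqrt(np.einsum("ij,jk,ik->i", B.T, Syy, B.T))
    B = B / np.where(bnorm > 0, bnorm, 1.0)[None, :]
    # sign convention
    for k in range(s):
        j = int(np.argmax(np.abs(A[:, k])))
        if A[j, k] < 0:
            A[:, k] *= -1
            B[:, k] *= -1
    cv_names = [f"CV{k + 1}" for k in range(s)]
    return CCAResult(
        correlations=r,
        x_weights=pd.DataFrame(A, index=X.columns, columns=cv_names),
        y_weights=pd.DataFrame(B, index=Y.columns, columns=cv_names),
        x_scores=pd.DataFrame(Xs @ A, index=X.index, columns=cv_names),
        y_scores=pd.DataFrame(Ys @ B, index=Y.index, columns=cv_names),
        wilks_lambda=float(np.prod(1.0 - r ** 2)),
        n=n, ridge_used=ridge_used, x_sd=x_sd, y_sd=y_sd)


def _rao_f(lam: float, n: int, p: int, q: int) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda."""
    if lam <= 0:
        return np.inf, p * q, 1.0, 0.0
    m = n - 1 - (p + q + 1) / 2.0
    num = p * q
    t2 = p ** 2 * q ** 2 - 4
    t = np.sqrt(t2 / (p ** 2 + q ** 2 - 5)) if p ** 2 + q ** 2 - 5 > 0 else 1.0
    den = m * t - num / 2.0 + 1.0
    L = lam ** (1.0 / t)
    F = (1 - L) / L * den / num
    pval = float(stats.f.sf(F, num, den)) if den > 0 else np.nan
    return float(F), float(num), float(den), pval


def wilks_test(result: CCAResult, X: pd.DataFrame, Y: pd.DataFrame,
               n_permutations: int = 999, seed: int = 0) -> dict:
    """Overall association test on Wilks' lambda.

    Default inference is a permutation test (rows of Y permuted, lambda
    recomputed, p = (1 + #{lambda_perm <= lambda_obs}) / (B + 1)); Rao's F
    approximation is emitted alongside. 999 permutations give a minimum
    attainable p of 0.001.
    """
    Xs, _ = _std(X)
    Ys, _ = _std(Y)
    ridge = 1e-6 if result.ridge_used else None
    rng = np.random.default_rng(seed)
    lam_obs = result.wilks_lambda
    count = 0
    n = len(Xs)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r = _canonical_correlations(Xs, Ys[perm], ridge=ridge)
        if float(np.prod(1.0 - r ** 2)) <= lam_obs + 1e-15:
            count += 1
    perm_p = (1 + count) / (n_permutations + 1)
    F, df1, df2, rao_p = _rao_f(lam_obs, n, X.shape[1], Y.shape[1])
    return {"wilks_lambda": lam_obs, "perm_p": float(perm_p),
            "n_permutations": n_permutations,
            "rao_F": F, "rao_df": (df1, df2), "rao_p": rao_p}


def hlt_per_cv(result: CCAResult) -> pd.DataFrame:
    """Sequential dimensionality tests on the Hotelling-Lawley trace.

    For CV k the statistic sums r_i^2/(1-r_i^2) over i = k..s, testing that
    all canonical correlations from the k-th on are zero, with the standard F
    approximation on the residual dimensions. Also reports the Pearson r
    between the k-th pair of canonical variates (identical to r_k by
    construction).
    """
    r = result.correlations
    s_all = len(r)
    p = result.x_weights.shape[0]
    q = result.y_weights.shape[0]
    n = result.n
    rows = []
    for k in range(s_all):
        rs = r[k:]
        r2 = np.clip(rs ** 2, 0.0, 1.0 - 1e-12)
        hlt = float(np.sum(r2 / (1.0 - r2)))
        pk, qk = p - k, q - k
        sk = min(pk, qk)
        mk = (abs(pk - qk) - 1) / 2.0
        Nk = (n - k - pk - qk - 2) / 2.0
        df1 = sk * (2 * mk + sk + 1)
        df2 = 2 * (sk * Nk + 1)
        if df2 > 0:
            F = df2 * hlt / (sk * df1) if df1 > 0 else np.nan
            pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else np.nan
        else:
            F, pval = np.nan, np.nan
        pear = float(np.corrcoef(result.x_scores.iloc[:, k],
                                 result.y_scores.iloc[:, k])[0, 1]) \
            if result.x_scores.iloc[:, k].std() > 0 and \
            result.y_scores.iloc[:, k].std() > 0 else np.nan
        rows.append({"cv": k + 1, "r": float(r[k]), "pearson_r": pear,
                     "HLT": hlt, "F": F, "df1": df1, "df2": df2, "p": pval})
    return pd.DataFrame(rows)


def protein_gc_association(
    proteins: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-protein adjusted logistic association with the binary GC outcome,
    BH-FDR corrected across proteins."""
    idx = outcome.index
    cov = covariates.loc[idx] if covariates is not None else None
    rows = []
    for prot in proteins.columns:
        x = proteins.loc[idx, prot]
        xs = (x - x.mean()) / x.std(ddof=0)
        try:
            res = adjusted_logistic(xs, outcome, cov)
            rows.append({"protein_id": prot, "OR": res.or_, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p})
        except SeparationError:
            rows.append({"protein_id": prot, "OR": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "note": "separation"})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out.loc[ok, "fdr_q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out
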