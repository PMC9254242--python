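"""Two-stage lipid association cascade and prospective progression analysis.

The discovery/validation filter mirrors a standard targeted-lipidomics
biomarker workflow: OPLS-DA variable importance (VIP > 1) for the GC-group
comparisons, covariate-adjusted logistic regression with Benjamini-Hochberg
FDR in the discovery set, replication in the validation set, inverse-variance
fixed-effect meta-analysis across the two stages, and a proportional-odds
ordinal regression of 3-level progression outcome (regression < no-change <
progression) in the prospective cohort.

All odds ratios are per unit of the supplied lipid column; with log-normalized
input (mean 0, SD 1) that is per SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SeparationError", "LogisticResult", "FilterTrace",
    "oplsda_vip", "adjusted_logistic", "firth_logistic", "bh_fdr",
    "meta_fixed", "ordinal_progression", "run_cascade", "CohortData",
]

_Z975 = stats.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation or fails
    to converge to a finite maximum."""


@dataclass
class LogisticResult:
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    method: str = "mle"  # "mle" | "firth"

    @classmethod
    def from_beta(cls, beta: float, se: float, method: str = "mle") -> "LogisticResult":
        lo, hi = beta - _Z975 * se, beta + _Z975 * se
        p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
        return cls(beta=beta, se=se, or_=float(np.exp(beta)),
                   ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
                   p=float(min(max(p, np.nextafter(0, 1)), 1.0)), method=method)


# ---------------------------------------------------------------------------
# OPLS-DA variable importance
# ---------------------------------------------------------------------------

def oplsda_vip(X: np.ndarray | pd.DataFrame, y: np.ndarray, n_ortho: int = 1) -> np.ndarray:
    """VIP of the predictive component of an OPLS-DA model.

    Fits one predictive plus ``n_ortho`` orthogonal components by NIPALS-style
    deflation: orthogonal variation (X variance uncorrelated with y) is removed
    first, then a single PLS component is fit on the filtered matrix. With one
    predictive component the VIP of variable j reduces to sqrt(p) * |w_j| for
    the unit-norm predictive weight vector, so sum(VIP^2) = p exactly.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("oplsda_vip requires both classes in y")
    sd = X.std(axis=0)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        name = cols[j] if cols else j
        raise ValueError(f"zero-variance column {name!r}")
    X = X - X.mean(axis=0)
    yc = y - y.mean()

    for _ in range(n_ortho):
        w = X.T @ yc
        w /= np.linalg.norm(w)
        t = X @ w
        p_load = X.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o /= nrm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)

    w = X.T @ yc
    w /= np.linalg.norm(w)
    p = X.shape[1]
    vip = np.sqrt(p) * np.abs(w)
    return vip


# ---------------------------------------------------------------------------
# Logistic regression (Wald inference) with Firth fallback
# ---------------------------------------------------------------------------

def _design(x: np.ndarray, covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x, dtype=float), np.asarray(x, float)]
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def adjusted_logistic(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    maxiter: int = 100,
) -> LogisticResult:
    """Maximum-likelihood logistic regression of binary ``y`` on a lipid column,
    adjusting for covariates (age, sex, H. pylori in the standard analysis).

    Returns Wald OR, 95% CI and p for the lipid coefficient. Raises
    :class:`SeparationError` on perfect separation or non-convergence.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y has a single class")
    X = _design(x, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
            raise SeparationError(str(e)) from e
    beta = res.params[1]
    se = res.bse[1]
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge")
    if not np.isfinite(se) or abs(beta) > 15 or se > 50:
        raise SeparationError("separation suspected: unbounded lipid coefficient")
    return LogisticResult.from_beta(float(beta), float(se))


def firth_logistic(X: np.ndarray, y: np.ndarray, maxiter: int = 200,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys prior).

    Newton iterations on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    h the leverages of the weighted design. Returns (beta, se) where the
    standard errors come from the inverse Fisher information at the optimum.
    Used as the fallback when ordinary MLE separates.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # damped Newton for stability on tiny samples
        while np.max(np.abs(step)) > 5.0:
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (p * (1 - p))[:, None])
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


# ---------------------------------------------------------------------------
# FDR, meta-analysis
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in sorted p order)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("bh_fdr: empty p-value input")
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_fixed(effects: list[tuple[float, float]]) -> LogisticResult:
    """Inverse-variance fixed-effect pooling of per-stage (log-OR, SE) pairs."""
    if len(effects) < 2:
        raise ValueError("meta_fixed needs at least 2 stages")
    b = np.array([e[0] for e in effects], float)
    s = np.array([e[1] for e in effects], float)
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / s ** 2
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return LogisticResult.from_beta(pooled, se, method="meta_fixed")


# ---------------------------------------------------------------------------
# Ordinal (proportional odds) progression regression
# ---------------------------------------------------------------------------

def ordinal_progression(
    x: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    maxiter: int = 200,
) -> LogisticResult:
    """Proportional-odds cumulative-logit fit of a 3-level ordered outcome
    (regression < no-change < progression) on a lipid column, adjusted for
    covariates (age, sex, H. pylori, baseline histology in the standard
    analysis). The OR is in the progression direction: OR > 1 means higher
    lipid level, higher odds of progression.
    """
    x = np.asarray(x, float)
    out = np.asarray(outcome)
    levels = np.unique(out)
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 observed levels")
    codes = np.searchsorted(levels, out)
    exog = [x]
    names = ["lipid"]
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        exog.extend(cov.T)
        names.extend(f"c{i}" for i in range(cov.shape[1]))
    exog_df = pd.DataFrame(np.column_stack(exog), columns=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(pd.Series(codes), exog_df, distr="logit")
        res = model.fit(method="bfgs", disp=0, maxiter=maxiter)
    beta = float(res.params["lipid"])
    se = float(res.bse["lipid"])
    if not res.mle_retvals.get("converged", True) or not np.isfinite(se) \
            or abs(beta) > 15 or se > 50:
        raise SeparationError("ordinal fit did not converge (separation?)")
    return LogisticResult.from_beta(beta, se, method="ordinal")


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Analysis-ready view of one cohort: log-normalized lipids, covariates,
    and either a 3-group lesion label ('mild'/'advanced'/'gc') or, for the
    prospective cohort, the 3-level progression outcome (-1/0/+1)."""

    X: pd.DataFrame  # lognorm lipids, subjects x lipids
    covariates: pd.DataFrame  # age, sex, hp (+ baseline severity for prospective)
    group: pd.Series | None = None  # lesion group label per subject
    outcome: pd.Series | None = None  # ordered progression outcome


@dataclass
class FilterTrace:
    identified: int
    vip_survivors: int
    discovery_significant: int
    validated: int
    progression_associated: int

    def counts(self) -> list[int]:
        return [self.identified, self.vip_survivors, self.discovery_significant,
                self.validated, self.progression_associated]

    def __post_init__(self) -> None:
        c = self.counts()
        if any(b > a for a, b in zip(c, c[1:])):
            raise ValueError("filter-trace counts must be non-increasing")


_COMPARISONS = {"gc_vs_mild": ("gc", "mild"), "gc_vs_advanced": ("gc", "advanced")}


def _comparison_mask(group: pd.Series, comparison: str) -> tuple[np.ndarray, np.ndarray]:
    case, ref = _COMPARISONS[comparison]
    mask = group.isin([case, ref]).to_numpy()
    y = (group[mask] == case).astype(float).to_numpy()
    return mask, y


def run_cascade(
    discovery: CohortData,
    validation: CohortData,
    prospective: CohortData,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
    n_ortho: int = 1,
) -> tuple[FilterTrace, pd.DataFrame]:
    """Apply the full discovery -> validation -> prospective filter cascade.

    Gates (strict inequalities): VIP > 1 in either GC comparison; adjusted
    logistic p < 0.05 and BH FDR-q < 0.05 in discovery (FDR across the VIP
    survivors within each comparison); p < 0.05 with a consistent direction in
    validation; ordinal progression p < 0.05 in the prospective cohort.
    Lipids whose fit separates or fails in a comparison are dropped from that
    comparison with a note in the record table.

    Returns the filter trace and a tidy record table (one row per lipid x
    comparison x stage) including the fixed-effect meta-analysis for lipids
    that replicate.
    """
    records: list[dict] = []
    lipids = list(discovery.X.columns)
    n_identified = len(lipids)

    # gate 1: VIP > threshold in either GC comparison (discovery)
    vip_pass: dict[str, set[str]] = {}
    vips: dict[str, pd.Series] = {}
    for comp in _COMPARISONS:
        mask, y = _comparison_mask(discovery.group, comp)
        vip = oplsda_vip(discovery.X.loc[mask], y, n_ortho=n_ortho)
        vips[comp] = pd.Series(vip, index=lipids)
        vip_pass[comp] = {l for l, v in vips[comp].items() if v > vip_threshold}
    vip_survivors = sorted(vip_pass["gc_vs_mild"] | vip_pass["gc_vs_advanced"],
                           key=lipids.index)

    # gate 2: adjusted logistic in discovery, BH-FDR within each comparison
    disc_pass: dict[str, dict[str, LogisticResult]] = {c: {} for c in _COMPARISONS}
    for comp in _COMPARISONS:
        tested = sorted(vip_pass[comp], key=lipids.index)
        if not tested:
            continue
        mask, y = _comparison_mask(discovery.group, comp)
        cov = discovery.covariates.loc[mask].to_numpy()
        fits: dict[str, LogisticResult] = {}
        for lip in tested:
            try:
                fits[lip] = adjusted_logistic(discovery.X.loc[mask, lip], y, cov)
            except SeparationError:
                records.append({"lipid_id": lip, "comparison": comp,
                                "stage": "discovery", "note": "separation"})
        if not fits:
            continue
        qs = bh_fdr([fits[l].p for l in fits])
        for (lip, res), q in zip(fits.items(), qs):
            records.append({
                "lipid_id": lip, "comparison": comp, "stage": "discovery",
                "VIP": float(vips[comp][lip]), "OR": res.or_, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p": res.p, "fdr_q": float(q)})
            if res.p < p_threshold and q < q_threshold:
                disc_pass[comp][lip] = res
    discovery_sig = sorted(set(disc_pass["gc_vs_mild"]) | set(disc_pass["gc_vs_advanced"]),
                           key=lipids.index)

    # gate 3: replication in validation (p < threshold, same direction)
    val_pass: dict[str, dict[str, LogisticResult]] = {c: {} for c in _COMPARISONS}
    for comp in _COMPARISONS:
        if not disc_pass[comp]:
            continue
        mask, y = _comparison_mask(validation.group, comp)
        cov = validation.covariates.loc[mask].to_numpy()
        for lip, dres in disc_pass[comp].items():
            try:
                res = adjusted_logistic(validation.X.loc[mask, lip], y, cov)
            except SeparationError:
                records.append({"lipid_id": lip, "comparison": comp,
                                "stage": "validation", "note": "separation"})
                continue
            records.append({
                "lipid_id": lip, "comparison": comp, "stage": "validation",
                "OR": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p})
            if res.p < p_threshold and np.sign(res.beta) == np.sign(dres.beta):
                val_pass[comp][lip] = res
                meta = meta_fixed([(dres.beta, dres.se), (res.beta, res.se)])
                records.append({
                    "lipid_id": lip, "comparison": comp, "stage": "meta",
                    "OR": meta.or_, "ci_low": meta.ci_low,
                    "ci_high": meta.ci_high, "p": meta.p})
    validated = sorted(set(val_pass["gc_vs_mild"]) | set(val_pass["gc_vs_advanced"]),
                       key=lipids.index)

    # gate 4: ordinal progression association in the prospective cohort
    prog_pass: list[str] = []
    cov = prospective.covariates.to_numpy()
    for lip in validated:
        try:
            res = ordinal_progression(prospective.X[lip], prospective.outcome, cov)
        except (SeparationError, np.linalg.LinAlgError):
            records.append({"lipid_id": lip, "comparison": "progression",
                            "stage": "prospective", "note": "separation"})
            continue
        records.append({
            "lipid_id": lip, "comparison": "progression", "stage": "prospective",
            "OR": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p})
        if res.p < p_threshold:
            prog_pass.append(lip)

    trace = FilterTrace(
        identified=n_identified, vip_survivors=len(vip_survivors),
        discovery_significant=len(discovery_sig), validated=len(validated),
        progression_associated=len(prog_pass))
    table = pd.DataFrame(records)
    table.attrs["surviving_lipids"] = prog_pass
    return trace, table
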