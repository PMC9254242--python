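"""PAM clustering of latent lipid profiles, lesion-severity trajectories over
follow-up, and cluster-wise progression odds ratios.

PAM (k-medoids) is implemented directly with the classic BUILD + SWAP phases
on Euclidean distances; the number of clusters is chosen by maximizing the
mean silhouette width. Per-cluster severity trajectories are penalized
cubic-spline smooths (generalized additive model, smoothing by GCV) with
pointwise +/-2 SE bands. Cluster-vs-reference progression odds ratios come
from one adjusted logistic model with cluster indicators, with a Firth
fallback when a cluster separates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .association import LogisticResult, firth_logistic
from .cohort import Subject, progression_outcome

__all__ = ["ClusterAssignment", "TrajectoryFit", "pam_cluster", "choose_k",
           "fit_trajectories", "cluster_progression_or", "plot_trajectories"]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # subject -> cluster label 1..k
    medoids: list  # subject ids (or row indices) of the medoids, by label
    silhouette: pd.Series
    k: int
    objective: float  # total distance to assigned medoid


def _pam_objective(D: np.ndarray, medoids: list[int]) -> tuple[float, np.ndarray]:
    sub = D[:, medoids]
    assign = sub.argmin(axis=1)
    return float(sub.min(axis=1).sum()), assign


def pam_cluster(X: np.ndarray | pd.DataFrame, k: int) -> ClusterAssignment:
    """Partitioning Around Medoids with BUILD and SWAP phases.

    The objective (total Euclidean distance of each point to its medoid) is
    non-increasing across swaps; iteration stops when no single swap improves
    it. Ties are broken by the lowest row index. Labels are 1..k in order of
    medoid row index.
    """
    index = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(X)))
    A = np.asarray(X, float)
    n = len(A)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, n]; got k={k}, n={n}")
    D = cdist(A, A)

    # BUILD: greedy seeding
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))  # argmax takes lowest index on ties

    # SWAP: steepest single-swap descent
    best_obj, _ = _pam_objective(D, medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                obj, _ = _pam_objective(D, cand)
                if obj < best_obj - 1e-12:
                    best_obj, best_swap = obj, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            improved = True
    medoids = sorted(medoids)
    obj, assign = _pam_objective(D, medoids)
    labels = pd.Series(assign + 1, index=index, name="cluster")
    if k == 1 or k >= n:
        sil = pd.Series(0.0, index=index)
    else:
        sil = pd.Series(silhouette_samples(A, labels.to_numpy()), index=index)
    return ClusterAssignment(labels=labels, medoids=[index[m] for m in medoids],
                             silhouette=sil, k=k, objective=obj)


def choose_k(X: np.ndarray | pd.DataFrame, k_range=range(2, 9)) -> tuple[int, pd.Series]:
    """k maximizing the mean silhouette width over ``k_range`` (ties -> smallest k).

    Returns (k, mean silhouette per candidate k)."""
    ks = [k for k in k_range if 2 <= k <= len(X) - 1]
    if not ks:
        raise ValueError("empty or infeasible k range")
    means = {}
    for k in ks:
        means[k] = float(pam_cluster(X, k).silhouette.mean())
    best = max(ks, key=lambda k: (means[k], -k))
    return best, pd.Series(means)


@dataclass
class TrajectoryFit:
    curves: pd.DataFrame  # long: cluster, day, fit, se, lo, hi
    flat_clusters: list[int]  # clusters smoothed as a flat mean (too few records)
    per_cluster_drift: pd.DataFrame  # cluster, start_fit, end_fit, drift, drift_se


def _gam_curve(days: np.ndarray, sev: np.ndarray, grid: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    df = min(6, len(np.unique(days)) - 1)
    bs = BSplines(days[:, None], df=[max(df, 3)], degree=[3])
    # GCV over a small alpha grid keeps the fit stable on sparse visit data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gam = GLMGam(sev, exog=np.ones((len(sev), 1)), smoother=bs)
        try:
            alpha = gam.select_penweight(alphas=[np.logspace(-2, 6, 12)])[0]
        except Exception:
            alpha = [1.0]
        res = GLMGam(sev, exog=np.ones((len(sev), 1)), smoother=bs,
                     alpha=alpha).fit()
    basis = bs.transform(grid[:, None])
    Xg = np.column_stack([np.ones(len(grid)), basis])
    fit = Xg @ res.params
    cov = res.cov_params()
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
    return fit, se


def fit_trajectories(subjects: list[Subject], labels: pd.Series,
                     n_grid: int = 60, min_records: int = 5) -> TrajectoryFit:
    """Per-cluster smooth of lesion severity (1-6) against follow-up day.

    Pools all (day, severity) visit records of a cluster's subjects and fits a
    penalized cubic spline; clusters with fewer than ``min_records`` records
    (or too few distinct days) fall back to a flat mean. Fitted severities are
    clipped to [1, 6]; bands are pointwise +/-2 SE.
    """
    recs = []
    for s in subjects:
        if s.id not in labels.index:
            continue
        for day, st in s.visits:
            recs.append({"cluster": int(labels[s.id]), "day": day, "sev": int(st)})
    df = pd.DataFrame(recs)
    if df.empty:
        raise ValueError("no visit records")
    rows, drift_rows, flat = [], [], []
    for cl, grp in df.groupby("cluster"):
        days = grp["day"].to_numpy(float)
        sev = grp["sev"].to_numpy(float)
        grid = np.linspace(days.min(), days.max(), n_grid)
        if len(grp) < min_records or len(np.unique(days)) < 4 or sev.std() == 0.0:
            mean = float(sev.mean())
            se_m = float(sev.std(ddof=1) / np.sqrt(len(sev))) if len(sev) > 1 else 0.0
            fit = np.full(n_grid, mean)
            se = np.full(n_grid, se_m)
            if len(grp) < min_records or len(np.unique(days)) < 4:
                flat.append(int(cl))
                warnings.warn(f"cluster {cl}: {len(grp)} visit records; flat mean used")
        else:
            fit, se = _gam_curve(days, sev, grid)
        fit = np.clip(fit, 1.0, 6.0)
        for d, f, s_ in zip(grid, fit, se):
            rows.append({"cluster": int(cl), "day": float(d), "fit": float(f),
                         "se": float(s_), "lo": float(np.clip(f - 2 * s_, 1, 6)),
                         "hi": float(np.clip(f + 2 * s_, 1, 6))})
        drift_rows.append({
            "cluster": int(cl), "start_fit": float(fit[0]), "end_fit": float(fit[-1]),
            "drift": float(fit[-1] - fit[0]),
            "drift_se": float(np.sqrt(se[0] ** 2 + se[-1] ** 2))})
    return TrajectoryFit(curves=pd.DataFrame(rows), flat_clusters=flat,
                         per_cluster_drift=pd.DataFrame(drift_rows))


def cluster_progression_or(
    labels: pd.Series,
    progressed: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster-vs-reference progression odds ratios from one logistic model.

    Cluster 1 (lowest label) is the reference (OR fixed at 1). Emits Wald ORs
    with 95% CIs, a global likelihood-ratio chi-square across the cluster
    terms, and a one-way ANOVA F of the progression indicator across clusters.
    A cluster with zero (or all) progressions separates the MLE; the model is
    then refit with Firth's penalty and flagged.
    """
    labels = labels.astype(int)
    y = progressed.loc[labels.index].astype(float).to_numpy()
    ks = sorted(labels.unique())
    ref = ks[0]
    dummies = np.column_stack([(labels == k).to_numpy(float) for k in ks[1:]]) \
        if len(ks) > 1 else np.empty((len(labels), 0))
    cov = covariates.loc[labels.index].to_numpy(float) if covariates is not None \
        else np.empty((len(labels), 0))
    Xfull = np.column_stack([np.ones(len(y)), dummies, cov])
    Xred = np.column_stack([np.ones(len(y)), cov])

    needs_firth = any(
        progressed.loc[labels.index][labels == k].nunique() < 2 for k in ks)
    method = "mle"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if needs_firth:
                raise np.linalg.LinAlgError("separation")
            full = sm.Logit(y, Xfull).fit(disp=0)
            red = sm.Logit(y, Xred).fit(disp=0)
            if not full.mle_retvals.get("converged", True) or \
                    np.any(np.abs(full.params[1:len(ks)]) > 15):
                raise np.linalg.LinAlgError("separation")
            betas, ses = full.params, full.bse
            lr = 2.0 * (full.llf - red.llf)
        except (np.linalg.LinAlgError, ValueError):
            method = "firth"
            betas, ses = firth_logistic(Xfull, y)
            lr = np.nan
    df_cl = len(ks) - 1
    global_p = float(stats.chi2.sf(lr, df_cl)) if np.isfinite(lr) else np.nan
    groups = [y[(labels == k).to_numpy()] for k in ks]
    if all(len(g) > 1 for g in groups) and len(groups) > 1:
        F, F_p = stats.f_oneway(*groups)
    else:
        F, F_p = np.nan, np.nan
    rows = [{"cluster": ref, "OR": 1.0, "ci_low": np.nan, "ci_high": np.nan,
             "p": np.nan, "method": "reference"}]
    for i, k in enumerate(ks[1:], start=1):
        r = LogisticResult.from_beta(float(betas[i]), float(ses[i]), method=method)
        rows.append({"cluster": k, "OR": r.or_, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "p": r.p, "method": method})
    out = pd.DataFrame(rows)
    out.attrs["lr_chi2"] = float(lr) if np.isfinite(lr) else np.nan
    out.attrs["lr_p"] = global_p
    out.attrs["anova_F"] = float(F)
    out.attrs["anova_p"] = float(F_p)
    return out


def progression_flags(subjects: list[Subject]) -> pd.Series:
    """Binary progression indicator (endpoint severity > baseline) per subject."""
    return pd.Series({s.id: int(progression_outcome(s) > 0) for s in subjects})


def plot_trajectories(traj: TrajectoryFit, path) -> None:
    """Write the per-cluster severity trajectories with their +/-2 SE bands
    to an SVG/PNG file (format from the extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "lipidcascade"  # reproducible SVG ids

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cl, grp in traj.curves.groupby("cluster"):
        line, = ax.plot(grp["day"], grp["fit"], label=f"cluster {cl}")
        ax.fill_between(grp["day"], grp["lo"], grp["hi"],
                        color=line.get_color(), alpha=0.15, linewidth=0)
    ax.set_xlabel("follow-up day")
    ax.set_ylabel("lesion severity (1=SG .. 6=invasive GC)")
    ax.set_ylim(0.8, 6.2)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if str(path).endswith(".svg"):
        fig.savefig(path, metadata={"Date": None})  # no timestamp: runs hash equal
    else:
        fig.savefig(path)
    plt.close(fig)
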