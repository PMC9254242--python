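"""Risk-prediction harness: lipid risk scores, ROC/AUC, the DeLong paired
test, micro-average multiclass AUC, and cross-validated gradient-boosted
model comparisons (baseline covariates vs + latent profiles vs + risk score).

AUCs use the Mann-Whitney statistic with midrank tie handling; paired AUC
comparisons use DeLong's structural-components (placement-value) covariance
estimate. Out-of-fold scores are the only scores ever evaluated; risk-score
coefficients are refit inside each training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .association import SeparationError, firth_logistic

__all__ = ["RiskScoreModel", "risk_score", "auc_roc", "delong_test",
           "micro_average_auc", "run_models", "ModelComparison"]


# ---------------------------------------------------------------------------
# Forward-stepwise lipid risk score
# ---------------------------------------------------------------------------

@dataclass
class RiskScoreModel:
    """Linear lipid risk score: sum of beta_i * lipid_i from an adjusted
    logistic model. ``selected`` holds the forward-stepwise (AIC) choice;
    ``full`` the all-lipid model, which is always fitted as well."""

    lipid_ids: list[str]
    selected: list[str]
    betas_selected: pd.Series
    betas_full: pd.Series

    def score(self, lipids: pd.DataFrame, which: str = "full") -> pd.Series:
        betas = self.betas_full if which == "full" else self.betas_selected
        cols = list(betas.index)
        return lipids[cols] @ betas


def _logit_fit(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params) > 15):
        raise SeparationError("separation in risk-score fit")
    return res


def risk_score(lipids: pd.DataFrame, outcome: np.ndarray | pd.Series,
               covariates: pd.DataFrame | None = None) -> RiskScoreModel:
    """Fit the lipid risk score on training data only.

    Forward stepwise: starting from covariates alone, repeatedly add the lipid
    that most improves AIC; stop when no addition improves it. The returned
    model also carries the all-lipid fit (the combination of every candidate
    lipid), whose score is the linear predictor minus intercept and covariate
    terms. Separation triggers a Firth-penalized fallback.
    """
    y = np.asarray(outcome, float)
    cov = covariates.to_numpy(float) if covariates is not None \
        else np.empty((len(y), 0))
    base_cols = [np.ones(len(y))] + ([cov] if cov.size else [])

    def fit(cols: list[str]):
        X = np.column_stack(base_cols + [lipids[cols].to_numpy()]) if cols \
            else np.column_stack(base_cols)
        try:
            res = _logit_fit(X, y)
            k = X.shape[1]
            return res.params, 2 * k - 2 * res.llf
        except (SeparationError, np.linalg.LinAlgError):
            beta, _ = firth_logistic(X, y)
            eta = np.clip(X @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            eps = 1e-12
            llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
            return beta, 2 * X.shape[1] - 2 * llf

    _, aic_cur = fit([])
    selected: list[str] = []
    remaining = list(lipids.columns)
    while remaining:
        trials = [(fit(selected + [l])[1], l) for l in remaining]
        best_aic, best_l = min(trials, key=lambda t: (t[0], lipids.columns.get_loc(t[1])))
        if best_aic < aic_cur - 1e-9:
            selected.append(best_l)
            remaining.remove(best_l)
            aic_cur = best_aic
        else:
            break
    n_cov = 1 + cov.shape[1]
    params_sel, _ = fit(selected)
    params_full, _ = fit(list(lipids.columns))
    return RiskScoreModel(
        lipid_ids=list(lipids.columns), selected=selected,
        betas_selected=pd.Series(params_sel[n_cov:], index=selected),
        betas_full=pd.Series(params_full[n_cov:], index=list(lipids.columns)))


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

def auc_roc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep) and AUC as the normalized Mann-Whitney
    statistic with midrank tie handling."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.r_[np.flatnonzero(np.diff(s[order]) != 0), len(s) - 1]
    roc = pd.DataFrame({
        "threshold": np.r_[np.inf, s[order][distinct]],
        "fpr": np.r_[0.0, fps[distinct] / n0],
        "tpr": np.r_[0.0, tps[distinct] / n1],
    })
    return roc, float(auc)


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # midrank comparison: 1 if >, 0.5 if ==
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> dict:
    """DeLong's test for two correlated AUCs on the same subjects.

    Returns z, two-sided p, the AUCs, and the 2x2 covariance matrix of the
    AUC estimates. Zero variance of the AUC difference (e.g. identical
    models) gives p = 1 with ``degenerate`` flagged.
    """
    y = np.asarray(labels, float)
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(sa) != len(y) or len(sb) != len(y):
        raise ValueError("scores must be paired on the same subjects")
    v10 = np.column_stack([_placements(sa, y)[0], _placements(sb, y)[0]])
    v01 = np.column_stack([_placements(sa, y)[1], _placements(sb, y)[1]])
    aucs = v10.mean(axis=0)
    m, n = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10.T, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01.T, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return {"z": 0.0, "p": 1.0, "auc_a": float(aucs[0]), "auc_b": float(aucs[1]),
                "cov": cov, "degenerate": True}
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z))),
            "auc_a": float(aucs[0]), "auc_b": float(aucs[1]), "cov": cov,
            "degenerate": False}


def delong_ci(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """AUC with a 95% CI from the single-model DeLong variance."""
    y = np.asarray(labels, float)
    v10, v01 = _placements(np.asarray(scores, float), y)
    auc = float(v10.mean())
    var = (v10.var(ddof=1) / len(v10) if len(v10) > 1 else 0.0) \
        + (v01.var(ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def micro_average_auc(scores: pd.DataFrame | np.ndarray,
                      labels: np.ndarray) -> float:
    """Micro-average AUC of a multiclass one-vs-rest score matrix: pool all
    (subject, class) indicator/score pairs and compute a single AUC."""
    S = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    classes = list(scores.columns) if isinstance(scores, pd.DataFrame) \
        else list(range(S.shape[1]))
    y = np.asarray(labels)
    missing = set(np.unique(y)) - set(classes)
    if missing:
        raise ValueError(f"no score column for class(es) {sorted(missing)}")
    onehot = np.column_stack([(y == c).astype(float) for c in classes])
    _, auc = auc_roc(S.ravel(), onehot.ravel())
    return auc


# ---------------------------------------------------------------------------
# Cross-validated XGBoost comparisons
# ---------------------------------------------------------------------------

_XGB_DEFAULTS = dict(max_depth=3, n_estimators=200, learning_rate=0.1,
                     subsample=0.9, colsample_bytree=0.9, nthread=1,
                     tree_method="hist", verbosity=0)


@dataclass
class ModelComparison:
    table: pd.DataFrame  # outcome, features, auc, ci_low, ci_high
    delong: pd.DataFrame  # outcome, comparison, z, p
    scores: dict = field(default_factory=dict)  # (outcome, features) -> out-of-fold scores


def _oof_scores(X: np.ndarray, y: np.ndarray, folds: int, seed: int,
                multiclass: bool, params: dict) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_classes = len(np.unique(y))
    oof = np.zeros((len(y), n_classes)) if multiclass else np.zeros(len(y))
    for tr, te in skf.split(X, y):
        assert len(np.intersect1d(tr, te)) == 0, "fold leakage"
        if multiclass:
            clf = xgb.XGBClassifier(objective="multi:softprob",
                                    num_class=n_classes, random_state=seed,
                                    **params)
            clf.fit(X[tr], y[tr])
            oof[te] = clf.predict_proba(X[te])
        else:
            clf = xgb.XGBClassifier(objective="binary:logistic",
                                    random_state=seed, **params)
            clf.fit(X[tr], y[tr])
            oof[te] = clf.predict_proba(X[te])[:, 1]
    return oof


def run_models(
    base: pd.DataFrame,
    outcomes: dict[str, pd.Series],
    latent: pd.DataFrame | None = None,
    lipids: pd.DataFrame | None = None,
    folds: int = 10,
    seed: int = 0,
    learner: dict | None = None,
) -> ModelComparison:
    """Train and compare gradient-boosted models per outcome and feature set.

    Feature sets: ``base`` (covariates only), ``base+latent`` and
    ``base+riskscore`` where inputs are available. Outcome values may be
    binary (0/1) or multiclass integer labels (evaluated by micro-average
    AUC). All evaluation uses stratified out-of-fold scores; risk-score
    coefficients are refit inside each training fold, so no evaluation subject
    ever influences its own score.
    """
    params = dict(_XGB_DEFAULTS, **(learner or {}))
    rows, dl_rows, all_scores = [], [], {}
    for name, y_ser in outcomes.items():
        idx = y_ser.index
        y = y_ser.to_numpy()
        multiclass = len(np.unique(y)) > 2
        Xb = base.loc[idx].to_numpy(float)
        feature_sets: dict[str, np.ndarray] = {"base": Xb}
        if latent is not None:
            feature_sets["base+latent"] = np.column_stack(
                [Xb, latent.loc[idx].to_numpy(float)])
        if lipids is not None and not multiclass:
            # per-fold risk score to avoid optimism
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            rs = np.zeros(len(y))
            lip = lipids.loc[idx]
            for tr, te in skf.split(Xb, y):
                assert len(np.intersect1d(tr, te)) == 0, "fold leakage"
                model = risk_score(lip.iloc[tr], y[tr],
                                   covariates=base.loc[idx].iloc[tr])
                rs[te] = model.score(lip.iloc[te], which="full").to_numpy()
            feature_sets["base+riskscore"] = np.column_stack([Xb, rs])
        for feats, X in feature_sets.items():
            oof = _oof_scores(X, y, folds, seed, multiclass, params)
            all_scores[(name, feats)] = oof
            if multiclass:
                auc = micro_average_auc(
                    pd.DataFrame(oof, columns=sorted(np.unique(y))), y)
                lo = hi = np.nan
            else:
                auc, lo, hi = delong_ci(oof, y)
            rows.append({"outcome": name, "features": feats, "auc": auc,
                         "ci_low": lo, "ci_high": hi})
        if not multiclass:
            for feats in feature_sets:
                if feats == "base":
                    continue
                d = delong_test(all_scores[(name, feats)],
                                all_scores[(name, "base")], y)
                dl_rows.append({"outcome": name, "comparison": f"{feats} vs base",
                                "z": d["z"], "p": d["p"],
                                "auc_aug": d["auc_a"], "auc_base": d["auc_b"],
                                "degenerate": d["degenerate"]})
    return ModelComparison(table=pd.DataFrame(rows),
                           delong=pd.DataFrame(dl_rows), scores=all_scores)
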