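"""Latent lipid profiles via repeated VAE fits with Elastic-Net selection.

The procedure (VAE + Elastic Net) generates many variational-autoencoder
latent matrices from the key-lipid matrix, selects the informative latent
dimensions of each by elastic-net regression (mixing 0.5, penalty by 5-fold
CV), scores the selected dimensions by out-of-fold R^2 of a multi-response
linear regression (10-fold CV) against target variables, and keeps the latent
matrix with the highest average R^2.

The VAE itself is a small fully-connected Gaussian encoder / Gaussian decoder
network written directly in numpy (manual backpropagation, Adam): with ~11
input lipids a single hidden layer of width 16 and a 4-dimensional latent
space is ample. The latent representation handed downstream is the encoder
posterior mean, so clustering and scoring are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV, LinearRegression
from sklearn.model_selection import KFold

__all__ = ["VAEConfig", "LatentProfileSet", "fit_vae", "en_select",
           "score_matrix", "vaen_run"]

NEG_INF = float("-inf")


@dataclass
class VAEConfig:
    latent_dim: int = 4
    hidden_dim: int = 16
    epochs: int = 500
    batch_size: int | None = None  # None = full batch
    learning_rate: float = 1e-2
    kl_weight: float = 0.1
    n_repeats: int = 200
    en_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 <= self.en_alpha <= 1.0:
            raise ValueError("en_alpha must lie in [0, 1]")


@dataclass
class LatentProfileSet:
    latent: pd.DataFrame  # subjects x selected dimensions (posterior means)
    selected_dims: list[int]
    average_R2: float
    best_repeat: int
    diagnostics: pd.DataFrame  # one row per repeat


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _init_params(d: int, h: int, L: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def glorot(a, b):
        return rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b))
    return {
        "W1": glorot(d, h), "b1": np.zeros(h),
        "W_mu": glorot(h, L), "b_mu": np.zeros(L),
        "W_lv": glorot(h, L) * 0.1, "b_lv": np.zeros(L),
        "W2": glorot(L, h), "b2": np.zeros(h),
        "W_out": glorot(h, d), "b_out": np.zeros(d),
    }


def _forward_backward(X: np.ndarray, P: dict[str, np.ndarray], E: np.ndarray,
                      kl_weight: float) -> tuple[float, dict[str, np.ndarray]]:
    n = X.shape[0]
    pre1 = X @ P["W1"] + P["b1"]
    H = _softplus(pre1)
    M = H @ P["W_mu"] + P["b_mu"]
    LV = np.clip(H @ P["W_lv"] + P["b_lv"], -10, 10)
    S = np.exp(0.5 * LV)
    Z = M + S * E
    pre2 = Z @ P["W2"] + P["b2"]
    H2 = _softplus(pre2)
    Xh = H2 @ P["W_out"] + P["b_out"]

    recon = 0.5 * np.sum((X - Xh) ** 2) / n
    kl = 0.5 * np.sum(np.exp(LV) + M ** 2 - 1.0 - LV) / n
    loss = recon + kl_weight * kl

    dXh = (Xh - X) / n
    g: dict[str, np.ndarray] = {}
    g["W_out"] = H2.T @ dXh
    g["b_out"] = dXh.sum(0)
    dH2 = dXh @ P["W_out"].T
    dpre2 = dH2 * _sigmoid(pre2)
    g["W2"] = Z.T @ dpre2
    g["b2"] = dpre2.sum(0)
    dZ = dpre2 @ P["W2"].T
    dM = dZ + kl_weight * M / n
    dLV = dZ * E * 0.5 * S + kl_weight * 0.5 * (np.exp(LV) - 1.0) / n
    g["W_mu"] = H.T @ dM
    g["b_mu"] = dM.sum(0)
    g["W_lv"] = H.T @ dLV
    g["b_lv"] = dLV.sum(0)
    dH = dM @ P["W_mu"].T + dLV @ P["W_lv"].T
    dpre1 = dH * _sigmoid(pre1)
    g["W1"] = X.T @ dpre1
    g["b1"] = dpre1.sum(0)
    return float(loss), g


def fit_vae(X: np.ndarray | pd.DataFrame, config: VAEConfig,
            seed: int | None = None) -> dict:
    """Train the VAE on a (log-normalized) lipid matrix by stochastic gradient
    descent on the negative ELBO; returns the posterior means as the latent
    matrix along with the loss trace. Deterministic under a fixed seed.
    """
    index = X.index if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, float)
    n, d = X.shape
    cfg_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(cfg_seed)
    bs = config.batch_size or n
    if n < bs:
        raise ValueError(f"need n >= batch size ({n} < {bs})")
    P = _init_params(d, config.hidden_dim, config.latent_dim, rng)
    opt = _Adam(P, config.learning_rate)
    losses = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            E = rng.standard_normal((len(idx), config.latent_dim))
            loss, g = _forward_backward(X[idx], P, E, config.kl_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf ELBO at epoch {epoch}; lower the learning rate "
                    f"(lr={config.learning_rate}, loss trace tail={losses[-3:]})")
            opt.step(P, g)
            ep_loss += loss
            nb += 1
        losses.append(ep_loss / nb)
    # posterior means (deterministic encode)
    H = _softplus(X @ P["W1"] + P["b1"])
    M = H @ P["W_mu"] + P["b_mu"]
    H2 = _softplus(M @ P["W2"] + P["b2"])
    Xh = H2 @ P["W_out"] + P["b_out"]
    cols = [f"z{k + 1}" for k in range(config.latent_dim)]
    latent = pd.DataFrame(M, index=index, columns=cols)
    return {"latent": latent, "loss_trace": np.array(losses),
            "reconstruction": Xh, "params": P}


def en_select(latent: np.ndarray | pd.DataFrame, response: np.ndarray,
              en_alpha: float = 0.5, folds: int = 5,
              seed: int = 0, rel_tol: float = 0.05) -> list[int]:
    """Latent dimensions selected by elastic-net regression of the response.

    The penalty is chosen by ``folds``-fold cross-validated deviance (squared
    error for the numeric response); a dimension counts as selected when its
    coefficient is nonzero and non-negligible — above ``rel_tol`` times the
    largest absolute coefficient, which screens out the near-zero path
    coefficients the CV-minimum penalty tends to retain. ``en_alpha`` mixes L1
    and L2 (0.5 by default); at the ridge boundary (0) no coefficient is
    exactly zero, so all dimensions are returned. An all-zero model returns
    the empty list, signalling an uninformative repeat.
    """
    Z = np.asarray(latent, float)
    y = np.asarray(response, float)
    if len(y) != len(Z):
        raise ValueError("response length must match latent rows")
    if en_alpha == 0.0:
        return list(range(Z.shape[1]))
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(l1_ratio=en_alpha, cv=cv, max_iter=5000)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    c = np.abs(model.coef_)
    if c.max() == 0.0:
        return []
    return [int(j) for j in np.flatnonzero(c > rel_tol * c.max())]


def score_matrix(latent: np.ndarray | pd.DataFrame, selected: list[int],
                 targets: np.ndarray | pd.DataFrame, folds: int = 10,
                 seed: int = 0) -> float:
    """Average out-of-fold R^2 of a multi-response linear regression of
    ``targets`` on the selected latent dimensions, averaged over responses and
    folds. Empty selection scores -inf (sentinel for an uninformative repeat).
    """
    if not selected:
        return NEG_INF
    Z = np.asarray(latent, float)[:, list(selected)]
    Y = np.asarray(targets, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    r2s = []
    for tr, te in cv.split(Z):
        reg = LinearRegression().fit(Z[tr], Y[tr])
        pred = reg.predict(Z[te])
        ss_res = np.sum((Y[te] - pred) ** 2, axis=0)
        ss_tot = np.sum((Y[te] - Y[te].mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0),
                          np.where(ss_res == 0, 1.0, 0.0))
        r2s.append(r2.mean())
    return float(np.mean(r2s))


def vaen_run(X: pd.DataFrame, response: np.ndarray,
             targets: np.ndarray | pd.DataFrame,
             config: VAEConfig | None = None) -> LatentProfileSet:
    """Full latent-profile extraction: ``n_repeats`` independent VAE fits
    (seeds derived from the master seed), elastic-net dimension selection per
    repeat, CV R^2 scoring, and selection of the repeat with the highest
    average R^2.
    """
    if config is None:
        config = VAEConfig()
    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(config.n_repeats)]
    best = None
    diag = []
    for r, rs in enumerate(repeat_seeds):
        fit = fit_vae(X, config, seed=rs)
        dims = en_select(fit["latent"], response, en_alpha=config.en_alpha,
                         folds=5, seed=rs)
        r2 = score_matrix(fit["latent"], dims, targets, folds=10, seed=rs)
        diag.append({"repeat": r, "seed": rs, "n_selected": len(dims),
                     "average_R2": r2, "final_loss": float(fit["loss_trace"][-1])})
        if best is None or r2 > best[1]:
            best = (r, r2, fit["latent"], dims)
    diagnostics = pd.DataFrame(diag)
    if best is None or best[1] == NEG_INF:
        raise RuntimeError("no informative latent matrix: every repeat had an "
                           "empty elastic-net selection")
    r, r2, latent, dims = best
    cols = [latent.columns[j] for j in dims]
    return LatentProfileSet(latent=latent[cols].copy(), selected_dims=list(dims),
                            average_R2=r2, best_repeat=r, diagnostics=diagnostics)
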