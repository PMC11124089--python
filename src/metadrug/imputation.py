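"""Drug-response imputation: batch harmonization, response power transform,
variance-based gene selection, per-drug ridge models, and patient prediction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RidgeModel",
    "RidgeModelBundle",
    "harmonize_expression",
    "power_transform_response",
    "select_variable_genes",
    "fit_ridge",
    "train_drug_models",
    "impute",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 4, 25)


# ---------------------------------------------------------------------------
# ComBat-style two-batch empirical-Bayes location/scale harmonization
# ---------------------------------------------------------------------------

def _eb_iterate(z: np.ndarray, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior,
                tol: float = 1e-4, max_iter: int = 200):
    """Parametric empirical-Bayes iteration for one batch (genes x samples)."""
    n = z.shape[1]
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + delta_star * gamma_bar) / (n * tau2 + delta_star)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - gamma_star).max() / np.abs(gamma_star).max() if np.abs(gamma_star).max() > 0 else 0.0,
            np.abs(d_new - delta_star).max() / np.abs(delta_star).max(),
        )
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


def harmonize_expression(
    train_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    min_common_genes: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to common genes and remove the batch effect
    between them with a two-batch empirical-Bayes location/scale adjustment.

    Returns the adjusted (train, target) pair, split back by source.
    """
    if train_expr.shape[1] < 2 or target_expr.shape[1] < 2:
        raise ValueError("each batch needs at least 2 samples")
    common = train_expr.index.intersection(target_expr.index)
    if len(common) == 0:
        raise ValueError("expression matrices share no genes")
    if len(common) < min_common_genes:
        raise ValueError(
            f"only {len(common)} common genes, below floor {min_common_genes}"
        )
    a = train_expr.loc[common]
    b = target_expr.loc[common]
    # genes must vary within both batches for the standardization to hold
    ok = (a.var(axis=1, ddof=1) > 0) & (b.var(axis=1, ddof=1) > 0)
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} zero-variance genes from harmonization",
            stacklevel=2,
        )
        a, b = a.loc[ok], b.loc[ok]

    x = np.hstack([a.to_numpy(float), b.to_numpy(float)])
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    batches = [slice(0, n1), slice(n1, n)]
    batch_means = np.stack([x[:, s].mean(axis=1) for s in batches], axis=1)
    grand = batch_means @ np.array([n1 / n, n2 / n])
    fitted = np.empty_like(x)
    for i, s in enumerate(batches):
        fitted[:, s] = batch_means[:, [i]]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    sd_pooled = np.sqrt(var_pooled)
    z = (x - grand[:, None]) / sd_pooled[:, None]

    adjusted = np.empty_like(z)
    for i, s in enumerate(batches):
        zb = z[:, s]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        gamma_star, delta_star = _eb_iterate(
            zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior
        )
        adjusted[:, s] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
    adjusted = adjusted * sd_pooled[:, None] + grand[:, None]

    out_a = pd.DataFrame(adjusted[:, batches[0]], index=a.index, columns=a.columns)
    out_b = pd.DataFrame(adjusted[:, batches[1]], index=b.index, columns=b.columns)
    return out_a, out_b


# ---------------------------------------------------------------------------
# Response power transform
# ---------------------------------------------------------------------------

def power_transform_response(
    auc: np.ndarray | pd.Series,
    lambda_grid: np.ndarray | None = None,
    eps: float = 1e-3,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Shift to strict positivity then Box-Cox with a grid-MLE exponent.

    Returns (transformed values, (shift, exponent)). Exponent 1 means
    identity up to the shift.
    """
    vals = np.asarray(auc, dtype=float)
    vals = vals[np.isfinite(vals)] if np.isnan(vals).any() else vals
    if len(vals) < 10:
        raise ValueError("power transform requires at least 10 finite values")
    if np.ptp(vals) == 0:
        warnings.warn("constant response vector; identity transform", stacklevel=2)
        return vals.copy(), (0.0, 1.0)
    shift = max(0.0, eps - vals.min())
    shifted = vals + shift
    grid = np.linspace(-2.0, 2.0, 81) if lambda_grid is None else np.asarray(lambda_grid)
    llf = np.array([stats.boxcox_llf(lam, shifted) for lam in grid])
    lam = float(grid[np.argmax(llf)])
    transformed = stats.boxcox(shifted, lmbda=lam)
    return transformed, (shift, lam)


def apply_power_transform(auc: np.ndarray | pd.Series, params: tuple[float, float]) -> np.ndarray:
    shift, lam = params
    return stats.boxcox(np.asarray(auc, float) + shift, lmbda=lam)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def select_variable_genes(expr: pd.DataFrame, fraction: float = 0.5) -> list[str]:
    """Top ``ceil(fraction * G)`` genes by variance across samples.

    Ties at the cut are broken by gene-id lexicographic order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    variances = expr.var(axis=1, ddof=1)
    k = math.ceil(fraction * len(variances))
    order = np.lexsort((expr.index.to_numpy(), -variances.to_numpy()))
    return [expr.index[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# Ridge regression with seeded k-fold CV over a log-spaced penalty grid
# ---------------------------------------------------------------------------

@dataclass
class RidgeModel:
    genes: list[str]
    coef: np.ndarray  # on the standardized-predictor scale
    intercept: float
    gene_means: np.ndarray
    gene_sds: np.ndarray
    lam: float
    transform_params: tuple[float, float] = (0.0, 1.0)
    n_train: int = 0

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise ValueError(f"model genes missing from matrix: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        x = expr.loc[self.genes].to_numpy(float).T
        xs = (x - self.gene_means) / self.gene_sds
        return pd.Series(self.intercept + xs @ self.coef, index=expr.columns)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "lambda": self.lam,
            "transform_params": list(self.transform_params),
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeModel":
        return cls(
            genes=list(d["genes"]),
            coef=np.asarray(d["coef"], float),
            intercept=float(d["intercept"]),
            gene_means=np.asarray(d["gene_means"], float),
            gene_sds=np.asarray(d["gene_sds"], float),
            lam=float(d["lambda"]),
            transform_params=tuple(d["transform_params"]),
            n_train=int(d["n_train"]),
        )


@dataclass
class RidgeModelBundle:
    models: dict[str, RidgeModel] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "models": {d: m.to_dict() for d, m in self.models.items()},
            "skipped": self.skipped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeModelBundle":
        return cls(
            models={k: RidgeModel.from_dict(v) for k, v in d["models"].items()},
            skipped=dict(d.get("skipped", {})),
        )


def _ridge_solve_svd(u, s, vt, y, lam):
    # beta = V diag(s/(s^2+lam)) U' y for centered, standardized X
    return vt.T @ ((s / (s**2 + lam)) * (u.T @ y))


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def fit_ridge(
    expr: pd.DataFrame,
    response: pd.Series,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 10,
    seed: int = 0,
    transform_params: tuple[float, float] = (0.0, 1.0),
    one_se_rule: bool = True,
) -> RidgeModel:
    """Fit one drug's ridge model on column-standardized predictors.

    The penalty is chosen by seeded k-fold cross-validation over the grid
    plus an intercept-only sentinel; with ``one_se_rule`` the largest
    penalty within one standard error of the CV minimum is taken, so drugs
    whose response carries no expression signal degenerate to a constant
    model instead of a noise fit. The intercept is unpenalized (handled by
    centering).
    """
    samples = [s for s in expr.columns if s in response.index]
    y_all = response.loc[samples].astype(float)
    mask = np.isfinite(y_all.to_numpy())
    samples = [s for s, m in zip(samples, mask) if m]
    if len(samples) < 10:
        raise ValueError(f"need >= 10 training samples, have {len(samples)}")
    x = expr[samples].to_numpy(float).T  # samples x genes
    y = y_all.loc[samples].to_numpy(float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    xs = (x - means) / sds
    y_mean = y.mean()
    yc = y - y_mean

    n = len(y)
    k = min(n_folds, n)
    folds = _kfold_indices(n, k, np.random.default_rng(seed))
    grid = np.asarray(lambda_grid, float)
    # last column is the intercept-only sentinel (lambda = +inf)
    fold_mse = np.zeros((k, len(grid) + 1))
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx, assume_unique=False)
        xt, yt = xs[train_idx], yc[train_idx]
        xv, yv = xs[val_idx], yc[val_idx]
        mu = yt.mean()
        u, s, vt = np.linalg.svd(xt, full_matrices=False)
        uty = u.T @ (yt - mu)
        for gi, lam in enumerate(grid):
            beta = vt.T @ ((s / (s**2 + lam)) * uty)
            pred = mu + xv @ beta
            fold_mse[fi, gi] = ((yv - pred) ** 2).mean()
        fold_mse[fi, -1] = ((yv - mu) ** 2).mean()
    mean_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(mean_mse))
    if one_se_rule and k > 1:
        # largest penalty whose CV error is within 1 SE of the minimum;
        # drugs with no predictive signal collapse to the intercept model
        se = fold_mse[:, best].std(ddof=1) / np.sqrt(k)
        eligible = np.flatnonzero(mean_mse <= mean_mse[best] + se)
        best = int(eligible.max())
    if best == len(grid):  # intercept-only model selected
        return RidgeModel(
            genes=list(expr.index),
            coef=np.zeros(xs.shape[1]),
            intercept=y_mean,
            gene_means=means,
            gene_sds=sds,
            lam=math.inf,
            transform_params=transform_params,
            n_train=n,
        )
    lam = float(grid[best])

    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    beta = _ridge_solve_svd(u, s, vt, yc, lam)
    return RidgeModel(
        genes=list(expr.index),
        coef=beta,
        intercept=y_mean,
        gene_means=means,
        gene_sds=sds,
        lam=lam,
        transform_params=transform_params,
        n_train=n,
    )


def train_drug_models(
    expr: pd.DataFrame,
    measured: pd.DataFrame,
    feature_fraction: float = 0.5,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 10,
    seed: int = 0,
    one_se_rule: bool = True,
) -> RidgeModelBundle:
    """Per-drug pipeline: power-transform response, select variable genes,
    fit ridge. Drugs with < 10 complete cases are skipped with a reason.
    """
    genes = select_variable_genes(expr, feature_fraction)
    sub = expr.loc[genes]
    bundle = RidgeModelBundle()
    for k, drug in enumerate(measured.columns):
        y = measured[drug].dropna()
        y = y[y.index.isin(sub.columns)]
        if len(y) < 10:
            reason = f"only {len(y)} complete cases (need >= 10)"
            logger.warning("skipping drug %s: %s", drug, reason)
            bundle.skipped[drug] = reason
            continue
        try:
            transformed, params = power_transform_response(y.to_numpy())
        except ValueError as exc:
            bundle.skipped[drug] = str(exc)
            continue
        y_t = pd.Series(transformed, index=y.index)
        bundle.models[drug] = fit_ridge(
            sub[y.index], y_t, lambda_grid=lambda_grid, n_folds=n_folds,
            seed=seed + k, transform_params=params, one_se_rule=one_se_rule,
        )
    return bundle


def impute(models: RidgeModelBundle, patient_expr: pd.DataFrame) -> pd.DataFrame:
    """Predicted response (transformed-AUC scale) per patient x drug."""
    cols = {}
    for drug, model in models.models.items():
        cols[drug] = model.predict(patient_expr)
    if not cols:
        raise ValueError("model bundle contains no trained models")
    return pd.DataFrame(cols)
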