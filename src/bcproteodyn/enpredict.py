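"""Nested cross-validated elastic-net prediction of drug response.

The procedure mirrors the published pharmacoproteomic modeling pipeline:

1. *inner tuning* — the elastic-net mixing parameter alpha and penalty
   strength lambda are chosen by minimising the mean CV error over several
   replicates of k-fold cross-validation on a (alpha, lambda-path) grid;
2. *bootstrap averaging* — the tuned model is refit on many random 90 %
   subsamples of the cell lines (without replacement) and the coefficient
   vectors averaged; predictors are ranked by the magnitude of the average
   coefficient;
3. *top-k selection* — ordinary least squares on the top-k predictors is
   scored by 10-fold CV for k = 1..k_max, and k is the smallest value whose
   CV error lies within one standard error of the minimum (the 1-SE rule);
4. *outer evaluation* — the whole of 1-3 is re-run inside a leave-one-out
   loop over cell lines, so the held-out prediction never sees the held-out
   line (standardisation parameters included); predictive power is the
   Pearson correlation between observed and LOO-predicted responses.

The penalised objective solved at each fit is the standard elastic net

    (1/2n) * ||y - b0 - X b||^2 + lambda * ( alpha*||b||_1
                                             + (1-alpha)/2 * ||b||_2^2 )

delegated to scikit-learn's coordinate-descent solver (``ElasticNet`` with
``alpha=lambda`` and ``l1_ratio=alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import OmicsMatrix, logger


# ---------------------------------------------------------------------------
# kNN imputation (feature-neighbour semantics)
# ---------------------------------------------------------------------------

def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing entries from the k nearest *features*.

    For each feature with missing cells, the k features closest in
    mean-squared-difference over co-observed samples (and observed in the
    target sample) supply the imputed value as their mean in that sample.
    Observed entries are never altered.  A feature with zero observed values
    is an error — filter first.
    """
    imputer = KNNFeatureImputer(n_neighbors=k)
    values = imputer.fit_transform(m.values.to_numpy(dtype=float).T).T
    return OmicsMatrix(m.layer_name,
                       pd.DataFrame(values, index=m.values.index,
                                    columns=m.values.columns))


class KNNFeatureImputer(BaseEstimator):
    """Impute a samples x features matrix from nearest features.

    Distances between features are mean squared differences over co-observed
    samples (scale-corrected for unequal overlap, as in expression-matrix
    kNN imputation); for each missing cell the ``n_neighbors`` nearest
    features that are observed in that sample contribute their mean.
    Features with no co-observed overlap are at infinite distance.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_all_finite="allow-nan", dtype=float)
        if (~np.isnan(X)).sum(axis=0).min() == 0:
            raise ValueError(
                "feature(s) with zero observed values cannot be imputed; "
                "filter them first"
            )
        self.is_fitted_ = True
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False,
                          ensure_all_finite="allow-nan", dtype=float)
        out = X.copy()
        obs = ~np.isnan(X)
        if obs.all():
            return out
        Xz = np.where(obs, X, 0.0)
        obs_f = obs.astype(float)
        # pairwise sum of squared differences over co-observed samples
        sq = Xz ** 2
        co = obs_f.T @ obs_f
        cross = Xz.T @ Xz
        ssq_a = sq.T @ obs_f
        ssd = ssq_a + ssq_a.T - 2.0 * cross
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = ssd / co
        dist[co == 0] = np.inf
        np.fill_diagonal(dist, np.inf)

        n_samples, n_features = X.shape
        for j in range(n_features):
            missing_rows = np.where(~obs[:, j])[0]
            if len(missing_rows) == 0:
                continue
            order = np.argsort(dist[j], kind="stable")
            for i in missing_rows:
                # nearest features observed in sample i, finite distance
                cand = order[np.isfinite(dist[j, order]) & obs[i, order]]
                if len(cand) == 0:
                    # no informative neighbour: fall back to the feature mean
                    out[i, j] = X[obs[:, j], j].mean()
                    continue
                out[i, j] = X[i, cand[: self.n_neighbors]].mean()
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ENConfig:
    """Grids and budgets of the nested elastic-net procedure.

    ``preset("paper")`` follows the published settings (alpha grid 0.1..1.0
    step 0.1, 10 replicates of 10-fold inner CV, 200 bootstrap fits on 90 %
    subsamples); ``preset("fast")`` is the same code path at desk scale.
    """

    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    n_lambdas: int = 100
    lambda_eps: float = 1e-2
    cv_folds: int = 10
    cv_reps: int = 10
    n_boot: int = 200
    subsample_fraction: float = 0.9
    k_max: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        for a in self.alpha_grid:
            if not 0 < a <= 1:
                raise ValueError("alpha values must be in (0, 1]")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "ENConfig":
        if name == "paper":
            return cls(seed=seed)
        if name == "fast":
            return cls(alpha_grid=(0.1, 0.5, 1.0), n_lambdas=12,
                       cv_folds=5, cv_reps=3, n_boot=50, k_max=50,
                       tol=1e-3, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class ENResult:
    """Per-drug outcome of the nested procedure."""

    drug: str
    alpha: float
    lam: float
    coef_mean: pd.Series
    ranking: list[str]
    k: int
    top_k: list[str]
    predictions: pd.Series           # LOO predictions, indexed by cell line
    predictive_power: float
    n_lines_used: int
    valid: bool = True


# ---------------------------------------------------------------------------
# elementary fits
# ---------------------------------------------------------------------------

def fit_elastic_net(X, y, alpha: float, lam: float, tol: float = 1e-6):
    """Single elastic-net fit; returns ``(intercept, coefficients)``.

    Deterministic for fixed inputs.  A degenerate design with zero columns
    yields an intercept-only model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per response value")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if X.shape[1] == 0:
        return float(np.mean(y)), np.zeros(0)
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                       max_iter=10000, tol=tol)
    model.fit(X, y)
    return float(model.intercept_), model.coef_.copy()


def _lambda_path(X, y, alpha: float, n_lambdas: int, eps: float) -> np.ndarray:
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / (len(y) * alpha)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def _standardize(train: np.ndarray, binary_mask: np.ndarray | None):
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    if binary_mask is not None:
        mean = np.where(binary_mask, 0.0, mean)
        scale = np.where(binary_mask, 1.0, scale)
    scale = np.where(scale == 0, 1.0, scale)
    return mean, scale


def tune_hyperparams(X, y, cfg: ENConfig, rng: np.random.Generator
                     ) -> tuple[float, float]:
    """Choose (alpha, lambda) minimising replicated k-fold CV error.

    The lambda path per alpha is geometric from the critical lambda of the
    full data down by ``lambda_eps``; CV MSE is averaged over ``cv_reps``
    independent fold partitions.  Ties prefer the larger lambda, then the
    larger alpha (the sparser model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = min(cfg.cv_folds, n)
    if folds < cfg.cv_folds:
        logger.warning("reducing CV folds from %d to %d (n=%d)",
                       cfg.cv_folds, folds, n)
    alphas = sorted(cfg.alpha_grid)
    paths = {a: _lambda_path(X, y, a, cfg.n_lambdas, cfg.lambda_eps)
             for a in alphas}
    sse = {a: np.zeros(cfg.n_lambdas) for a in alphas}
    count = 0
    for _rep in range(cfg.cv_reps):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        for tr, te in kf.split(X):
            Xtr, ytr = X[tr], y[tr]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr = (Xtr - mu) / sd
            Xte = (X[te] - mu) / sd
            ym = ytr.mean()
            for a in alphas:
                _, coefs, _ = enet_path(Xtr, ytr - ym, l1_ratio=a,
                                        alphas=paths[a], tol=cfg.tol)
                pred = Xte @ coefs + ym
                sse[a] += ((pred - y[te][:, None]) ** 2).sum(axis=0)
        count += 1
    best = None
    for a in alphas:                      # ascending alpha
        mse = sse[a] / (count * n)
        for li in range(cfg.n_lambdas):   # descending lambda
            key = (mse[li], li, -a)       # ties -> larger lambda, larger alpha
            if best is None or key < best[0]:
                best = (key, a, paths[a][li])
    return best[1], float(best[2])


def bootstrap_coefficients(X, y, alpha: float, lam: float, cfg: ENConfig,
                           rng: np.random.Generator):
    """Average coefficients over ``n_boot`` elastic-net fits on random
    ``subsample_fraction`` subsets of the lines (without replacement).

    Returns ``(mean_coefs, per_run_matrix, ranking_indices)`` with the
    ranking by descending ``|mean coefficient|``, ties by feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    m = int(np.floor(cfg.subsample_fraction * n))
    if m < 3:
        raise ValueError("bootstrap subsample smaller than 3 lines")
    runs = np.empty((cfg.n_boot, X.shape[1]))
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                       max_iter=10000, tol=cfg.tol)
    for b in range(cfg.n_boot):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        model.fit(X[idx], y[idx])
        runs[b] = model.coef_
    mean = runs.mean(axis=0)
    ranking = np.lexsort((np.arange(len(mean)), -np.abs(mean)))
    return mean, runs, ranking


def _cv_ols_mse(X, y, splits) -> np.ndarray:
    """Per-fold MSE of intercept-augmented OLS over fixed CV splits."""
    mses = []
    for tr, te in splits:
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), X[te]]) @ coef
        mses.append(float(np.mean((pred - y[te]) ** 2)))
    return np.array(mses)


def select_top_k(X, y, ranking, cfg: ENConfig, rng: np.random.Generator) -> int:
    """1-SE rule over OLS models on the top-k ranked predictors.

    For k = 1..k_max, the top-k OLS model is scored by 10-fold CV over one
    common fold partition (so the curves are comparable across k); the
    selected k is the smallest whose CV error is within one standard error
    of the minimum.
    """
    ranking = np.asarray(ranking)
    if len(ranking) == 0:
        raise ValueError("empty predictor ranking")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    k_max = int(min(cfg.k_max, len(ranking), max(n - 2, 1)))
    kf = KFold(n_splits=min(10, n), shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    splits = list(kf.split(X))
    cvs, ses = np.empty(k_max), np.empty(k_max)
    for k in range(1, k_max + 1):
        mses = _cv_ols_mse(X[:, ranking[:k]], y, splits)
        cvs[k - 1] = mses.mean()
        ses[k - 1] = (mses.std(ddof=1) / np.sqrt(len(mses))
                      if len(mses) > 1 else 0.0)
    kmin = int(np.argmin(cvs))
    threshold = cvs[kmin] + ses[kmin]
    return int(np.where(cvs <= threshold)[0][0]) + 1


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class NestedElasticNet(BaseEstimator, RegressorMixin):
    """Elastic-net predictor with bootstrap-averaged top-k refit.

    ``fit`` runs tuning, bootstrap coefficient averaging, 1-SE top-k
    selection and an OLS refit on the selected predictors; ``predict`` uses
    the refit model.  All randomness derives from ``random_state``.

    Parameters
    ----------
    config : ENConfig
        Grids and budgets (see :class:`ENConfig`).
    binary_features : array-like of bool, optional
        Columns to exclude from standardisation (e.g. mutation indicators).

    Attributes
    ----------
    alpha_, lambda_ : tuned hyperparameters
    coef_mean_ : bootstrap-averaged coefficients (standardised scale)
    ranking_ : column indices by descending |mean coefficient|
    k_ : selected model size
    selected_ : column indices of the top-k predictors
    coef_, intercept_ : the final OLS refit on the selected predictors
    """

    def __init__(self, config: ENConfig | None = None,
                 binary_features=None, random_state: int = 0):
        self.config = config
        self.binary_features = binary_features
        self.random_state = random_state

    def _cfg(self) -> ENConfig:
        return self.config if self.config is not None else ENConfig.preset("fast")

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float, y_numeric=True)
        if np.std(y) == 0:
            raise ValueError("constant response: model undefined")
        cfg = self._cfg()
        rng = np.random.default_rng(self.random_state)
        mask = (np.asarray(self.binary_features, dtype=bool)
                if self.binary_features is not None else None)
        self.x_mean_, self.x_scale_ = _standardize(X, mask)
        Xs = (X - self.x_mean_) / self.x_scale_
        self.alpha_, self.lambda_ = tune_hyperparams(Xs, y, cfg, rng)
        self.coef_mean_, self.boot_runs_, self.ranking_ = \
            bootstrap_coefficients(Xs, y, self.alpha_, self.lambda_, cfg, rng)
        self.k_ = select_top_k(Xs, y, self.ranking_, cfg, rng)
        self.selected_ = self.ranking_[: self.k_]
        A = np.column_stack([np.ones(len(y)), Xs[:, self.selected_]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        Xs = (X - self.x_mean_) / self.x_scale_
        return Xs[:, self.selected_] @ self.coef_ + self.intercept_


# ---------------------------------------------------------------------------
# outer evaluation and layer comparison
# ---------------------------------------------------------------------------

def loocv_evaluate(X: pd.DataFrame, y: pd.Series, cfg: ENConfig | None = None,
                   drug: str = "", binary_features=None,
                   seed: int = 0) -> ENResult:
    """Leave-one-out evaluation of the full nested procedure.

    Every fold re-runs tuning, bootstrap averaging, top-k selection and the
    OLS refit on the remaining lines only (standardisation included), then
    predicts the held-out line.  The reported hyperparameters, ranking and k
    come from one final fit on all lines; ``predictive_power`` is the Pearson
    r between observed and LOO-predicted responses.
    """
    cfg = cfg if cfg is not None else ENConfig.preset("fast")
    if y.isna().any():
        X, y = X.loc[y.notna()], y.dropna()
    n = len(y)
    if n < 10:
        logger.warning("drug %s: only %d lines with response; model invalid",
                       drug, n)
        return ENResult(drug, np.nan, np.nan, pd.Series(dtype=float), [], 0,
                        [], pd.Series(dtype=float), np.nan, n, valid=False)
    if y.std() == 0:
        raise ValueError("constant response: predictive power undefined")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        est = NestedElasticNet(config=cfg, binary_features=binary_features,
                               random_state=seed + i + 1)
        est.fit(Xv[keep], yv[keep])
        preds[i] = est.predict(Xv[i][None, :])[0]
    final = NestedElasticNet(config=cfg, binary_features=binary_features,
                             random_state=seed)
    final.fit(Xv, yv)
    if np.std(preds) == 0:
        power = 0.0
    else:
        power = float(stats.pearsonr(yv, preds)[0])
    features = list(X.columns)
    return ENResult(
        drug=drug, alpha=final.alpha_, lam=final.lambda_,
        coef_mean=pd.Series(final.coef_mean_, index=features),
        ranking=[features[i] for i in final.ranking_],
        k=final.k_, top_k=[features[i] for i in final.selected_],
        predictions=pd.Series(preds, index=y.index),
        predictive_power=power, n_lines_used=n,
    )


def assemble_features(layers: dict[str, OmicsMatrix],
                      cell_lines) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (lines x features) from cell-line-level layers.

    Columns are tagged ``"<layer>:<feature>"``; the returned boolean mask
    marks mutation columns (left binary, never standardised).  Intensity
    layers must already be imputed (no missing values).
    """
    blocks, mask = [], []
    for tag in sorted(layers):
        m = layers[tag]
        block = m.values.T.loc[list(cell_lines)]
        if m.layer_name != "mutation" and block.isna().any().any():
            raise ValueError(f"layer {tag!r} has missing values; impute first")
        block.columns = [f"{tag}:{f}" for f in block.columns]
        blocks.append(block)
        mask.extend([m.layer_name == "mutation"] * block.shape[1])
    X = pd.concat(blocks, axis=1)
    return X, np.array(mask, dtype=bool)


def compare_layer_combos(layers: dict[str, OmicsMatrix],
                         response, drugs, combos,
                         cfg: ENConfig | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Predictive power per (drug, layer combo) as a long-format table.

    ``combos`` are strings over layer tags, e.g. ``["D", "E", "DE", "MDE"]``.
    Drugs with fewer than 10 observed responses yield invalid rows (NaN
    power); empty combos are skipped with a warning.
    """
    rows = []
    for combo in combos:
        chosen = {tag: layers[tag] for tag in combo if tag in layers}
        if len(chosen) < len(combo):
            logger.warning("combo %s: missing layer(s); skipped", combo)
            continue
        for drug in drugs:
            y = response.response(drug)
            lines = [l for l in y.index if all(
                l in m.sample_ids for m in chosen.values())]
            X, mask = assemble_features(chosen, lines)
            res = loocv_evaluate(X, y.loc[lines], cfg, drug=drug,
                                 binary_features=mask, seed=seed)
            rows.append((drug, combo, res.predictive_power,
                         res.n_lines_used, res.valid))
    return pd.DataFrame(rows, columns=["drug", "combo", "predictive_power",
                                       "n_lines", "valid"])


def paired_combo_test(table: pd.DataFrame, combo_a: str, combo_b: str):
    """Paired t-test of predictive power between two combos over drugs."""
    a = table[table["combo"] == combo_a].set_index("drug")["predictive_power"]
    b = table[table["combo"] == combo_b].set_index("drug")["predictive_power"]
    common = a.index.intersection(b.index)
    t, p = stats.ttest_rel(a.loc[common], b.loc[common])
    return float(t), float(p)
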