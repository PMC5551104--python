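"""Presence-background maximum-entropy SDM (MaxEnt) re-implementation.

The model is the Gibbs distribution over background cells that maximizes
the L1-regularized presence log-likelihood

    L(lambda) = mean_presence(eta) - log sum_bg exp(eta) - sum_j beta_j |lambda_j|

with eta(cell) = lambda . f(cell) over an automatic feature expansion
(linear, quadratic, product, hinge) of the environmental covariates, all
features scaled to [0, 1] on the background sample. This mirrors the
behavior of the classic desktop MaxEnt (v3.3-era defaults): feature classes
switch on with presence sample size (hinge at n >= 15, products at n >= 80),
per-feature regularization beta_j scales a class default by the presence SD
of the feature over sqrt(n), and the logistic output is
tau*e^H*raw / (1 + tau*e^H*raw) with prevalence tau = 0.5 and H the entropy
of the fitted distribution.

Fitting is cyclic coordinate descent with prox-Newton soft-threshold
updates; the objective is concave, so the optimum is unique up to features
that are linearly dependent on the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .grid import EnvStack

# class-default regularization: interpolated over presence count,
# following the classic MaxEnt tables
_BETA_LQP_N = np.array([0.0, 10.0, 30.0, 100.0])
_BETA_LQP = np.array([1.0, 1.0, 0.2, 0.05])
_BETA_HINGE = 0.5
# presence-SD clamp for linear/quadratic/product features: the floor keeps
# beta_j > 0 for features (nearly) constant on presences, the ceiling is the
# maximum SD of a [0,1]-valued feature
_SD_FLOOR = 0.05
_SD_CEIL = 0.5


@dataclass
class BackgroundSample:
    """Covariates of cells sampled uniformly from the study mask."""

    X: np.ndarray            # (n_bg, k)
    rows: np.ndarray
    cols: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.X.shape[0]


def sample_background(components: EnvStack, n_bg: int = 10000,
                      seed: int = 0) -> BackgroundSample:
    """Sample ``n_bg`` cells uniformly without replacement from the mask
    (all cells if the mask holds fewer than ``n_bg``)."""
    rows, cols = np.nonzero(components.mask)
    rng = np.random.default_rng(seed)
    if len(rows) > n_bg:
        pick = rng.choice(len(rows), size=n_bg, replace=False)
        rows, cols = rows[pick], cols[pick]
    return BackgroundSample(X=components.values_at(rows, cols),
                            rows=rows, cols=cols, seed=seed)


class FeatureExpansion:
    """MaxEnt feature expansion with background min/max scaling to [0, 1].

    Feature classes are activated by the presence sample size ``n``:
    linear and quadratic always, hinge (both orientations, ``n_knots``
    equally spaced interior knots per covariate) when n >= hinge_threshold,
    pairwise products when n >= product_threshold. Features constant on
    the background are dropped. Values outside the background range are
    clamped into [0, 1].
    """

    def __init__(self, background_X: np.ndarray, n_presence: int,
                 n_knots: int = 20, hinge_threshold: int = 15,
                 product_threshold: int = 80):
        bg = np.atleast_2d(np.asarray(background_X, float))
        k = bg.shape[1]
        if k == 0:
            raise ValueError("need at least one covariate")
        self.n_covariates = k
        self.use_hinge = n_presence >= hinge_threshold
        self.use_product = n_presence >= product_threshold
        self.cov_min = bg.min(axis=0)
        self.cov_max = bg.max(axis=0)

        defs: list[tuple] = [("linear", i) for i in range(k)]
        defs += [("quadratic", i) for i in range(k)]
        if self.use_product:
            defs += [("product", i, j) for i in range(k) for j in range(i + 1, k)]
        if self.use_hinge:
            for i in range(k):
                knots = np.linspace(self.cov_min[i], self.cov_max[i],
                                    n_knots + 2)[1:-1]
                defs += [("hinge_up", i, t) for t in knots]
                defs += [("hinge_down", i, t) for t in knots]

        raw = self._raw(bg, defs)
        fmin, fmax = raw.min(axis=0), raw.max(axis=0)
        keep = fmax > fmin
        self.definitions = [d for d, k_ in zip(defs, keep) if k_]
        self.f_min = fmin[keep]
        self.f_max = fmax[keep]
        self.classes = np.array([d[0].split("_")[0] for d in self.definitions])

    @property
    def n_features(self) -> int:
        return len(self.definitions)

    @staticmethod
    def _raw(X: np.ndarray, defs: list[tuple]) -> np.ndarray:
        cols = []
        for d in defs:
            kind = d[0]
            if kind == "linear":
                cols.append(X[:, d[1]])
            elif kind == "quadratic":
                cols.append(X[:, d[1]] ** 2)
            elif kind == "product":
                cols.append(X[:, d[1]] * X[:, d[2]])
            elif kind == "hinge_up":
                cols.append(np.maximum(X[:, d[1]] - d[2], 0.0))
            elif kind == "hinge_down":
                cols.append(np.maximum(d[2] - X[:, d[1]], 0.0))
            else:  # pragma: no cover
                raise ValueError(kind)
        return np.column_stack(cols)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scaled feature matrix in [0, 1] (out-of-range values clamped)."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_covariates:
            raise ValueError("covariate dimension mismatch")
        raw = self._raw(X, self.definitions)
        scaled = (raw - self.f_min) / (self.f_max - self.f_min)
        return np.clip(scaled, 0.0, 1.0)


def _class_beta(classes: np.ndarray, n_presence: int) -> np.ndarray:
    lqp = float(np.interp(n_presence, _BETA_LQP_N, _BETA_LQP))
    table = {"linear": lqp, "quadratic": lqp, "product": lqp,
             "hinge": _BETA_HINGE}
    return np.array([table[c] for c in classes])


class MaxentModel(BaseEstimator):
    """L1-regularized maximum-entropy presence-background model.

    Scikit-learn-style estimator: ``fit(X, y)`` with ``y = 1`` for
    presence rows and ``y = 0`` for background rows; the background rows
    define both the feature scaling and the normalization of the Gibbs
    distribution.

    Parameters
    ----------
    beta_multiplier : float
        Global multiplier on the per-feature regularization (MaxEnt's
        ``betamultiplier``); 0 disables regularization.
    tol : float
        Convergence threshold on the relative objective change per sweep.
    max_iter : int
        Maximum coordinate-descent sweeps; exceeding it sets
        ``converged_ = False`` (never silent).
    tau : float
        Assumed prevalence of the logistic output.

    Attributes
    ----------
    weights_ : (n_features,) fitted feature weights.
    features_ : the fitted :class:`FeatureExpansion`.
    beta_ : per-feature regularization actually used.
    log_z_ : log normalizer over the background.
    entropy_ : entropy H of the fitted distribution over the background.
    converged_ : bool; n_iter_ : sweeps used.
    """

    def __init__(self, beta_multiplier: float = 1.0, tol: float = 1e-5,
                 max_iter: int = 500, n_knots: int = 20,
                 hinge_threshold: int = 15, product_threshold: int = 80,
                 tau: float = 0.5):
        self.beta_multiplier = beta_multiplier
        self.tol = tol
        self.max_iter = max_iter
        self.n_knots = n_knots
        self.hinge_threshold = hinge_threshold
        self.product_threshold = product_threshold
        self.tau = tau

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            init_weights: np.ndarray | None = None) -> "MaxentModel":
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y)
        presence_X, background_X = X[y == 1], X[y == 0]
        n = presence_X.shape[0]
        if n < 1:
            raise ValueError("no presence rows (y == 1)")
        if background_X.shape[0] < 2:
            raise ValueError("need background rows (y == 0)")

        feats = FeatureExpansion(
            background_X, n, n_knots=self.n_knots,
            hinge_threshold=self.hinge_threshold,
            product_threshold=self.product_threshold)
        F_bg = feats.transform(background_X)
        F_pr = feats.transform(presence_X)
        p_mean = F_pr.mean(axis=0)
        # hinge features use a constant deviation term (as in maxnet, the
        # reference re-implementation); lqp features use the clamped
        # presence SD
        sd_pr = np.clip(F_pr.std(axis=0), _SD_FLOOR, _SD_CEIL)
        sd_pr[feats.classes == "hinge"] = 1.0
        beta = self.beta_multiplier * _class_beta(feats.classes, n) * sd_pr / np.sqrt(n)

        lam, log_z, n_iter, converged = self._optimize(
            F_bg, p_mean, beta, init_weights)

        self.features_ = feats
        self.weights_ = lam
        self.beta_ = beta
        self.log_z_ = log_z
        self.n_presence_ = n
        self.presence_means_ = p_mean
        w = np.exp(F_bg @ lam - log_z)
        self.entropy_ = float(-np.sum(w * np.log(np.clip(w, 1e-300, None))))
        self.background_expectations_ = w @ F_bg
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def _optimize(self, F_bg, p_mean, beta, init_weights):
        n_bg, J = F_bg.shape
        lam = (np.zeros(J) if init_weights is None
               else np.asarray(init_weights, float).copy())
        eta = F_bg @ lam
        log_z = logsumexp(eta)
        w = np.exp(eta - log_z)
        obj = p_mean @ lam - log_z - beta @ np.abs(lam)
        converged = False
        for sweep in range(1, self.max_iter + 1):
            for j in range(J):
                fj = F_bg[:, j]
                u = w @ fj
                grad = p_mean[j] - u
                # zero weight staying zero: subgradient condition
                if lam[j] == 0.0 and abs(grad) <= beta[j]:
                    continue
                var = w @ (fj * fj) - u * u
                if var < 1e-12:
                    continue
                target = lam[j] + grad / var
                new = np.sign(target) * max(abs(target) - beta[j] / var, 0.0)
                delta = np.clip(new - lam[j], -5.0, 5.0)
                with np.errstate(divide="ignore"):
                    log_w = np.log(w)
                # backtracking: the quadratic model can overshoot
                for _ in range(30):
                    cand = lam[j] + delta
                    log_ratio = logsumexp(log_w + delta * fj)
                    gain = (p_mean[j] * delta - log_ratio
                            - beta[j] * (abs(cand) - abs(lam[j])))
                    if gain >= 0 or abs(delta) < 1e-15:
                        break
                    delta *= 0.5
                if abs(delta) < 1e-15:
                    continue
                lam[j] += delta
                log_z += log_ratio
                w = w * np.exp(delta * fj - log_ratio)
            # refresh from scratch to kill incremental drift
            eta = F_bg @ lam
            log_z = logsumexp(eta)
            w = np.exp(eta - log_z)
            new_obj = p_mean @ lam - log_z - beta @ np.abs(lam)
            kkt = self._kkt_violation(lam, p_mean, w @ F_bg, beta)
            if abs(new_obj - obj) < self.tol * (abs(obj) + 1e-10) and kkt < 5e-4:
                obj = new_obj
                converged = True
                break
            obj = new_obj
        return lam, float(log_z), sweep, converged

    @staticmethod
    def _kkt_violation(lam, p_mean, bg_exp, beta) -> float:
        """Max violation of the stationarity conditions of the L1 problem."""
        grad = p_mean - bg_exp
        viol = np.where(lam == 0.0, np.maximum(np.abs(grad) - beta, 0.0),
                        np.abs(grad - np.sign(lam) * beta))
        return float(viol.max()) if len(viol) else 0.0

    def kkt_violation_(self) -> float:
        return self._kkt_violation(self.weights_, self.presence_means_,
                                   self.background_expectations_, self.beta_)

    # -- prediction ---------------------------------------------------------

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor eta = lambda . f(x)."""
        return self.features_.transform(X) @ self.weights_

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Gibbs probability exp(eta)/Z; sums to 1 over the background."""
        return np.exp(self.decision_function(X) - self.log_z_)

    def predict_logistic(self, X: np.ndarray) -> np.ndarray:
        """Logistic output tau*e^H*raw / (1 + tau*e^H*raw) in (0, 1)."""
        q = self.tau * np.exp(self.entropy_) * self.predict_raw(X)
        return q / (1.0 + q)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_logistic(X)

    # -- grids --------------------------------------------------------------

    def predict_raw_grid(self, components: EnvStack) -> np.ndarray:
        """Raw prediction over masked cells (0 outside the mask)."""
        grid = np.zeros(components.spec.shape)
        grid[components.mask] = self.predict_raw(components.masked_matrix())
        return grid

    def predict_logistic_grid(self, components: EnvStack) -> np.ndarray:
        grid = np.zeros(components.spec.shape)
        grid[components.mask] = self.predict_logistic(components.masked_matrix())
        return grid


def fit_maxent(presence_X: np.ndarray, background: BackgroundSample,
               **params) -> MaxentModel:
    """Fit a :class:`MaxentModel` from presence covariates and a background
    sample (thin functional wrapper)."""
    X = np.vstack([np.atleast_2d(presence_X), background.X])
    y = np.r_[np.ones(len(np.atleast_2d(presence_X))), np.zeros(background.n)]
    return MaxentModel(**params).fit(X, y)
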