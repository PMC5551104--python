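"""Layer normalization, raster PCA, and county climate-representativeness metrics.

The preparation pipeline mirrors standard SDM practice: normalize each
environmental layer to zero mean and unit (population) SD over the study
mask, run a PCA on the cell-by-layer matrix, and keep the leading
components that explain a target fraction of total variance. The
county-level summaries quantify how well a single point (the county
centroid) represents a county's climate: an eigenvalue-fraction-weighted
centroid-versus-county-mean offset and an eigenvalue-fraction-weighted
within-county variance.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import EnvStack
from .simulate import CountyPartition


class LayerNormalizer(BaseEstimator, TransformerMixin):
    """Standardize layers to mean 0 / population SD 1 over masked-in cells."""

    def fit(self, env: EnvStack, y=None):
        X = env.masked_matrix()
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0)  # population SD
        self.layer_names_ = list(env.layer_names)
        if np.any(self.sds_ == 0):
            bad = [n for n, s in zip(env.layer_names, self.sds_) if s == 0]
            raise ValueError(f"constant layer(s) over the mask: {', '.join(bad)}")
        return self

    def transform(self, env: EnvStack) -> EnvStack:
        layers = (env.layers - self.means_[:, None, None]) / self.sds_[:, None, None]
        return EnvStack(spec=env.spec, layers=layers,
                        layer_names=list(env.layer_names), mask=env.mask.copy())


def normalize_layers(env: EnvStack) -> tuple[EnvStack, LayerNormalizer]:
    """Normalize every layer; returns the new stack and the fitted constants."""
    norm = LayerNormalizer().fit(env)
    return norm.transform(env), norm


class RasterPCA(BaseEstimator, TransformerMixin):
    """PCA of an environmental stack over its masked cells.

    Eigendecomposition of the (population) covariance matrix of the
    cell-by-layer matrix. Components are ordered by descending eigenvalue;
    the sign convention makes the largest-magnitude loading of each
    component positive.

    Attributes
    ----------
    components_ : (n_layers, n_layers) array, rows = loading vectors.
    explained_variance_ : eigenvalues, nonincreasing.
    explained_variance_ratio_ : eigenvalue fractions, summing to 1.
    mean_ : per-layer means removed before projection.
    """

    def fit(self, env: EnvStack, y=None):
        X = env.masked_matrix()
        n, p = X.shape
        if n < max(20, p + 1):
            raise ValueError(f"need more masked-in cells ({n}) than layers ({p})")
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                             np.arange(p)])
        evecs = evecs * flip[None, :]
        self.components_ = evecs.T
        self.explained_variance_ = evals
        self.explained_variance_ratio_ = evals / evals.sum()
        self.layer_names_ = list(env.layer_names)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean_) @ self.components_.T

    def n_components_for(self, cum_threshold: float) -> int:
        """Smallest k with cumulative variance fraction >= cum_threshold."""
        if not 0 < cum_threshold <= 1:
            raise ValueError("cum_threshold must lie in (0, 1]")
        cum = np.cumsum(self.explained_variance_ratio_)
        if cum_threshold == 1.0:
            return int(np.count_nonzero(self.explained_variance_ >
                                        1e-12 * self.explained_variance_[0]))
        return int(np.searchsorted(cum, cum_threshold) + 1)

    def to_json(self, path) -> None:
        payload = {
            "layer_names": self.layer_names_,
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "eigenvalues": self.explained_variance_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RasterPCA":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls()
        model.layer_names_ = payload["layer_names"]
        model.mean_ = np.asarray(payload["mean"])
        model.components_ = np.asarray(payload["components"])
        model.explained_variance_ = np.asarray(payload["eigenvalues"])
        model.explained_variance_ratio_ = (
            model.explained_variance_ / model.explained_variance_.sum())
        return model


def fit_pca(env: EnvStack) -> RasterPCA:
    """Fit a :class:`RasterPCA` on a (normalized) stack."""
    return RasterPCA().fit(env)


def select_components(model: RasterPCA, env: EnvStack,
                      cum_threshold: float = 0.985) -> EnvStack:
    """Project the stack onto the leading components covering
    ``cum_threshold`` of total variance; returns PC1..PCk grids."""
    k = model.n_components_for(cum_threshold)
    shape = env.spec.shape
    layers = np.zeros((k, *shape))
    scores = model.transform(env.masked_matrix())[:, :k]
    for i in range(k):
        layers[i][env.mask] = scores[:, i]
    return EnvStack(spec=env.spec, layers=layers,
                    layer_names=[f"PC{i + 1}" for i in range(k)],
                    mask=env.mask.copy())


# ---------------------------------------------------------------------------
# County climate-representativeness metrics


def _county_layer_stats(components: EnvStack, partition: CountyPartition):
    """Per-county per-layer means and population variances.

    Returns (county_ids, means, variances) with means/vars shaped
    (n_counties, n_layers).
    """
    valid = components.mask & (partition.labels >= 0)
    labels = partition.labels[valid]
    ids = partition.county_ids
    if np.any(~np.isin(ids, labels)):
        empty = sorted(set(ids) - set(np.unique(labels)))
        raise ValueError(f"county with no masked-in cells: {empty}")
    nmax = labels.max() + 1
    counts = np.bincount(labels, minlength=nmax)
    means = np.empty((len(ids), components.n_layers))
    variances = np.empty_like(means)
    for k in range(components.n_layers):
        vals = components.layers[k][valid]
        s1 = np.bincount(labels, weights=vals, minlength=nmax)
        s2 = np.bincount(labels, weights=vals * vals, minlength=nmax)
        with np.errstate(invalid="ignore"):
            mu = s1 / counts
            var = s2 / counts - mu**2
        means[:, k] = mu[ids]
        variances[:, k] = np.clip(var[ids], 0.0, None)
    return ids, means, variances


def _component_weights(model: RasterPCA, n_components: int) -> np.ndarray:
    return model.explained_variance_ratio_[:n_components]


def county_climate_offset(components: EnvStack, model: RasterPCA,
                          partition: CountyPartition) -> pd.Series:
    """Eigenvalue-fraction-weighted |centroid value - county mean| per county.

    offset(county) = sum_k w_k * |z_k(centroid cell) - mean_county(z_k)|
    with w_k the eigenvalue fraction of component k. Zero when climate is
    constant within the county.
    """
    ids, means, _ = _county_layer_stats(components, partition)
    rows, cols = partition.centroid_cells()
    centroid_vals = components.values_at(rows, cols)
    w = _component_weights(model, components.n_layers)
    offsets = np.abs(centroid_vals - means) @ w
    return pd.Series(offsets, index=pd.Index(ids, name="county_id"),
                     name="offset_metric")


def county_climate_variance(components: EnvStack, model: RasterPCA,
                            partition: CountyPartition) -> pd.Series:
    """Eigenvalue-fraction-weighted within-county component variance.

    variance(county) = sum_k w_k * Var_county(z_k) (population variance);
    zero for constant climate and for single-cell counties.
    """
    ids, _, variances = _county_layer_stats(components, partition)
    w = _component_weights(model, components.n_layers)
    return pd.Series(variances @ w, index=pd.Index(ids, name="county_id"),
                     name="variance_metric")


def within_county_sd(layer: np.ndarray, partition: CountyPartition,
                     mask: np.ndarray | None = None) -> pd.Series:
    """Population SD of a single layer within each county."""
    spec = partition.spec
    stack = EnvStack(spec=spec, layers=layer[None], layer_names=["layer"],
                     mask=partition.mask if mask is None else mask)
    ids, _, variances = _county_layer_stats(stack, partition)
    return pd.Series(np.sqrt(variances[:, 0]),
                     index=pd.Index(ids, name="county_id"), name="sd")
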