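"""Unsupervised partitioning of the response-time distribution.

Response times are clustered with univariate Gaussian mixtures fitted by
expectation-maximization over a grid of component counts and covariance
types; the model minimizing the Bayesian Information Criterion is kept.
With four components, three map to fast/medium/slow categories by
ascending mean and the low-weight slowest component is treated as an
outlier cluster whose trials are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = ["RTClusterModel", "fit_gmm_bic", "assign_categories"]

_COV_ORDER = ("spherical", "diagonal", "tied", "full")
# sklearn naming: univariate "diagonal" is spelled "diag"
_COV_TO_SKLEARN = {"spherical": "spherical", "diagonal": "diag", "tied": "tied", "full": "full"}


@dataclass
class RTClusterModel:
    """A fitted mixture over response times plus its category mapping."""

    n_components: int
    covariance_type: str
    means: np.ndarray          # (k,) ms
    variances: np.ndarray      # (k,) ms^2
    weights: np.ndarray        # (k,) sum to 1
    bic: float
    category_map: dict[int, str] | None = None
    bic_grid: dict = field(default_factory=dict, repr=False)

    def responsibilities(self, rt_ms: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, (n, k)."""
        rt = np.asarray(rt_ms, dtype=float)[:, None]
        log_pdf = (
            -0.5 * np.log(2 * np.pi * self.variances)[None, :]
            - 0.5 * (rt - self.means[None, :]) ** 2 / self.variances[None, :]
        )
        log_w = np.log(self.weights)[None, :] + log_pdf
        log_w -= log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w)
        return w / w.sum(axis=1, keepdims=True)

    def to_json(self, path) -> None:
        payload = {
            "n_components": self.n_components,
            "covariance_type": self.covariance_type,
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "weights": self.weights.tolist(),
            "bic": self.bic,
            "category_map": ({str(k): v for k, v in self.category_map.items()}
                             if self.category_map else None),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RTClusterModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_components=d["n_components"],
            covariance_type=d["covariance_type"],
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            weights=np.array(d["weights"]),
            bic=d["bic"],
            category_map=({int(k): v for k, v in d["category_map"].items()}
                          if d["category_map"] else None),
        )


def _extract_variances(gm: GaussianMixture) -> np.ndarray:
    cov = gm.covariances_
    k = gm.n_components
    if gm.covariance_type == "spherical":
        return np.asarray(cov, dtype=float)
    if gm.covariance_type == "diag":
        return cov[:, 0].astype(float)
    if gm.covariance_type == "tied":
        return np.full(k, float(cov[0, 0]))
    return cov[:, 0, 0].astype(float)  # full


def _category_map(means: np.ndarray, weights: np.ndarray, grand_median: float):
    """Map component indices to fast/medium/slow (+ outlier for k=4).

    The outlier is the smallest-weight component among those whose mean
    exceeds the grand median of the data (the sparse slow tail); remaining
    components are named by ascending mean.
    """
    k = len(means)
    if k == 3:
        order = np.argsort(means)
        return {int(order[i]): name for i, name in enumerate(("fast", "medium", "slow"))}
    if k == 4:
        above = [i for i in range(k) if means[i] > grand_median]
        if not above:
            above = [int(np.argmax(means))]
        outlier = min(above, key=lambda i: (weights[i], -means[i]))
        rest = sorted((i for i in range(k) if i != outlier), key=lambda i: means[i])
        cmap = {int(rest[i]): name for i, name in enumerate(("fast", "medium", "slow"))}
        cmap[int(outlier)] = "outlier"
        return cmap
    return None


def fit_gmm_bic(
    rt_ms: np.ndarray,
    component_range=range(1, 9),
    covariance_types=_COV_ORDER,
    seed: int = 0,
    n_init: int = 10,
) -> RTClusterModel:
    """Fit every (k, covariance type) candidate and keep the lowest BIC.

    Each candidate is fitted with ``n_init`` random EM initializations,
    keeping the best log-likelihood. Ties in BIC break toward smaller k,
    then by covariance order spherical < diagonal < tied < full.
    """
    rt = np.asarray(rt_ms, dtype=float).ravel()
    if len(rt) < 10:
        raise ValueError("need at least 10 response times")
    if np.ptp(rt) == 0:
        raise ValueError("degenerate input: all response times identical")
    ks = sorted(set(int(k) for k in component_range))
    if not ks or ks[0] < 1 or ks[-1] > 10:
        raise ValueError("component_range must lie within [1, 10]")
    covs = [c for c in _COV_ORDER if c in set(covariance_types)]
    if not covs:
        raise ValueError("no valid covariance types requested")

    X = rt[:, None]
    best = None
    grid: dict[tuple[int, str], float] = {}
    for k in ks:
        for ci, cov in enumerate(covs):
            gm = GaussianMixture(
                n_components=k,
                covariance_type=_COV_TO_SKLEARN[cov],
                n_init=n_init,
                random_state=seed,
                reg_covar=1e-6,
            ).fit(X)
            bic = float(gm.bic(X))
            grid[(k, cov)] = bic
            key = (bic, k, ci)
            if best is None or key < best[0]:
                best = (key, gm, cov)

    (_, _, _), gm, cov = best
    means = gm.means_[:, 0].astype(float)
    weights = gm.weights_.astype(float)
    model = RTClusterModel(
        n_components=gm.n_components,
        covariance_type=cov,
        means=means,
        variances=_extract_variances(gm),
        weights=weights,
        bic=grid[(gm.n_components, cov)],
        category_map=_category_map(means, weights, float(np.median(rt))),
        bic_grid=grid,
    )
    return model


def assign_categories(model: RTClusterModel, rt_ms: np.ndarray) -> np.ndarray:
    """Hard MAP category per response time (array of label strings).

    Trials assigned to the outlier component are labeled "outlier" and are
    meant to be excluded before augmentation.
    """
    if model.category_map is None:
        raise ValueError(
            "no category mapping for a model with "
            f"{model.n_components} components (need 3 or 4)")
    non_outlier = sum(1 for v in model.category_map.values() if v != "outlier")
    if non_outlier < 2:
        raise ValueError("model has fewer than 2 non-outlier components")
    resp = model.responsibilities(np.asarray(rt_ms, dtype=float))
    comp = np.argmax(resp, axis=1)
    return np.array([model.category_map[int(c)] for c in comp])
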