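"""Bootstrap ERP augmentation and eigenspace reconstruction-error filtering.

ERPs are generated by repeatedly averaging small random subsets of trials
within each (subject, response-speed category) pool. A category-specific
dropout schedule permanently removes trials from the pool at a fixed
iteration interval, which both limits near-duplicate averages and
rebalances minority categories (slow pools shrink more slowly, so their
relative share of the augmented set grows). A PCA-based filter then drops
augmented samples whose reconstruction error from the raw-trial eigenspace
falls outside central percentiles: low-error samples are overly faithful
to the raw trials (noisy), extreme-error samples are overly averaged
(biased).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synth import TrialSet

__all__ = [
    "BootstrapParams",
    "AugmentedERPSet",
    "bootstrap_erps",
    "expected_sample_count",
    "eigenspace_filter",
    "category_shares",
]

logger = logging.getLogger(__name__)

_DEFAULT_ALPHA = {"fast": 0.3, "medium": 0.2, "slow": 0.1}


@dataclass(frozen=True)
class BootstrapParams:
    """Bootstrap schedule: r trials per average, per-category dropout rate
    alpha, at most n iterations per pool, one drop event every n_alpha
    iterations."""

    r: int = 50
    alpha: dict = field(default_factory=lambda: dict(_DEFAULT_ALPHA))
    n: int = 1500
    n_alpha: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1 or self.n < 1 or self.n_alpha < 1:
            raise ValueError("r, n and n_alpha must all be >= 1")
        for cat, a in self.alpha.items():
            if not (0 < a < 1):
                raise ValueError(f"dropout rate for {cat!r} must lie in (0, 1)")

    def drop_size(self, category: str) -> int:
        """Trials removed per drop event: round(r * alpha), at least 1."""
        if category not in self.alpha:
            raise KeyError(f"no dropout rate for category {category!r}")
        return max(1, int(round(self.r * self.alpha[category])))


@dataclass
class AugmentedERPSet:
    """Bootstrap-averaged ERPs with per-sample provenance."""

    erps: np.ndarray            # (n_samples, n_channels, n_times)
    category: np.ndarray        # label per sample
    subject_id: np.ndarray
    provenance: np.ndarray      # raw trials averaged per sample
    sfreq: float
    epoch_window: tuple[float, float]
    channel_names: tuple[str, ...] | None = None
    residual: np.ndarray | None = None  # set by eigenspace_filter

    @property
    def n_samples(self) -> int:
        return self.erps.shape[0]

    def subset(self, mask: np.ndarray) -> "AugmentedERPSet":
        return AugmentedERPSet(
            erps=self.erps[mask],
            category=self.category[mask],
            subject_id=self.subject_id[mask],
            provenance=self.provenance[mask],
            sfreq=self.sfreq,
            epoch_window=self.epoch_window,
            channel_names=self.channel_names,
            residual=self.residual[mask] if self.residual is not None else None,
        )


def expected_sample_count(pool_size: int, params: BootstrapParams, category: str) -> int:
    """Closed-form prediction of the number of ERPs a pool emits.

    A pool no larger than r emits its overall mean once. Otherwise one ERP
    is emitted per iteration and m = round(r*alpha) trials are dropped every
    n_alpha iterations; once the pool falls to <= r the next iteration emits
    the terminal mean-of-remaining sample and the pool stops. The iteration
    cap n bounds the total.
    """
    if pool_size < 0:
        raise ValueError("pool_size must be >= 0")
    if pool_size == 0:
        return 0
    if pool_size <= params.r:
        return 1
    m = params.drop_size(category)
    drops_needed = -(-(pool_size - params.r) // m)  # ceil
    # the terminal mean-of-remaining sample exists only if the final drop
    # left a non-empty pool
    terminal = 1 if pool_size - drops_needed * m > 0 else 0
    return min(params.n, drops_needed * params.n_alpha + terminal)


def bootstrap_erps(trials: TrialSet, labels: np.ndarray,
                   params: BootstrapParams) -> AugmentedERPSet:
    """Run the bootstrap schedule over every (subject, category) pool.

    ``labels`` gives the response-speed category per trial; trials labeled
    "outlier" are excluded. Deterministic under ``params.seed``.
    """
    labels = np.asarray(labels)
    if len(labels) != trials.n_trials:
        raise ValueError("labels length must match trial count")
    rng = np.random.default_rng(params.seed)

    keep = labels != "outlier"
    cats = [c for c in ("fast", "medium", "slow") if c in set(labels[keep])]
    subjects = sorted(set(str(s) for s in trials.subject_id[keep]))

    erps, out_cat, out_subj, prov = [], [], [], []
    for subj in subjects:
        for cat in cats:
            pool = np.flatnonzero((trials.subject_id == subj) & (labels == cat))
            if len(pool) == 0:
                logger.warning("empty pool for subject=%s category=%s", subj, cat)
                continue
            m = params.drop_size(cat)
            pool = list(pool)
            for j in range(1, params.n + 1):
                if len(pool) == 0:
                    break
                if len(pool) <= params.r:
                    erps.append(trials.data[pool].mean(axis=0))
                    prov.append(len(pool))
                    out_cat.append(cat)
                    out_subj.append(subj)
                    break
                pick = rng.choice(len(pool), size=params.r, replace=False)
                erps.append(trials.data[[pool[i] for i in pick]].mean(axis=0))
                prov.append(params.r)
                out_cat.append(cat)
                out_subj.append(subj)
                if j % params.n_alpha == 0:
                    drop = rng.choice(len(pool), size=min(m, len(pool)), replace=False)
                    for i in sorted(drop, reverse=True):
                        pool.pop(i)

    if erps:
        stack = np.stack(erps).astype(np.float32)
    else:
        stack = np.empty((0,) + trials.data.shape[1:], dtype=np.float32)
        logger.warning("bootstrap produced zero samples")
    return AugmentedERPSet(
        erps=stack,
        category=np.array(out_cat, dtype=object) if out_cat else np.empty(0, dtype=object),
        subject_id=np.array(out_subj, dtype=object) if out_subj else np.empty(0, dtype=object),
        provenance=np.array(prov, dtype=int),
        sfreq=trials.sfreq,
        epoch_window=trials.epoch_window,
        channel_names=trials.channel_names,
    )


def eigenspace_residuals(raw: TrialSet, augmented: AugmentedERPSet,
                         k: int | float = 0.95) -> np.ndarray:
    """Euclidean reconstruction-error norm of each augmented sample from the
    top-k principal axes of the centered raw trials.

    ``k`` is a component count, or a variance fraction in (0, 1) selecting
    the smallest count explaining that fraction of raw-trial variance.
    """
    if raw.n_trials < 2:
        raise ValueError("need at least 2 raw trials for an eigenspace")
    if augmented.n_samples == 0:
        raise ValueError("augmented set is empty")
    X = raw.data.reshape(raw.n_trials, -1).astype(np.float64)
    mean = X.mean(axis=0)
    Xc = X - mean
    # Gram-based PCA: dimensions far exceed trials, so work in trial space.
    U, s, _ = np.linalg.svd(Xc @ Xc.T)
    s = np.sqrt(np.maximum(s, 0.0))
    rank = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    if isinstance(k, float) and 0 < k < 1:
        var = s**2
        frac = np.cumsum(var) / var.sum()
        k_eff = int(np.searchsorted(frac, k) + 1)
    else:
        k_eff = int(k)
        if k_eff > rank:
            logger.warning("k=%d exceeds raw rank %d; clipping", k_eff, rank)
    k_eff = max(1, min(k_eff, rank))
    # Principal axes in feature space: V = Xc^T U / s.
    V = (Xc.T @ U[:, :k_eff]) / s[:k_eff]

    res = np.empty(augmented.n_samples)
    chunk = max(1, int(2e8 // (8 * Xc.shape[1])))
    for i in range(0, augmented.n_samples, chunk):
        A = augmented.erps[i:i + chunk].reshape(-1, Xc.shape[1]).astype(np.float64) - mean
        proj = A @ V
        res[i:i + chunk] = np.sqrt(np.maximum(
            np.einsum("ij,ij->i", A, A) - np.einsum("ij,ij->i", proj, proj), 0.0))
    return res


def eigenspace_filter(raw: TrialSet, augmented: AugmentedERPSet,
                      k: int | float = 0.95, lo: float = 25.0,
                      hi: float = 75.0) -> AugmentedERPSet:
    """Retain augmented samples whose eigenspace reconstruction error lies
    within the [lo, hi] percentiles of the pooled error distribution
    (inclusive bounds, stable order)."""
    res = eigenspace_residuals(raw, augmented, k)
    q_lo, q_hi = np.percentile(res, [lo, hi])
    mask = (res >= q_lo) & (res <= q_hi)
    out = augmented.subset(mask)
    out.residual = res[mask]
    return out


def category_shares(counts: dict[str, int], ndigits: int = 0) -> dict[str, float]:
    """Per-category percentage shares of a count table (rounded)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {c: round(100.0 * n / total, ndigits) if ndigits else
            round(100.0 * n / total) for c, n in counts.items()}


def provenance_table(augmented: AugmentedERPSet):
    """Provenance as a pandas DataFrame (sample id, subject, category,
    trials averaged, residual if filtered)."""
    import pandas as pd

    return pd.DataFrame({
        "sample": np.arange(augmented.n_samples),
        "subject": augmented.subject_id,
        "category": augmented.category,
        "trials_averaged": augmented.provenance,
        "residual": (augmented.residual if augmented.residual is not None
                     else np.full(augmented.n_samples, np.nan)),
    })
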