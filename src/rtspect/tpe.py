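"""Tree-structured Parzen estimator (TPE) hyperparameter search.

Sequential model-based optimization: after a startup phase of random
draws, observed trials are split at the gamma quantile of the objective
into a "good" and a "bad" set; per-dimension Parzen (kernel-density)
estimators l(x) and g(x) are fitted to the two sets, and each new proposal
is the candidate (out of ``n_candidates`` draws from l) maximizing the
density ratio l(x)/g(x). The objective is maximized (validation accuracy
in the decoder search).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Uniform", "LogUniform", "QUniform", "QLogUniform", "Choice",
    "tpe_search", "decoder_space", "config_from_params",
    "DEFAULT_BUDGET",
]

logger = logging.getLogger(__name__)

#: Search budget used in the published experiment (73 trials).
DEFAULT_BUDGET = 73


# --------------------------------------------------------------------------
# parameter distributions

@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float
    log: bool = False
    q: float | None = None

    def _space(self, x):
        return np.log(x) if self.log else np.asarray(x, dtype=float)

    def _unspace(self, z):
        x = np.exp(z) if self.log else z
        x = np.clip(x, self.lo, self.hi)
        if self.q is not None:
            x = np.clip(np.round(x / self.q) * self.q, self.lo, self.hi)
        return x

    def sample(self, rng):
        lo, hi = self._space(self.lo), self._space(self.hi)
        return float(self._unspace(rng.uniform(lo, hi)))


def LogUniform(lo, hi):
    return Uniform(lo, hi, log=True)


def QUniform(lo, hi, q=1):
    return Uniform(lo, hi, q=q)


def QLogUniform(lo, hi, q=1):
    return Uniform(lo, hi, log=True, q=q)


@dataclass(frozen=True)
class Choice:
    options: tuple

    def __init__(self, options):
        object.__setattr__(self, "options", tuple(options))

    def sample(self, rng):
        return self.options[rng.integers(len(self.options))]


# --------------------------------------------------------------------------
# Parzen estimators

class _ContinuousParzen:
    """Gaussian mixture over observations plus a uniform prior component."""

    def __init__(self, dist: Uniform, obs):
        self.dist = dist
        self.lo, self.hi = dist._space(dist.lo), dist._space(dist.hi)
        self.span = max(self.hi - self.lo, 1e-12)
        z = np.sort(dist._space(np.asarray(obs, dtype=float))) if len(obs) else np.empty(0)
        self.mu = z
        if len(z):
            gaps = np.diff(np.concatenate([[self.lo], z, [self.hi]]))
            sig = np.maximum(gaps[:-1], gaps[1:])
            self.sigma = np.clip(sig, self.span / max(len(z), 1) / 10, self.span)
        else:
            self.sigma = np.empty(0)
        self.n = len(z)

    def sample(self, rng):
        # one prior pseudo-observation
        i = rng.integers(self.n + 1)
        if i == self.n:
            z = rng.uniform(self.lo, self.hi)
        else:
            z = rng.normal(self.mu[i], self.sigma[i])
        return float(self.dist._unspace(np.clip(z, self.lo, self.hi)))

    def logpdf(self, x):
        z = self.dist._space(np.asarray([x], dtype=float))[0]
        comps = [np.log(1.0 / self.span)]
        if self.n:
            comps.extend(
                -0.5 * ((z - self.mu) / self.sigma) ** 2
                - np.log(self.sigma * np.sqrt(2 * np.pi)))
        comps = np.asarray(comps, dtype=float)
        m = comps.max()
        return float(m + np.log(np.exp(comps - m).sum()) - np.log(self.n + 1))


class _CategoricalParzen:
    """Smoothed frequency estimate over the observed choices."""

    def __init__(self, dist: Choice, obs):
        counts = np.ones(len(dist.options))  # +1 prior
        index = {o: i for i, o in enumerate(dist.options)}
        for o in obs:
            counts[index[o]] += 1
        self.dist = dist
        self.p = counts / counts.sum()

    def sample(self, rng):
        return self.dist.options[rng.choice(len(self.p), p=self.p)]

    def logpdf(self, x):
        return float(np.log(self.p[self.dist.options.index(x)]))


def _parzen(dist, obs):
    if isinstance(dist, Choice):
        return _CategoricalParzen(dist, obs)
    return _ContinuousParzen(dist, obs)


# --------------------------------------------------------------------------
# search driver

def tpe_search(space: dict, budget: int, objective, seed: int = 0,
               gamma: float = 0.25, n_candidates: int = 20,
               n_startup: int = 10):
    """Maximize ``objective(params)`` over ``space`` with ``budget`` trials.

    Returns (best_params, log): the arg-max parameter dict and the full
    trial log, a list of {"params", "score", "trial"} dicts. Failed trials
    (objective raising) are logged with score -inf; if every trial fails,
    raises with the log attached.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    log: list[dict] = []

    def propose():
        done = [t for t in log if np.isfinite(t["score"])]
        if len(done) < n_startup:
            return {k: d.sample(rng) for k, d in space.items()}
        scores = np.array([t["score"] for t in done])
        n_good = max(1, int(np.ceil(gamma * len(done))))
        order = np.argsort(-scores)
        good = [done[i] for i in order[:n_good]]
        bad = [done[i] for i in order[n_good:]] or good
        best_cand, best_ratio = None, -np.inf
        models = {k: (_parzen(d, [t["params"][k] for t in good]),
                      _parzen(d, [t["params"][k] for t in bad]))
                  for k, d in space.items()}
        for _ in range(n_candidates):
            cand = {k: lm.sample(rng) for k, (lm, gm) in models.items()}
            ratio = sum(lm.logpdf(cand[k]) - gm.logpdf(cand[k])
                        for k, (lm, gm) in models.items())
            if ratio > best_ratio:
                best_cand, best_ratio = cand, ratio
        return best_cand

    for t in range(budget):
        params = propose()
        try:
            score = float(objective(params))
        except Exception as exc:  # noqa: BLE001 - log and continue the search
            logger.warning("trial %d failed: %s", t, exc)
            score = -np.inf
        log.append({"trial": t, "params": params, "score": score})

    finite = [t for t in log if np.isfinite(t["score"])]
    if not finite:
        err = RuntimeError("all TPE trials failed")
        err.trial_log = log
        raise err
    best = max(finite, key=lambda t: t["score"])
    return best["params"], log


# --------------------------------------------------------------------------
# decoder search space

def decoder_space() -> dict:
    """Default decoder hyperparameter space: depth 2-4, base filter width
    16-256 (log), FC width 64-1024, dropout 0.2-0.6, learning rate
    1e-4..1e-1 (log), optimizer choice."""
    return {
        "depth": Choice([2, 3, 4]),
        "filters_base": QLogUniform(16, 256),
        "fc_units": QUniform(64, 1024),
        "dropout": Uniform(0.2, 0.6),
        "learning_rate": LogUniform(1e-4, 1e-1),
        "optimizer": Choice(["adagrad", "adam", "sgd"]),
    }


def config_from_params(params: dict, epochs: int = 20, seed: int = 0,
                       kernel: int = 5, batch_size: int = 64):
    """Build a DecoderConfig from a sampled parameter dict; filter widths
    grow linearly with depth as in the published architecture."""
    from .nn import DecoderConfig

    depth = int(params["depth"])
    base = int(params["filters_base"])
    return DecoderConfig(
        conv_filters=tuple(base * (i + 1) for i in range(depth)),
        kernel=kernel,
        fc_units=(int(params["fc_units"]),),
        dropout=float(params["dropout"]),
        optimizer=str(params["optimizer"]),
        learning_rate=float(params["learning_rate"]),
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
    )
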