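import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rtspect as r
from rtspect.augment import eigenspace_residuals
from rtspect.synth import TrialSet


def drop_schedule_oracle(pool_size, r_, m, n, n_alpha):
    """Discrete-event simulation of the bootstrap schedule: count emitted
    samples directly, independent of the closed form."""
    if pool_size == 0:
        return 0
    emitted = 0
    pool = pool_size
    for j in range(1, n + 1):
        if pool == 0:
            break
        if pool <= r_:
            emitted += 1
            break
        emitted += 1
        if j % n_alpha == 0:
            pool -= min(m, pool)
    return emitted


def _toy_trials(data, subjects=None):
    n = data.shape[0]
    return TrialSet(
        data=data.astype(np.float32),
        rt_ms=np.full(n, 400.0),
        subject_id=np.array(subjects if subjects is not None else ["S01"] * n),
        sfreq=100.0, epoch_window=(0.0, 100.0),
    )


def test_pool_of_identical_trials_emits_that_waveform():
    wave = np.arange(8, dtype=np.float32).reshape(2, 4)
    data = np.repeat(wave[None], 5, axis=0)
    ts = _toy_trials(data)
    params = r.BootstrapParams(r=5, alpha={"fast": 0.2}, n=50, n_alpha=5, seed=0)
    out = r.bootstrap_erps(ts, np.array(["fast"] * 5), params)
    assert out.n_samples == 1
    assert np.allclose(out.erps[0], wave)


def test_sample_count_examples():
    params = r.BootstrapParams(r=50, alpha={"fast": 0.2}, n=1500, n_alpha=10)
    assert r.expected_sample_count(10, params, "fast") == 1
    # drop schedule slower than the iteration cap
    big = r.BootstrapParams(r=50, alpha={"fast": 0.02}, n=100, n_alpha=10)
    assert r.expected_sample_count(10_000, big, "fast") == 100
    # worked case: pool 100, drops of 10 every 10 iterations
    p = r.BootstrapParams(r=50, alpha={"fast": 0.2}, n=1500, n_alpha=10)
    assert r.expected_sample_count(100, p, "fast") == 51


def test_sample_counts_match_simulation_grid():
    """Closed form vs discrete-event oracle over a 200-case grid."""
    cases = 0
    for pool in (0, 1, 5, 20, 50, 51, 99, 100, 230, 1000):
        for r_ in (10, 50):
            for alpha in (0.1, 0.3):
                for n, n_alpha in ((60, 5), (200, 10), (1500, 10),
                                   (30, 1), (7, 3)):
                    params = r.BootstrapParams(r=r_, alpha={"fast": alpha},
                                               n=n, n_alpha=n_alpha)
                    m = params.drop_size("fast")
                    assert (r.expected_sample_count(pool, params, "fast")
                            == drop_schedule_oracle(pool, r_, m, n, n_alpha)), (
                        pool, r_, alpha, n, n_alpha)
                    cases += 1
    assert cases == 200


@settings(max_examples=60, deadline=None, derandomize=True)
@given(pool=st.integers(0, 2000), r_=st.integers(1, 100),
       alpha=st.floats(0.01, 0.99), n=st.integers(1, 500),
       n_alpha=st.integers(1, 50))
def test_sample_count_property(pool, r_, alpha, n, n_alpha):
    params = r.BootstrapParams(r=r_, alpha={"fast": alpha}, n=n, n_alpha=n_alpha)
    m = params.drop_size("fast")
    assert (r.expected_sample_count(pool, params, "fast")
            == drop_schedule_oracle(pool, r_, m, n, n_alpha))


def test_bootstrap_emission_counts_match_closed_form():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(130, 2, 4))
    labels = np.array(["fast"] * 80 + ["slow"] * 50)
    ts = _toy_trials(data)
    params = r.BootstrapParams(r=10, alpha={"fast": 0.3, "slow": 0.1},
                               n=40, n_alpha=5, seed=1)
    out = r.bootstrap_erps(ts, labels, params)
    for cat, pool in (("fast", 80), ("slow", 50)):
        assert ((out.category == cat).sum()
                == r.expected_sample_count(pool, params, cat))
    assert np.all(out.provenance <= params.r)


def test_outliers_excluded_and_empty_pool_warns(caplog):
    rng = np.random.default_rng(1)
    data = rng.normal(size=(30, 2, 4))
    labels = np.array(["outlier"] * 30)
    ts = _toy_trials(data)
    params = r.BootstrapParams(r=5, alpha={"fast": 0.2}, n=10, n_alpha=5)
    out = r.bootstrap_erps(ts, labels, params)
    assert out.n_samples == 0


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(60, 3, 5))
    labels = np.array(["fast"] * 60)
    ts = _toy_trials(data)
    params = r.BootstrapParams(r=10, alpha={"fast": 0.2}, n=30, n_alpha=5, seed=9)
    a = r.bootstrap_erps(ts, labels, params)
    b = r.bootstrap_erps(ts, labels, params)
    assert np.array_equal(a.erps, b.erps)


def test_minority_share_increases_after_augmentation():
    """Category-specific dropout rebalances: the slow share of samples
    strictly exceeds its share of raw trials."""
    rng = np.random.default_rng(3)
    n_fast, n_slow = 300, 45
    data = rng.normal(size=(n_fast + n_slow, 2, 4))
    labels = np.array(["fast"] * n_fast + ["slow"] * n_slow)
    ts = _toy_trials(data)
    params = r.BootstrapParams(r=20, alpha={"fast": 0.3, "slow": 0.1},
                               n=200, n_alpha=10, seed=0)
    out = r.bootstrap_erps(ts, labels, params)
    raw_share = n_slow / (n_fast + n_slow)
    aug_share = (out.category == "slow").mean()
    assert aug_share > raw_share


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        r.BootstrapParams(r=0)
    with pytest.raises(ValueError):
        r.BootstrapParams(alpha={"fast": 1.5})


# --------------------------------------------------------------------------
# eigenspace filter

def _raw_and_augmented(n_raw=20, n_aug=40, seed=0):
    rng = np.random.default_rng(seed)
    raw = _toy_trials(rng.normal(size=(n_raw, 4, 10)))
    erp = rng.normal(size=(n_aug, 4, 10)).astype(np.float32)
    aug = r.AugmentedERPSet(
        erps=erp, category=np.array(["fast"] * n_aug),
        subject_id=np.array(["S01"] * n_aug),
        provenance=np.full(n_aug, 5), sfreq=100.0, epoch_window=(0.0, 100.0))
    return raw, aug


def test_filter_retains_exact_interquartile_fraction():
    raw, aug = _raw_and_augmented(n_aug=1000, seed=1)
    kept = r.eigenspace_filter(raw, aug, k=3)
    assert kept.n_samples == 500


def test_raw_trial_has_zero_residual_at_full_rank():
    raw, _ = _raw_and_augmented()
    aug = r.AugmentedERPSet(
        erps=raw.data[:5].copy(), category=np.array(["fast"] * 5),
        subject_id=np.array(["S01"] * 5), provenance=np.ones(5, dtype=int),
        sfreq=100.0, epoch_window=(0.0, 100.0))
    res = eigenspace_residuals(raw, aug, k=raw.n_trials - 1)
    scale = np.linalg.norm(raw.data[:5].reshape(5, -1), axis=1)
    assert np.all(res <= 1e-6 * scale)


def test_residuals_match_svd_oracle():
    """Residual norms agree with a direct SVD reconstruction (1e-8 rel)."""
    raw, aug = _raw_and_augmented(seed=2)
    k = 5
    res = eigenspace_residuals(raw, aug, k=k)
    X = raw.data.reshape(raw.n_trials, -1).astype(float)
    mean = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - mean, full_matrices=False)
    V = Vt[:k].T
    A = aug.erps.reshape(aug.n_samples, -1).astype(float) - mean
    oracle = np.linalg.norm(A - (A @ V) @ V.T, axis=1)
    assert np.allclose(res, oracle, rtol=1e-8, atol=1e-10)


def test_residual_monotone_in_k():
    raw, aug = _raw_and_augmented(seed=3)
    prev = None
    for k in (1, 3, 6, 10, 15):
        res = eigenspace_residuals(raw, aug, k=k)
        if prev is not None:
            assert np.all(res <= prev + 1e-9)
        prev = res


def test_k_exceeding_rank_is_clipped():
    raw, aug = _raw_and_augmented(n_raw=6, seed=4)
    res = eigenspace_residuals(raw, aug, k=1000)
    assert np.all(np.isfinite(res))


def test_sampling_fraction_matches_reported_rate():
    """Default r=50 over a ~900-trial per-subject pool is the reported
    5-6% sampling fraction."""
    params = r.BootstrapParams()
    assert 0.05 <= params.r / 900 <= 0.06


def test_category_shares_arithmetic():
    shares = r.category_shares({"slow": 4025, "medium": 11029, "fast": 30496})
    assert shares == {"slow": 9, "medium": 24, "fast": 67}
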