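"""Bootstrap ERP augmentation with category-specific dropout and
eigenspace filtering.

Averaging r random trials per iteration produces many low-noise ERP
samples; dropping trials from each pool at a fixed interval rebalances
minority categories; the PCA reconstruction-error filter then keeps the
central half of the error distribution.
"""

import numpy as np

import rtspect as r

ts = r.generate_trials(n_subjects=3, trials_per_subject=250, seed=2)
model = r.fit_gmm_bic(ts.rt_ms, seed=2)
labels = r.assign_categories(model, ts.rt_ms)

params = r.BootstrapParams(r=20, alpha={"fast": 0.3, "medium": 0.2,
                                        "slow": 0.1},
                           n=120, n_alpha=10, seed=2)
erps = r.bootstrap_erps(ts, labels, params)

raw_counts = {c: int((labels == c).sum()) for c in ("fast", "medium", "slow")}
aug_counts = {c: int((erps.category == c).sum())
              for c in ("fast", "medium", "slow")}
print("raw trial shares      :", r.category_shares(raw_counts))
print("augmented ERP shares  :", r.category_shares(aug_counts))
# The slow share grows: its low dropout rate keeps its pools alive longer.

pool = int((labels == "fast").sum()) // 3  # one subject's fast pool
print(f"predicted samples from a {pool}-trial fast pool:",
      r.expected_sample_count(pool, params, "fast"))

kept = r.eigenspace_filter(ts, erps, k=0.95)
print(f"eigenspace filter: kept {kept.n_samples} of {erps.n_samples} "
      f"({100 * kept.n_samples / erps.n_samples:.0f}%)")
print(f"residual range of kept samples: {kept.residual.min():.1f}-"
      f"{kept.residual.max():.1f} uV (central 25th-75th percentiles)")
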