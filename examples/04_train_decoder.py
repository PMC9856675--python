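"""Train the convolutional decoder on topomaps and inspect its metrics.

A compact chain on a small synthetic cohort: generate, cluster, augment,
render topomaps, train a small configuration, evaluate on held-out
samples. The published architecture is available as
``published_config()`` (4 blocks of 52/104/156/208 5x5 filters, FC
713/1019, dropout 0.47, Adagrad at 0.006, 165 epochs); here a reduced
configuration keeps the example quick.
"""

import numpy as np

import rtspect as r

ts = r.generate_trials(3, 250, seed=4)
labels = r.assign_categories(r.fit_gmm_bic(ts.rt_ms, seed=4), ts.rt_ms)
params = r.BootstrapParams(r=20, alpha={"fast": 0.3, "medium": 0.2,
                                        "slow": 0.1}, n=100, n_alpha=10,
                           seed=4)
kept = r.eigenspace_filter(ts, r.bootstrap_erps(ts, labels, params))
imgs, _ = r.topomap_pipeline(kept.erps, ts.sfreq, r.default_montage())
cats = kept.category.astype(str)

rng = np.random.default_rng(4)
idx = rng.permutation(len(imgs))
test, train = idx[:len(idx) // 5], idx[len(idx) // 5:]

cfg = r.DecoderConfig(conv_filters=(12, 24), fc_units=(64,), dropout=0.2,
                      learning_rate=0.008, epochs=20, batch_size=64, seed=4)
decoder = r.build_decoder(cfg, imgs.shape[1:])
print(f"decoder: {decoder.n_params()} trainable parameters")
r.train(decoder, imgs[train], cats[train], cfg)
print(f"best validation accuracy: {max(decoder.history['val_accuracy']):.3f}")

metrics = r.evaluate(decoder, imgs[test], cats[test])
print(f"test accuracy: {metrics['accuracy']:.3f}")
print("per-class precision / recall / F1:")
for cls, m in metrics["per_class"].items():
    print(f"  {cls:7s}: {m['precision']:.2f} / {m['recall']:.2f} / "
          f"{m['f1']:.2f}  (n = {m['support']})")
print(f"macro F1: {metrics['macro']['f1']:.2f}, mean softmax score of the "
      f"correct class: {metrics['mean_correct_softmax']:.2f}")
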