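"""End-to-end orchestration: synth -> cluster -> augment -> filter ->
topomap -> train -> saliency -> stats.

Each stage reads the previous stage's persisted artifacts from the run
directory, writes its own artifact plus a JSON manifest (parameters, seed,
input hash, in/out counts), and can be rerun independently; a single
global seed is fanned out as ``seed + stage_index`` so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as aug
from . import clustering, nn, saliency, stats, synth, topomap, tpe
from .montage import default_montage, project_montage

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "cluster", "augment", "filter", "topomap", "train",
          "saliency", "stats")


@dataclass
class PipelineConfig:
    out_dir: str = "rtspect_run"
    seed: int = 0
    # synth
    n_subjects: int = 4
    trials_per_subject: int = 150
    # augment
    r: int = 20
    alpha: dict = field(default_factory=lambda: {"fast": 0.3, "medium": 0.2,
                                                 "slow": 0.1})
    n_iterations: int = 60
    n_alpha: int = 10
    # filter
    pca_k: float = 0.95
    percentile_lo: float = 25.0
    percentile_hi: float = 75.0
    # topomap
    grid: int = 32
    # decoder
    conv_filters: tuple = (8, 16)
    fc_units: tuple = (32,)
    dropout: float = 0.3
    learning_rate: float = 0.01
    optimizer: str = "adagrad"
    epochs: int = 8
    batch_size: int = 32
    val_fraction: float = 0.25
    test_fraction: float = 0.25
    use_tpe: bool = False
    tpe_budget: int = 10
    # stats
    random_intercept: str | None = "sample"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        cfg = cls(**d)
        cfg.conv_filters = tuple(cfg.conv_filters)
        cfg.fc_units = tuple(cfg.fc_units)
        return cfg


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return int(cfg.seed) + STAGES.index(stage)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest(run: Path, stage: str, cfg: PipelineConfig, t0: float,
              inputs: list[Path], counts: dict) -> None:
    payload = {
        "stage": stage,
        "seed": _stage_seed(cfg, stage),
        "elapsed_s": round(time.time() - t0, 3),
        "inputs": {str(p.name): _hash_file(p) for p in inputs if p.exists()},
        "counts": counts,
        "config": {k: v for k, v in asdict(cfg).items()
                   if not isinstance(v, (dict, list, tuple))},
    }
    with open(run / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifact {path}")
    return path


# --------------------------------------------------------------------------
# stages

def stage_synth(cfg: PipelineConfig) -> Path:
    run = Path(cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    ts = synth.generate_trials(cfg.n_subjects, cfg.trials_per_subject,
                               seed=_stage_seed(cfg, "synth"))
    synth.save_trialset(ts, run / "trials")
    _manifest(run, "synth", cfg, t0, [], {"trials_out": ts.n_trials})
    return run


def stage_cluster(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = _require(run / "trials.npz", "cluster")
    ts = synth.load_trialset(run / "trials")
    model = clustering.fit_gmm_bic(ts.rt_ms, seed=_stage_seed(cfg, "cluster"))
    labels = clustering.assign_categories(model, ts.rt_ms)
    model.to_json(run / "rt_model.json")
    pd.DataFrame({"label": labels}).to_csv(run / "rt_labels.csv", index=False)
    _manifest(run, "cluster", cfg, t0, [src],
              {"trials_in": ts.n_trials,
               "outliers": int((labels == "outlier").sum()),
               "components": model.n_components})


def stage_augment(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = [_require(run / "trials.npz", "augment"),
           _require(run / "rt_labels.csv", "augment")]
    ts = synth.load_trialset(run / "trials")
    labels = pd.read_csv(run / "rt_labels.csv")["label"].to_numpy()
    params = aug.BootstrapParams(r=cfg.r, alpha=dict(cfg.alpha),
                                 n=cfg.n_iterations, n_alpha=cfg.n_alpha,
                                 seed=_stage_seed(cfg, "augment"))
    erps = aug.bootstrap_erps(ts, labels, params)
    np.savez_compressed(run / "augmented.npz", erps=erps.erps)
    aug.provenance_table(erps).assign(
        subject=erps.subject_id, category=erps.category).to_csv(
        run / "augmented_meta.csv", index=False)
    _manifest(run, "augment", cfg, t0, src,
              {"trials_in": int((labels != "outlier").sum()),
               "samples_out": erps.n_samples})


def _load_augmented(run: Path) -> aug.AugmentedERPSet:
    ts = synth.load_trialset(run / "trials")
    erps = np.load(run / "augmented.npz")["erps"]
    meta = pd.read_csv(run / "augmented_meta.csv")
    return aug.AugmentedERPSet(
        erps=erps, category=meta["category"].to_numpy(),
        subject_id=meta["subject"].to_numpy(),
        provenance=meta["trials_averaged"].to_numpy(),
        sfreq=ts.sfreq, epoch_window=ts.epoch_window,
        channel_names=ts.channel_names)


def stage_filter(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = [_require(run / "augmented.npz", "filter")]
    ts = synth.load_trialset(run / "trials")
    erps = _load_augmented(run)
    kept = aug.eigenspace_filter(ts, erps, k=cfg.pca_k,
                                 lo=cfg.percentile_lo, hi=cfg.percentile_hi)
    np.savez_compressed(run / "filtered.npz", erps=kept.erps)
    aug.provenance_table(kept).to_csv(run / "filtered_meta.csv", index=False)
    _manifest(run, "filter", cfg, t0, src,
              {"samples_in": erps.n_samples, "samples_out": kept.n_samples})


def stage_topomap(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = [_require(run / "filtered.npz", "topomap")]
    ts = synth.load_trialset(run / "trials")
    erps = np.load(run / "filtered.npz")["erps"]
    meta = pd.read_csv(run / "filtered_meta.csv")
    montage = default_montage()
    images, last = topomap.topomap_pipeline(erps, ts.sfreq, montage,
                                            grid=(cfg.grid, cfg.grid))
    np.savez_compressed(run / "topomaps.npz", images=images,
                        electrode_pixels=last.electrode_pixels)
    meta.to_csv(run / "topomap_labels.csv", index=False)
    _manifest(run, "topomap", cfg, t0, src,
              {"samples_in": erps.shape[0], "images_out": images.shape[0]})


def _decoder_config(cfg: PipelineConfig, seed: int) -> nn.DecoderConfig:
    return nn.DecoderConfig(
        conv_filters=cfg.conv_filters, fc_units=cfg.fc_units,
        dropout=cfg.dropout, optimizer=cfg.optimizer,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, val_fraction=cfg.val_fraction, seed=seed)


def stage_train(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = [_require(run / "topomaps.npz", "train")]
    seed = _stage_seed(cfg, "train")
    images = np.load(run / "topomaps.npz")["images"]
    meta = pd.read_csv(run / "topomap_labels.csv")
    labels = meta["category"].to_numpy()
    rng = np.random.default_rng(seed)
    test_idx, train_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_test = max(1, int(round(cfg.test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)

    if cfg.use_tpe:
        def objective(params):
            c = tpe.config_from_params(params, epochs=max(2, cfg.epochs // 2),
                                       seed=seed, batch_size=cfg.batch_size)
            d = nn.build_decoder(c, images.shape[1:])
            nn.train(d, images[train_idx], labels[train_idx], c)
            return max(d.history["val_accuracy"])
        best, log = tpe.tpe_search(tpe.decoder_space(), cfg.tpe_budget,
                                   objective, seed=seed)
        pd.DataFrame([{**t["params"], "score": t["score"],
                       "trial": t["trial"]} for t in log]).to_csv(
            run / "tpe_log.csv", index=False)
        dcfg = tpe.config_from_params(best, epochs=cfg.epochs, seed=seed,
                                      batch_size=cfg.batch_size)
    else:
        dcfg = _decoder_config(cfg, seed)

    decoder = nn.build_decoder(dcfg, images.shape[1:])
    nn.train(decoder, images[train_idx], labels[train_idx], dcfg)
    metrics = nn.evaluate(decoder, images[test_idx], labels[test_idx])
    decoder.save_weights(run / "decoder_weights.npz")
    with open(run / "decoder_config.json", "w") as fh:
        json.dump(asdict(dcfg), fh, indent=1)
    with open(run / "metrics.json", "w") as fh:
        json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in metrics.items()}, fh, indent=1)
    np.save(run / "test_idx.npy", test_idx)
    _manifest(run, "train", cfg, t0, src,
              {"images_in": images.shape[0], "train": len(train_idx),
               "test": len(test_idx),
               "test_accuracy": round(metrics["accuracy"], 4)})


def _load_decoder(run: Path, input_shape) -> nn.Decoder:
    with open(run / "decoder_config.json") as fh:
        d = json.load(fh)
    dcfg = nn.DecoderConfig(**d)
    decoder = nn.build_decoder(dcfg, input_shape)
    decoder.load_weights(run / "decoder_weights.npz")
    return decoder


def stage_saliency(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = [_require(run / "decoder_weights.npz", "saliency"),
           _require(run / "topomaps.npz", "saliency")]
    arrs = np.load(run / "topomaps.npz")
    images, pixels = arrs["images"], arrs["electrode_pixels"]
    meta = pd.read_csv(run / "topomap_labels.csv")
    test_idx = np.load(run / "test_idx.npy")
    decoder = _load_decoder(run, images.shape[1:])
    montage = default_montage()
    table = saliency.activation_table(
        decoder, images[test_idx], pixels, montage.channel_names,
        ("alpha", "beta", "gamma"),
        subjects=meta["subject"].to_numpy()[test_idx])
    table.to_csv(run / "activations.csv", index=False)
    _manifest(run, "saliency", cfg, t0, src,
              {"images_in": len(test_idx), "rows_out": len(table)})


def stage_stats(cfg: PipelineConfig) -> None:
    run = Path(cfg.out_dir)
    t0 = time.time()
    src = [_require(run / "activations.csv", "stats")]
    table = pd.read_csv(run / "activations.csv")
    try:
        report = stats.factorial_anova(table,
                                       random_intercept=cfg.random_intercept)
        report.table.to_csv(run / "anova.csv", index=False)
        anova_ok = True
    except ValueError as exc:
        logger.warning("ANOVA skipped: %s", exc)
        anova_ok = False
    posthoc = []
    for band in table["band"].unique():
        try:
            posthoc.append(tukey := stats.tukey_contrasts(table, {"band": band}))
        except ValueError:
            pass
    if posthoc:
        pd.concat(posthoc).to_csv(run / "tukey.csv", index=False)
    try:
        ranking = stats.rank_activations(table, seed=_stage_seed(cfg, "stats"))
        ranking.to_csv(run / "ranking.csv", index=False)
    except ValueError as exc:
        logger.warning("ranking skipped: %s", exc)
    _manifest(run, "stats", cfg, t0, src,
              {"rows_in": len(table), "anova": anova_ok})


_STAGE_FN = {
    "synth": stage_synth, "cluster": stage_cluster, "augment": stage_augment,
    "filter": stage_filter, "topomap": stage_topomap, "train": stage_train,
    "saliency": stage_saliency, "stats": stage_stats,
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all eight stages in order; returns the run directory."""
    run = Path(config.out_dir)
    for stage in STAGES:
        logger.info("stage %s", stage)
        _STAGE_FN[stage](config)
    return run
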