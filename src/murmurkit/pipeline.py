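"""End-to-end orchestration: recordings to murmur-detection metrics.

Stage order: filter complete patients -> synchronize (align + loop) ->
stacked audio augmentation (default 3 copies) -> Mel spectrograms ->
masked spectrogram variants (1 original + 3 masked per file) -> image
embedding -> train/test split -> MiniROCKET bias fit + transform ->
ridge fit/predict -> metrics.  Per-stage counts are persisted: with P
patients and 3 audio copies, the bookkeeping is 4P original files,
16P files after augmentation, 16P labeled groups, and 64P spectrograms
(for P = 232: 928, 3712, 3712, 14,848).

Every random stage derives its seed from the run's master seed, so a
rerun with equal config and data is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import augment, classify, embed, metrics, minirocket, spectrogram, sync
from .io import VALVES, AudioSignal, filter_complete_patients, read_patient_table, read_wav, resample
from .sync import ValveChannelSet

logger = logging.getLogger("murmurkit")

__all__ = ["RunConfig", "PipelineResult", "load_dataset", "run_pipeline", "evaluate_repeats"]


@dataclass
class RunConfig:
    """All pipeline knobs, serialized verbatim into each run's output."""

    seed: int = 0
    target_rate: int = 4000
    # synchronization; target_len_s=None loops to the dataset's longest recording
    sync_smooth_win_s: float = sync.DEFAULT_SMOOTH_WIN_S
    sync_min_sep_s: float = sync.DEFAULT_MIN_SEP_S
    target_len_s: float | None = sync.DEFAULT_TARGET_LEN_S
    # audio augmentation
    aug_depth: int = augment.DEFAULT_DEPTH
    aug_n_copies: int = augment.DEFAULT_N_COPIES
    aug_ranges: augment.AugmentRanges = field(default_factory=augment.AugmentRanges)
    # spectrograms
    mel: spectrogram.MelParams = field(default_factory=spectrogram.MelParams)
    mask_max_ms: float = spectrogram.DEFAULT_MAX_MASK_MS
    mask_max_freq_bins: int = spectrogram.DEFAULT_MAX_FREQ_MASK_BINS
    n_spec_variants: int = 4  # 1 original + 3 masked
    # embedding
    embedder: str = "fixture"
    embed_dim: int = embed.DEFAULT_DIM
    image_size: int = embed.DEFAULT_IMAGE_SIZE
    # MiniROCKET
    mr_n_features: int = minirocket.DEFAULT_N_FEATURES
    mr_mv_mode: str = "per_channel"
    mr_bias_mode: str = "quantile"
    mr_bias_sample: int = minirocket.DEFAULT_BIAS_SAMPLE
    # classifier / split
    fraction_train: float = 0.8
    split_mode: str = "patient_level"
    standardize: bool = True
    class_weight: str | None = None
    # caching
    cache_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "aug_ranges" in raw:
            raw["aug_ranges"] = augment.AugmentRanges(
                **{k: tuple(v) for k, v in raw["aug_ranges"].items()}
            )
        if "mel" in raw:
            raw["mel"] = spectrogram.MelParams(**raw["mel"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    counts: dict
    report: metrics.MetricsReport
    confusion: metrics.ConfusionCounts
    model: classify.RidgeModel
    split: classify.SplitPlan
    embedding: embed.EmbeddingArray
    config: RunConfig


def load_dataset(table_path, config: RunConfig) -> list:
    """Read a patient table, keep complete patients, load + resample audio."""
    records = filter_complete_patients(read_patient_table(table_path))
    groups = []
    for rec in records:
        channels = {}
        for valve in VALVES:
            sig = read_wav(rec.files[valve])
            channels[valve] = resample(sig, config.target_rate)
        n_min = min(len(s) for s in channels.values())
        channels = {v: AudioSignal(s.samples[:n_min], s.rate) for v, s in channels.items()}
        groups.append(
            ValveChannelSet(channels=channels, label=rec.label,
                            patient_id=rec.patient_id, lineage=rec.patient_id)
        )
    return groups


def _cached_mel(samples: np.ndarray, rate: int, config: RunConfig):
    """Mel spectrogram with optional on-disk caching keyed by content+params."""
    if config.cache_dir is None:
        return spectrogram.mel_spectrogram(AudioSignal(samples, rate), config.mel)
    cache = Path(config.cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    key = hashlib.sha1(samples.tobytes() + repr((rate, config.mel)).encode()).hexdigest()
    path = cache / f"mel_{key}.npy"
    if path.exists():
        matrix = np.load(path)
        return spectrogram.MelSpec(
            matrix=matrix, rate=rate, hop=config.mel.hop, win=config.mel.win,
            n_mels=config.mel.n_mels, fmin=config.mel.fmin, fmax=config.mel.fmax,
        )
    spec = spectrogram.mel_spectrogram(AudioSignal(samples, rate), config.mel)
    np.save(path, spec.matrix)
    return spec


def _make_embedder(config: RunConfig):
    if config.embedder == "fixture":
        return embed.FixtureEmbedder(dim=config.embed_dim, seed=config.seed,
                                     input_size=config.image_size)
    if config.embedder == "vit":
        class _Vit:
            name, dim, deterministic = "vit", config.embed_dim, True
            def __call__(self, image):
                return embed.vit_embed(image)
        return _Vit()
    raise ValueError(f"unknown embedder {config.embedder!r}")


def build_embeddings(groups: list, config: RunConfig):
    """Stages sync -> augment -> mel -> mask -> embed; returns (array, counts)."""
    counts = {"patients": len(groups), "audio_files_original": 4 * len(groups)}
    target_len = config.target_len_s
    if target_len is None:
        target_len = max(g.n_samples / g.rate for g in groups)

    synced = []
    for g in groups:
        try:
            synced.append(sync.synchronize_group(
                g, target_len=target_len,
                min_sep=config.sync_min_sep_s, smooth_win=config.sync_smooth_win_s))
        except sync.SyncError as exc:
            raise sync.SyncError(f"synchronize: patient {g.patient_id}: {exc}") from exc

    audio_groups = []
    for g in synced:
        audio_groups.append(g)
        audio_groups.extend(augment.make_augmented_copies(
            g, n_copies=config.aug_n_copies, depth=config.aug_depth,
            seed=config.seed, ranges=config.aug_ranges))
    counts["audio_files_augmented_total"] = 4 * len(audio_groups)
    logger.info("audio: %d groups (%d files)", len(audio_groups), 4 * len(audio_groups))

    labeled, n_specs = [], 0
    for a_idx, g in enumerate(audio_groups):
        specs = {v: spectrogram.normalize(_cached_mel(g.channels[v].samples, g.rate, config))
                 for v in VALVES}
        mask_seed = augment.derive_seed(config.seed, g.lineage, "mask")
        variants = spectrogram.expand_group_to_four(
            specs, mask_seed, config.mask_max_ms, config.mask_max_freq_bins)
        variants = variants[: config.n_spec_variants]
        for s_idx, variant in enumerate(variants):
            gid = f"{g.patient_id}:a{a_idx}:s{s_idx}"
            labeled.append((gid, variant, g.label, g.patient_id))
            n_specs += 4
    counts["spectrograms"] = n_specs
    counts["labeled_groups"] = len(labeled)
    logger.info("spectrograms: %d in %d labeled groups", n_specs, len(labeled))

    embedder = _make_embedder(config)
    array = embed.build_embedding_array(labeled, embedder, size=config.image_size)
    return array, counts


def classify_embeddings(array: embed.EmbeddingArray, config: RunConfig, seed=None):
    """Stages split -> MiniROCKET -> ridge -> metrics on a prebuilt array."""
    seed = config.seed if seed is None else seed
    split = classify.make_split(
        array.group_ids, array.labels, fraction_train=config.fraction_train,
        seed=seed, mode=config.split_mode, patient_ids=array.patient_ids)
    bank = minirocket.build_kernel_bank(
        input_length=array.dim, n_features=config.mr_n_features,
        n_channels=array.values.shape[1], mv_mode=config.mr_mv_mode,
        bias_mode=config.mr_bias_mode, seed=seed)
    train_values = array.values[split.train_ids]
    bank = minirocket.fit_biases(train_values, bank, seed=seed,
                                 max_sample=config.mr_bias_sample)
    fm_train = minirocket.transform(train_values, bank)
    fm_test = minirocket.transform(array.values[split.test_ids], bank)
    model = classify.fit(fm_train, array.labels[split.train_ids],
                         standardize=config.standardize, class_weight=config.class_weight)
    y_pred, _ = classify.predict(model, fm_test)
    conf = metrics.confusion(array.labels[split.test_ids], y_pred)
    return metrics.report(conf), conf, model, split


def run_pipeline(groups_or_table, config: RunConfig | None = None, out_dir=None) -> PipelineResult:
    """Run the full flow on ValveChannelSets or a patient-table path."""
    config = config or RunConfig()
    if isinstance(groups_or_table, (str, Path)):
        groups = load_dataset(groups_or_table, config)
    else:
        groups = list(groups_or_table)
    if not groups:
        raise ValueError("no complete patients to process")
    array, counts = build_embeddings(groups, config)
    rep, conf, model, split = classify_embeddings(array, config)
    counts["train_groups"] = len(split.train_ids)
    counts["test_groups"] = len(split.test_ids)
    result = PipelineResult(counts=counts, report=rep, confusion=conf,
                            model=model, split=split, embedding=array, config=config)
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    (out_dir / "counts.json").write_text(json.dumps(result.counts, indent=2))
    (out_dir / "metrics.json").write_text(result.report.to_json())
    c = result.confusion
    (out_dir / "confusion.csv").write_text(
        "tp,fp,tn,fn\n" + f"{c.tp},{c.fp},{c.tn},{c.fn}\n")
    classify.save_model(result.model, out_dir / "model")
    rows = classify.top_features(result.model, k=30)
    with open(out_dir / "top_features.tsv", "w") as fh:
        fh.write("feature\tkernel\tdilation\tchannels\tcoefficient\n")
        for fid, coef in rows:
            fh.write(f"{fid.get('feature')}\t{fid.get('kernel', '')}\t"
                     f"{fid.get('dilation', '')}\t{fid.get('channels', '')}\t{coef:.6g}\n")


def evaluate_repeats(array: embed.EmbeddingArray, config: RunConfig, n_repeats: int = 10):
    """Re-run split/fit/predict with derived seeds; mean-of-metrics aggregation."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    reports, confusions = [], []
    for i in range(n_repeats):
        seed = augment.derive_seed(config.seed, "repeat", i) if n_repeats > 1 else config.seed
        rep, conf, _, _ = classify_embeddings(array, config, seed=seed)
        reports.append(rep)
        confusions.append(conf)
    return metrics.aggregate_reports(reports), reports, confusions
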