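"""Reproducible training loops for alignment pretraining and text-guided
segmentation fine-tuning.

Training follows the published recipe: Adam, batch 16, temperature 0.07,
sum of bidirectional global and local InfoNCE terms for alignment, and
Dice + cross-entropy for segmentation, with rotation (+/-10 deg),
horizontal-flip and intensity augmentation.  A ``tiny`` desk-scale preset
(64 x 64 phantoms, small encoders, 30 epochs) drives the test suite; the
paper-scale preset is retained in configuration only.

All randomness (shuffling, augmentation, label-fraction subsetting,
parameter init) descends from a single seed via independent child
generators, so identical seeds reproduce identical runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .alignment_core import TemperatureSet, batched_local_nce, global_nce_loss
from .encoders import AlignmentModel, EncoderSpec, VisualEncoder, aggregation_matrix
from .nn import Tensor, Adam
from .phantom_forge import PhantomSample, SplitManifest
from .seg_decoder import (DecoderConfig, SegmentationModel, one_hot,
                          segmentation_loss)
from .text_processing import TokenizedReport, Vocabulary, build_vocabulary, \
    tokenize_report

__all__ = ["AugmentationConfig", "TrainConfig", "TrainHistory",
           "augment_sample", "train_alignment", "train_segmentation",
           "TextBatch", "prepare_text", "embed_text_features",
           "retrieval_similarity", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_deg: float = 10.0
    hflip_prob: float = 0.5
    gain_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.02


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    temps: TemperatureSet = field(default_factory=TemperatureSet)
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    augment: bool = True
    seed: int = 0
    label_fraction: float = 1.0
    n_runs: int = 3
    reduction: str = "sum"
    val_every: int = 5
    adam_betas: tuple[float, float] = (0.9, 0.99)
    max_subword_len: int = 6

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be > 0 and batch_size >= 1")
        if not (0 < self.label_fraction <= 1):
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        defaults = dict(epochs=30)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainHistory:
    losses: list[dict] = field(default_factory=list)       # one dict per epoch
    val_metrics: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = -np.inf
    seed: int = 0
    config: dict = field(default_factory=dict)


def _snapshot(cfg: TrainConfig) -> dict:
    return json.loads(json.dumps(asdict(cfg)))


# ---------------------------------------------------------------------------
# augmentation

def augment_sample(image: np.ndarray, mask: np.ndarray | None,
                   aug: AugmentationConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray | None]:
    """Synchronized geometric + image-only intensity augmentation.

    Rotation angle ~ U(-rotation_deg, +rotation_deg) with bilinear
    resampling for the image and nearest-neighbor for the mask; a shared
    horizontal flip; multiplicative gain and additive Gaussian noise applied
    to the image only, then clipped to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    angle = rng.uniform(-aug.rotation_deg, aug.rotation_deg)
    flip = rng.random() < aug.hflip_prob
    gain = rng.uniform(*aug.gain_range)
    noise = rng.normal(0.0, aug.noise_sd, size=image.shape) if aug.noise_sd > 0 else 0.0

    out = image
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1,
                             mode="constant", cval=float(np.median(image)))
    if flip:
        out = out[:, ::-1]
    out = np.clip(out * gain + noise, 0.0, 1.0)

    out_mask = None
    if mask is not None:
        out_mask = np.asarray(mask)
        if angle != 0.0:
            out_mask = ndimage.rotate(out_mask, angle, reshape=False, order=0,
                                      mode="constant", cval=0)
        if flip:
            out_mask = out_mask[:, ::-1]
        out_mask = np.ascontiguousarray(out_mask)
    return np.ascontiguousarray(out), out_mask


# ---------------------------------------------------------------------------
# text batching

@dataclass
class TextBatch:
    token_ids: np.ndarray      # (B, N)
    pad_mask: np.ndarray       # (B, N)
    agg: np.ndarray            # (B, Wmax, N)
    word_mask: np.ndarray      # (B, Wmax)
    toks: list[TokenizedReport]


def prepare_text(reports: list[str], vocab: Vocabulary,
                 max_subword_len: int | None = None) -> TextBatch:
    toks = [tokenize_report(r, vocab, max_subword_len) for r in reports]
    N = max(t.n_tokens for t in toks)
    Wmax = max(t.n_words for t in toks)
    B = len(toks)
    ids = np.full((B, N), vocab.pad_id, dtype=int)
    pad_mask = np.zeros((B, N))
    agg = np.zeros((B, Wmax, N))
    word_mask = np.zeros((B, Wmax))
    for b, t in enumerate(toks):
        ids[b, :t.n_tokens] = t.token_ids
        pad_mask[b, :t.n_tokens] = 1.0
        agg[b] = aggregation_matrix(t.word_map, N, Wmax)
        word_mask[b, :t.n_words] = 1.0
    return TextBatch(ids, pad_mask, agg, word_mask, toks)


def embed_text_features(model: AlignmentModel, batch: TextBatch
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frozen-text convenience: (t_g (B,D), t_l (B,Wmax,D), word_mask)."""
    t_g, t_l = model.embed_texts(batch.token_ids, batch.pad_mask,
                                 batch.agg, batch.word_mask)
    return t_g.data, t_l.data, batch.word_mask


# ---------------------------------------------------------------------------
# alignment pretraining

def _split_samples(samples: list[PhantomSample], ids: list[str]
                   ) -> list[PhantomSample]:
    idset = set(ids)
    return [s for s in samples if s.patient_id in idset]


def retrieval_similarity(model: AlignmentModel, samples: list[PhantomSample],
                         vocab: Vocabulary, temps: TemperatureSet,
                         use_local: bool = True) -> np.ndarray:
    """Image x report similarity matrix over a sample list.

    Global cosine similarity, plus the local match score Z when
    ``use_local`` (both computed from the same checkpoint, mirroring the
    global+local retrieval configuration).
    """
    from .alignment_core import _batched_scores

    images = np.stack([s.image for s in samples])[:, None]
    batch = prepare_text([s.report for s in samples], vocab)
    v_g, v_l, _ = model.embed_images(Tensor(images))
    t_g, t_l = model.embed_texts(batch.token_ids, batch.pad_mask,
                                 batch.agg, batch.word_mask)
    sim = v_g.data @ t_g.data.T
    if use_local:
        z = _batched_scores(Tensor(v_l.data), Tensor(t_l.data),
                            batch.word_mask, temps).data
        sim = sim + z
    return sim


def hit_at_1(sim: np.ndarray) -> float:
    """Fraction of query images whose paired report ranks first."""
    return float(np.mean(np.argmax(sim, axis=1) == np.arange(sim.shape[0])))


def train_alignment(samples: list[PhantomSample], split: SplitManifest,
                    cfg: TrainConfig, spec: EncoderSpec | None = None
                    ) -> tuple[AlignmentModel, Vocabulary, TrainHistory]:
    """Minimize the bidirectional global + local contrastive objective.

    Returns the model restored to its best-validation-hit@1 parameters,
    the vocabulary built from the training reports, and the history.
    """
    spec = spec or EncoderSpec.tiny()
    train = _split_samples(samples, split.train)
    val = _split_samples(samples, split.val)
    if not train or not val:
        raise ValueError("empty train or validation split")

    vocab = build_vocabulary([s.report for s in train],
                             max_subword_len=cfg.max_subword_len)
    model = AlignmentModel(spec, len(vocab), seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.adam_betas)
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    text_all = prepare_text([s.report for s in train], vocab)
    history = TrainHistory(seed=cfg.seed, config=_snapshot(cfg))
    best_state = model.state_dict()

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(train))
        sums = {"global_v|t": 0.0, "global_t|v": 0.0,
                "local_v|t": 0.0, "local_t|v": 0.0, "total": 0.0}
        n_seen = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue
            imgs = []
            for i in idx:
                img = train[i].image
                if cfg.augment:
                    img, _ = augment_sample(img, None, cfg.augmentation, aug_rng)
                imgs.append(img)
            images = Tensor(np.stack(imgs)[:, None])
            v_g, v_l, _ = model.embed_images(images)
            t_g, t_l = model.embed_texts(text_all.token_ids[idx],
                                         text_all.pad_mask[idx],
                                         text_all.agg[idx],
                                         text_all.word_mask[idx])
            g_vt = global_nce_loss(v_g, t_g, cfg.temps.t1, "v_given_t")
            g_tv = global_nce_loss(v_g, t_g, cfg.temps.t1, "t_given_v")
            l_vt = batched_local_nce(v_l, t_l, text_all.word_mask[idx],
                                     cfg.temps, "v_given_t")
            l_tv = batched_local_nce(v_l, t_l, text_all.word_mask[idx],
                                     cfg.temps, "t_given_v")
            loss = cfg.lambda1 * (g_vt + g_tv) + cfg.lambda2 * (l_vt + l_tv)
            if cfg.reduction == "mean":
                loss = loss / float(len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums["global_v|t"] += g_vt.item()
            sums["global_t|v"] += g_tv.item()
            sums["local_v|t"] += l_vt.item()
            sums["local_t|v"] += l_tv.item()
            sums["total"] += (cfg.lambda1 * (g_vt.item() + g_tv.item())
                              + cfg.lambda2 * (l_vt.item() + l_tv.item()))
            n_seen += len(idx)
        history.losses.append({k: v / max(n_seen, 1) for k, v in sums.items()})

        if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
            sim = retrieval_similarity(model, val, vocab, cfg.temps)
            metric = hit_at_1(sim)
            history.val_metrics.append({"epoch": epoch, "hit@1": metric})
            if metric >= history.best_metric:
                history.best_metric = metric
                history.best_epoch = epoch
                best_state = model.state_dict()

    model.load_state_dict(best_state)
    return model, vocab, history


# ---------------------------------------------------------------------------
# segmentation fine-tuning

def label_fraction_patients(train_patients: list[str], fraction: float,
                            seed: int) -> list[str]:
    """Seeded nested patient subsets: fraction a <= b implies subset(a) ⊆ subset(b)."""
    order = list(np.random.default_rng(seed).permutation(sorted(train_patients)))
    k = int(np.floor(fraction * len(order)))
    if k == 0:
        raise ValueError(
            f"label fraction {fraction} yields zero of {len(order)} train patients")
    return order[:k]


def _foreground_dice(pred_mask: np.ndarray, true_mask: np.ndarray,
                     k_classes: int) -> float:
    from .evaluation import dice_coefficient
    scores = [dice_coefficient(pred_mask, true_mask, c)
              for c in range(1, k_classes)]
    return float(np.mean(scores))


def evaluate_segmentation(model: SegmentationModel,
                          samples: list[PhantomSample],
                          t_l: np.ndarray | None, word_mask: np.ndarray | None,
                          batch_size: int = 16) -> float:
    """Mean foreground Dice of argmax predictions over a sample list."""
    scores = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        images = Tensor(np.stack([s.image for s in chunk])[:, None])
        tl = Tensor(t_l[start:start + len(chunk)]) if t_l is not None else None
        wm = word_mask[start:start + len(chunk)] if word_mask is not None else None
        probs = model(images, tl, wm).data
        preds = np.argmax(probs, axis=1)
        for p, s in zip(preds, chunk):
            scores.append(_foreground_dice(p, s.mask, model.cfg.k_classes))
    return float(np.mean(scores))


def train_segmentation(samples: list[PhantomSample], split: SplitManifest,
                       cfg: TrainConfig, init: str = "random",
                       align_model: AlignmentModel | None = None,
                       vocab: Vocabulary | None = None,
                       seg_cfg: DecoderConfig | None = None,
                       spec: EncoderSpec | None = None
                       ) -> tuple[SegmentationModel, TrainHistory]:
    """Minimize Dice + cross-entropy over the labeled training fraction.

    ``init='aligned-checkpoint'`` copies the pretrained visual encoder and
    uses the pretrained (frozen) text pipeline for modulation;
    ``init='random'`` starts from fresh weights with an untrained frozen
    text pipeline.  Only train-split patients, subset by
    ``cfg.label_fraction`` at the patient level, contribute gradients.
    """
    if init not in ("random", "aligned-checkpoint"):
        raise ValueError("init must be 'random' or 'aligned-checkpoint'")
    if init == "aligned-checkpoint" and (align_model is None or vocab is None):
        raise ValueError("aligned-checkpoint init requires align_model and vocab")
    spec = spec or (align_model.spec if align_model else EncoderSpec.tiny())
    seg_cfg = seg_cfg or DecoderConfig()

    labeled = label_fraction_patients(split.train, cfg.label_fraction, cfg.seed)
    train = _split_samples(samples, labeled)
    val = _split_samples(samples, split.val)
    if not train or not val:
        raise ValueError("empty train or validation split")

    # frozen text pipeline supplying word embeddings for modulation
    if vocab is None:
        vocab = build_vocabulary([s.report for s in samples])
    text_model = align_model if align_model is not None else \
        AlignmentModel(spec, len(vocab), seed=cfg.seed + 1)

    def frozen_text(sample_list):
        if not seg_cfg.text_modulation:
            return None, None
        batch = prepare_text([s.report for s in sample_list], vocab)
        _, t_l, word_mask = embed_text_features(text_model, batch)
        return t_l, word_mask

    encoder = VisualEncoder(spec, np.random.default_rng(cfg.seed + 2))
    if init == "aligned-checkpoint":
        encoder.load_state_dict(align_model.visual.state_dict())
    model = SegmentationModel(encoder, seg_cfg, text_dim=spec.shared_dim,
                              seed=cfg.seed + 3)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.adam_betas)
    ss = np.random.SeedSequence(cfg.seed + 4)
    shuffle_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    model._frozen_text = (text_model, vocab)   # pipeline reused at eval time
    t_l_train, wm_train = frozen_text(train)
    t_l_val, wm_val = frozen_text(val)
    k = seg_cfg.k_classes
    history = TrainHistory(seed=cfg.seed, config=_snapshot(cfg))
    best_state = model.state_dict()

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(train))
        total = 0.0
        n_seen = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, m = train[i].image, train[i].mask
                if cfg.augment:
                    img, m = augment_sample(img, m, cfg.augmentation, aug_rng)
                imgs.append(img)
                masks.append(m)
            images = Tensor(np.stack(imgs)[:, None])
            target = one_hot(np.stack(masks), k)
            tl = Tensor(t_l_train[idx]) if t_l_train is not None else None
            wm = wm_train[idx] if wm_train is not None else None
            probs = model(images, tl, wm)
            loss = segmentation_loss(probs, target, seg_cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
            n_seen += len(idx)
        history.losses.append({"seg": total / max(n_seen, 1)})

        if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
            dice = evaluate_segmentation(model, val, t_l_val, wm_val)
            history.val_metrics.append({"epoch": epoch, "dice": dice})
            if dice >= history.best_metric:
                history.best_metric = dice
                history.best_epoch = epoch
                best_state = model.state_dict()

    model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | Path, model, vocab: Vocabulary | None = None,
                    meta: dict | None = None) -> None:
    """Parameters as .npz with a JSON sidecar (vocabulary + metadata)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    side = {"meta": meta or {}}
    if vocab is not None:
        side["vocab"] = vocab.token_to_id
    path.with_suffix(".json").write_text(json.dumps(side))


def load_checkpoint(path: str | Path, model) -> dict:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    side_path = path.with_suffix(".json")
    return json.loads(side_path.read_text()) if side_path.exists() else {}
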