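"""End-to-end benchmark runners on synthetic phantoms.

These functions reproduce the study's desk-scale experimental protocol:
alignment pretraining with retrieval/localization/zero-shot evaluation, and
text-guided segmentation across label fractions with random vs pretrained
initialization.  The same runners back the acceptance script and the
end-to-end tests, so reported numbers always come from a fresh computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .alignment_core import TemperatureSet
from .encoders import AlignmentModel, EncoderSpec
from .evaluation import attention_overlay, auroc
from .phantom_forge import SamplerParams, generate_dataset, patient_split
from .seg_decoder import DecoderConfig
from .text_processing import Vocabulary
from .training import (TrainConfig, _split_samples, hit_at_1, load_checkpoint,
                       retrieval_similarity, train_alignment,
                       train_segmentation)

__all__ = ["ZERO_SHOT_PROMPTS", "encode_prompt",
           "instrumentation_zero_shot_auroc", "run_alignment_benchmark",
           "run_segmentation_benchmark", "load_alignment_checkpoint",
           "derive_seeds"]

#: fixed prompt sets over the report vocabulary, one list per class
ZERO_SHOT_PROMPTS: dict[str, list[str]] = {
    # one prompt per lumbar level so the class embedding marginalizes over
    # where the hardware sits
    "instrumentation": [
        f"pedicle screw fixation with rod instrumentation at the l{i} "
        "vertebra ." for i in range(1, 6)
    ],
    # negatives cover both normal studies and non-hardware pathology
    "no_instrumentation": [
        "vertebral bodies show normal alignment .",
        "no instrumentation or degeneration is seen .",
        "disc space narrowing with degeneration at the l2 disc space .",
        "disc space narrowing with degeneration at the l4 disc space .",
    ],
}


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, deterministic in ``base_seed``."""
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def encode_prompt(model: AlignmentModel, vocab: Vocabulary, text: str
                  ) -> np.ndarray:
    """Global text embedding t_g of one prompt."""
    from .training import prepare_text

    batch = prepare_text([text], vocab)
    t_g, _ = model.embed_texts(batch.token_ids, batch.pad_mask,
                               batch.agg, batch.word_mask)
    return t_g.data[0]


def instrumentation_zero_shot_auroc(model: AlignmentModel, vocab: Vocabulary,
                                    samples) -> float:
    """AUROC for instrumentation presence from prompt-embedding similarity."""
    from .evaluation import zero_shot_classify
    from .nn import Tensor

    images = np.stack([s.image for s in samples])[:, None]
    v_g, _, _ = model.embed_images(Tensor(images))
    out = zero_shot_classify(v_g.data, ZERO_SHOT_PROMPTS,
                             lambda p: encode_prompt(model, vocab, p))
    pos = out["classes"].index("instrumentation")
    neg = out["classes"].index("no_instrumentation")
    scores = out["cosine"][:, pos] - out["cosine"][:, neg]
    labels = np.array([s.labels["instrumentation"] for s in samples])
    return auroc(scores, labels)


def run_alignment_benchmark(base_seed: int, n_patients: int = 200,
                            epochs: int = 30, n_seeds: int = 3,
                            spec: EncoderSpec | None = None) -> dict:
    """Alignment pretraining with retrieval, localization and zero-shot
    evaluation on the held-out test patients, repeated over seeds.

    Reports per-seed values and the across-seed medians of: image-to-report
    hit@1, the localization enrichment of the word "screw" on instrumented
    test phantoms, zero-shot instrumentation AUROC, and the ratio of final
    to first epoch training loss.
    """
    spec = spec or EncoderSpec.tiny()
    runs = []
    models = []
    for seed in derive_seeds(base_seed, n_seeds):
        samples = generate_dataset(n_patients, 1,
                                   SamplerParams(unique_findings=True), seed)
        split = patient_split(samples, seed=seed)
        cfg = TrainConfig.tiny(seed=seed, epochs=epochs, val_every=2)
        model, vocab, hist = train_alignment(samples, split, cfg, spec=spec)
        test = _split_samples(samples, split.test)
        sim = retrieval_similarity(model, test, vocab, cfg.temps)

        instrumented = [s for s in test if s.labels["instrumentation"] == 1]
        loc_scores = [attention_overlay(s, "screw", model, vocab,
                                        cfg.temps).localization_score
                      for s in instrumented]
        runs.append({
            "seed": seed,
            "hit@1": hit_at_1(sim),
            "screw_localization": float(np.median(loc_scores))
            if loc_scores else float("nan"),
            "zero_shot_auroc": instrumentation_zero_shot_auroc(model, vocab,
                                                               test),
            "loss_first": hist.losses[0]["total"],
            "loss_final": hist.losses[-1]["total"],
        })
        models.append((model, vocab))
    result = {
        "runs": runs,
        "median_hit@1": float(np.median([r["hit@1"] for r in runs])),
        "median_screw_localization": float(np.median(
            [r["screw_localization"] for r in runs])),
        "median_zero_shot_auroc": float(np.median(
            [r["zero_shot_auroc"] for r in runs])),
        "loss_decrease_ratio": float(np.median(
            [r["loss_final"] / r["loss_first"] for r in runs])),
        "_models": models,
    }
    return result


def run_segmentation_benchmark(base_seed: int, n_patients: int = 143,
                               epochs: int = 30, n_seeds: int = 3,
                               fractions: tuple[float, ...] = (0.01, 0.1, 1.0),
                               align_models: list | None = None,
                               spec: EncoderSpec | None = None,
                               batch_size: int = 4, lr: float = 1e-3) -> dict:
    """Label-fraction segmentation study: random init across fractions plus
    pretrained-encoder init at the 10% fraction, repeated over seeds.

    Returns per-seed test foreground Dice and across-seed medians per
    configuration.
    """
    spec = spec or EncoderSpec.tiny()
    seeds = derive_seeds(base_seed, n_seeds)
    per_fraction: dict[float, list[float]] = {f: [] for f in fractions}
    aligned_10: list[float] = []
    for i, seed in enumerate(seeds):
        samples = generate_dataset(n_patients, 1, SamplerParams(), seed)
        split = patient_split(samples, seed=seed)

        def run(fraction: float, init: str, align_model=None, vocab=None):
            cfg = TrainConfig.tiny(seed=seed, epochs=epochs, val_every=5,
                                   batch_size=batch_size, lr=lr,
                                   label_fraction=fraction)
            model, _ = train_segmentation(
                samples, split, cfg, init=init, align_model=align_model,
                vocab=vocab, seg_cfg=DecoderConfig(), spec=spec)
            return segmentation_test_dice(model, samples, split)

        for f in fractions:
            per_fraction[f].append(run(f, "random"))
        if align_models is not None:
            model_i, vocab_i = align_models[i % len(align_models)]
            aligned_10.append(run(0.1, "aligned-checkpoint", model_i, vocab_i))
    result = {
        "seeds": seeds,
        "dice_per_fraction": {str(f): per_fraction[f] for f in fractions},
        "median_dice": {str(f): float(np.median(per_fraction[f]))
                        for f in fractions},
    }
    if align_models is not None:
        result["dice_aligned_10"] = aligned_10
        result["median_dice_aligned_10"] = float(np.median(aligned_10))
    return result


def segmentation_test_dice(model, samples, split) -> float:
    """Foreground Dice of a trained segmentation model on the test split,
    using the frozen text pipeline the model was trained with."""
    from .training import (embed_text_features, evaluate_segmentation,
                           prepare_text)

    test = _split_samples(samples, split.test)
    if model.cfg.text_modulation:
        text_model, vocab = model._frozen_text
        batch = prepare_text([s.report for s in test], vocab)
        _, t_l, wm = embed_text_features(text_model, batch)
    else:
        t_l, wm = None, None
    return evaluate_segmentation(model, test, t_l, wm)


def load_alignment_checkpoint(stem: str | Path
                              ) -> tuple[AlignmentModel, Vocabulary]:
    """Rebuild an alignment model + vocabulary from a checkpoint stem."""
    side = json.loads(Path(stem).with_suffix(".json").read_text())
    vocab = Vocabulary(side["vocab"])
    model = AlignmentModel(EncoderSpec.tiny(), len(vocab), seed=0)
    load_checkpoint(stem, model)
    return model, vocab
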