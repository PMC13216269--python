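"""Shared fixtures: the expensive end-to-end benchmark runs are computed
once per session and reused by all acceptance checks that consume them."""

import numpy as np
import pytest

from glocalmm.experiments import (run_alignment_benchmark,
                                  run_segmentation_benchmark)

#: base seed for the end-to-end study fixtures
STUDY_SEED = 0


@pytest.fixture(scope="session")
def alignment_study():
    """Three seeded alignment pretraining runs at the study scale
    (200 pairs, 64x64, 30 epochs, batch 16, Adam 1e-4, temperature 0.07)."""
    return run_alignment_benchmark(STUDY_SEED)


@pytest.fixture(scope="session")
def segmentation_study(alignment_study):
    """Label-fraction segmentation study (100 train phantoms, 64x64),
    random init at 1/10/100% plus pretrained init at 10%, three seeds."""
    return run_segmentation_benchmark(
        STUDY_SEED, align_models=alignment_study["_models"])
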