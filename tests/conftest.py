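"""Shared fixtures: synthetic cohorts and one trained IHC model.

The trained model is session-scoped because training (even at desk scale)
is the expensive step; the learnability and Grad-CAM localization tests
share it.
"""

from __future__ import annotations

import numpy as np
import pytest

import her2light as hl

# Desk-scale study conditions: 12 patients x 10 patches at 128 px for the
# IHC learnability cohort (one synthetic "patient" per style offset).
IHC_COHORT = dict(n_patients=12, patches_per_patient=10, stain="IHC",
                  seed=7, size=128)


def binary_subject_split(manifest, images, seed, test_fraction=1 / 3):
    """Subject-wise split of a 4-class cohort, then binary grouping
    (negative = {0, 1+}, positive = 3+, equivocal 2+ dropped)."""
    split = hl.split_subjectwise(manifest, test_fraction, seed=seed)
    labels, keep = hl.group_labels(manifest["her2_score"], "binary")
    y = np.full(len(manifest), -1)
    y[keep] = labels
    tr = [i for i in split.train_idx if keep[i]]
    te = [i for i in split.test_idx if keep[i]]
    return (images[tr], y[tr]), (images[te], y[te]), (tr, te)


@pytest.fixture(scope="session")
def ihc_cohort():
    manifest, images, masks = hl.generate_cohort(**IHC_COHORT)
    return manifest, images, masks


@pytest.fixture(scope="session")
def trained_ihc_binary(ihc_cohort):
    """ATHER2 (128x128) fitted on the IHC cohort for the binary task under a
    subject-wise split; returns (model, test_accuracy, manifest, images, masks)."""
    manifest, images, masks = ihc_cohort
    (xtr, ytr), (xte, yte), _ = binary_subject_split(manifest, images, seed=7)
    model, _ = hl.build_ather2((128, 128, 3), 2, seed=1)
    cfg = hl.TrainConfig(initial_lr=6e-3, max_epochs=80, plateau_patience=3,
                         early_stop_patience=8, batch_size=24, seed=1)
    model, history = hl.train(model, (xtr, ytr), (xte, yte), cfg)
    _, acc = hl.evaluate(model, xte, yte)
    return model, acc, manifest, images, masks
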