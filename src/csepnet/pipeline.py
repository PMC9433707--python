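"""End-to-end pipeline runs: synthetic study → images → CNN → attribution.

`scaled_recovery_run` is the package's desk-scale validation profile: a
synthetic study with 8 subjects, 5 fixed score levels (0, 25, 50, 75, 100),
2 sentences × 20 repeats per pool, ERP images bootstrapped 400 train /
100 test with 20-epoch averages, augmentation ×2, and the ``small`` CNN
profile (128 × 128 input, filter counts ÷ 4) trained for 5 epochs.  It
exists so class recovery and electrode attribution can be measured on a
single CPU; the full-size configuration (87 subjects, 80-epoch averages,
800/200 images, ×10 augmentation, 299 × 299 CNN) uses the same code path.
"""

from __future__ import annotations

import numpy as np

from . import augment, classifier, csep, occlusion, synthetic

SCALED_IMAGE_SIZE = 128


def scaled_recovery_run(
    seed: int = 0,
    n_subjects: int = 8,
    repeats: int = 20,
    n_sentences: int = 2,
    n_train: int = 400,
    n_test: int = 100,
    n_avg: int = 20,
    augment_factor: int = 2,
    kind: str = "ERP",
    epochs: int = 5,
    fm: synthetic.ForwardModelParams = synthetic.ForwardModelParams(),
) -> dict:
    """Run the scaled validation pipeline; returns model, data and accuracy."""
    rng = np.random.default_rng(seed)
    study = synthetic.scaled_study(seed=seed, n_subjects=n_subjects,
                                   repeats=repeats, n_sentences=n_sentences, fm=fm)
    feats = None if kind == "ERP" else study.features_of_kind(kind)
    split = csep.bootstrap_dataset(
        study.pools, study.labels, n_train=n_train, n_test=n_test, kind=kind,
        seed=int(rng.integers(0, 2**31 - 1)), features=feats, n_avg=n_avg)
    train_images = split.train
    if augment_factor > 1:
        cfg = augment.AugmentationConfig(expansion_factor=augment_factor,
                                         seed=int(rng.integers(0, 2**31 - 1)))
        train_images = augment.augment_dataset(train_images, cfg)
    Xtr, ytr = csep.render_dataset(train_images, SCALED_IMAGE_SIZE)
    Xte, yte = csep.render_dataset(split.test, SCALED_IMAGE_SIZE)
    clf = classifier.CSEPImageClassifier(
        profile="small", epochs=epochs,
        random_state=int(rng.integers(0, 2**31 - 1))).fit(Xtr, ytr)
    result = classifier.evaluate_accuracy(clf, Xte, yte)
    return {
        "study": study,
        "split": split,
        "clf": clf,
        "X_test": Xte,
        "y_test": yte,
        "accuracy_pct": result["accuracy_pct"],
        "result": result,
        "history": clf.history_,
        "seed": seed,
    }


def occlusion_recovery(run: dict, k: int = None, max_images: int = 6) -> dict:
    """Fraction of the forward model's informative channels found in the top-k."""
    informative = set(synthetic.DEFAULT_INFORMATIVE_CHANNELS)
    k = k or len(informative)
    cs = occlusion.mean_occlusion_channels(
        run["clf"], run["X_test"], run["y_test"], max_images=max_images)
    top = occlusion.topk_channels(cs, k)
    recovered = informative & set(top)
    return {
        "top_channels": top,
        "recovered": sorted(recovered),
        "recovery_fraction": len(recovered) / len(informative),
        "sensitivity": cs,
    }
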