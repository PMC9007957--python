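import dataclasses

import pytest

import lwvessel as lw


def small_params(size=(64, 64), **overrides) -> lw.SynthParams:
    """Source-preset generator at a reduced resolution for fast tests."""
    return dataclasses.replace(lw.preset_params("source"), size=size, **overrides)


@pytest.fixture(scope="session")
def tiny_model():
    """A small seeded W-Net with random (untrained) weights."""
    return lw.build_wnet(lw.ArchSpec(3, 8, 3, 1), seed=0)


@pytest.fixture(scope="session")
def tiny_samples():
    return lw.make_samples(4, seed=7, params=small_params())


@pytest.fixture(scope="session")
def desk_scale_run():
    """The reference desk-scale experiment, run once per session.

    A Little W-Net trained on 20 source-preset synthetic images at 128x128 for
    500 gradient steps (seed 0), with validation-AUC model selection, train-set
    threshold calibration and a pooled evaluation on 4 held-out images.
    """
    samples = lw.make_samples(28, "source", seed=0)
    train, val, test = samples[:20], samples[20:24], samples[24:]
    cfg = lw.TrainConfig(target_iterations=500, seed=0)
    bundle = lw.run_training(train, val, spec=lw.ArchSpec(3, 8, 3, 1),
                             cfg=cfg, kind="wnet")
    train_probs = [lw.restore_native(lw.predict_tta(bundle.model, s.image_float()),
                                     s.native_size) for s in train]
    threshold = lw.calibrate_threshold(train_probs, [s.label for s in train],
                                       [s.fov for s in train])
    report = lw.evaluate_split(bundle.model, test, threshold)
    return {"bundle": bundle, "train": train, "val": val, "test": test,
            "train_probs": train_probs, "threshold": threshold,
            "report": report}
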