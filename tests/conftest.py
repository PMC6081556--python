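import numpy as np
import pytest

from emgkit import (
    GestureProfile,
    WindowConfig,
    featurize,
    init_model,
    make_benchmark,
    synthesize_recording,
    train,
    training_set,
)


@pytest.fixture(scope="session")
def two_gesture_model():
    """A quickly trained model on a trivially separable 2-gesture benchmark.

    Gesture 0 activates channel 1 only, gesture 1 activates channel 2 only;
    noise is light, so the classifier should separate them perfectly.
    """
    profiles = [
        GestureProfile(0, np.array([1.0, 0.0])),
        GestureProfile(1, np.array([0.0, 1.0])),
    ]
    schedule = [(0, 2000.0), (1, 2000.0)]
    train_rec = synthesize_recording(profiles, schedule, snr_db=25.0, seed=1)
    test_rec = synthesize_recording(profiles, schedule, snr_db=25.0, seed=2)
    config = WindowConfig()
    train_xy = training_set(featurize(train_rec, config))
    test_xy = training_set(featurize(test_rec, config))
    model = init_model([2, 4, 2], seed=0)
    run, fitted = train(
        model, train_xy, test_xy, learning_rate=0.05, max_epochs=400,
        patience=30, seed=0,
    )
    return fitted, run, train_xy, test_xy
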