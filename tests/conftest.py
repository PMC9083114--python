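import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 32x32x8 phantom with two repeated motifs, plus its degraded LR pair."""
    from tensorsr.operators import DegradationSpec
    from tensorsr.synthetic_data import PhantomSpec, degrade, generate_phantom

    spec = PhantomSpec(
        shape=(32, 32, 8),
        n_motifs=2,
        motif_size=(6, 6, 4),
        repeats_per_motif=3,
        seed=0,
    )
    gt = generate_phantom(spec)
    deg = DegradationSpec(blur_sigma=1.0, down_factor=2)
    lr = degrade(gt, deg, noise_sigma=0.01, seed=0)
    return {"spec": spec, "gt": gt, "deg": deg, "lr": lr}
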