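import numpy as np
import pytest

from myophys import synthetic


@pytest.fixture(scope="session")
def clean_ap_train():
    """Noiseless 30-beat train with beat-to-beat APD variability."""
    spec = synthetic.APTrainSpec(n_beats=30, apd90_sd=10.0, seed=3)
    return synthetic.gen_ap_train(spec)


@pytest.fixture(scope="session")
def noisy_linescan():
    """Line-scan with 10 well-separated sparks at noise 0.1*F0."""
    rng = np.random.default_rng(42)
    sparks = synthetic.random_spark_population(
        10, rng, length_um=512 * 0.2, duration_ms=512 * 2.0
    )
    spec = synthetic.LineScanSpec(sparks=sparks, noise_sd=100.0, seed=0)
    return synthetic.gen_linescan(spec)


@pytest.fixture(scope="session")
def detected(noisy_linescan):
    """Full spark analysis of the shared noisy line-scan."""
    from myophys import sparks as spark_mod

    img, truth = noisy_linescan
    spark_list, summary = spark_mod.analyze_linescan(img)
    return img, truth, spark_list, summary
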