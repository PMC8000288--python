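import numpy as np
import pandas as pd
import pytest

from perioeval.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and blur-free phantom with a crater defect."""
    return generate_phantom(
        PhantomSpec(height=96, width=96, n_teeth=3, lesion="crater",
                    noise_sd=0.0, blur_sigma=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def textured_phantom():
    """Blurred, noisy phantom used where realistic texture matters."""
    return generate_phantom(
        PhantomSpec(height=96, width=96, n_teeth=3, lesion="horizontal",
                    noise_sd=4.0, blur_sigma=1.2, seed=5)
    )


@pytest.fixture()
def tiny_rating_table():
    """Hand-built rating table: two observers, two images, two methods."""
    rows = [
        ("o1", "expert", "i1", "A", 1),
        ("o1", "expert", "i2", "A", 2),
        ("o1", "expert", "i1", "B", 3),
        ("o1", "expert", "i2", "B", 4),
        ("o2", "lay", "i1", "A", 2),
        ("o2", "lay", "i2", "A", 2),
        ("o2", "lay", "i1", "B", 3),
        ("o2", "lay", "i2", "B", 2),
    ]
    return pd.DataFrame(
        rows, columns=["observer_id", "group", "image_id", "method", "score"]
    )
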