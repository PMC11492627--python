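import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mrtriangle as mt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_variants(n, rng, chromosome="1", prefix="rs"):
    """A small valid summary-statistic frame with random but sane values."""
    beta = rng.normal(0.2, 0.05, size=n) * rng.choice([-1, 1], size=n)
    se = np.full(n, 0.02)
    p = 2 * np.exp(-0.5 * (beta / se) ** 2)  # monotone in |z|, fine for ordering
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}{i + 1:04d}" for i in range(n)],
            "chromosome": chromosome,
            "position": 1_000_000 + 2_000 * np.arange(n),
            "effect_allele": "A",
            "other_allele": "C",
            "eaf": rng.uniform(0.1, 0.9, size=n),
            "beta": beta,
            "se": se,
            "p_value": np.clip(p, 1e-300, 1.0),
            "n": 10_000,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """One toy study written to disk and run through the whole pipeline."""
    outdir = tmp_path_factory.mktemp("toy_study")
    study = mt.simulate_toy_study(seed=3)
    config_path = mt.write_toy_study(study, outdir, seed=3)
    config = mt.load_config(config_path)
    bundle = mt.run_pipeline(config)
    return {
        "study": study,
        "config_path": config_path,
        "config": config,
        "bundle": bundle,
        "outdir": outdir,
    }
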