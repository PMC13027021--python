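import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from deupanel import simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel (study conditions), seed 1."""
    return simulate.generate_panel(simulate.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def clean_recovery_panel():
    """Six-module panel for parameter recovery: noise 0.03, n=300, no planted
    outliers or QC failures."""
    config = simulate.GeneratorConfig(
        n_genes=300, ratio_noise_sd=0.03, outlier_profiles=(),
        n_qc_fail_error=0, n_qc_fail_lowcount=0, seed=7,
    )
    return simulate.generate_panel(config)


def make_counts(rows):
    """Counts DataFrame from (gene, ppm, rep1, rep2) tuples."""
    return pd.DataFrame(rows, columns=["gene_id", "ppm", "rep1", "rep2"])


@pytest.fixture
def four_gene_counts():
    rng = np.random.default_rng(0)
    rows = []
    for g in ("GA", "GB", "GC", "GD"):
        for ppm in (40, 80, 150, 300):
            base = rng.integers(100, 500)
            rows.append((g, ppm, base, base + rng.integers(0, 10)))
    return make_counts(rows)
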