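import numpy as np
import pytest

from polyexpress import synth
from polyexpress.pipeline import demo_config, run_pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort with all eleven carrier groups present."""
    cfg = synth.GeneratorConfig(n_variant_negative=2000, n_snps=120,
                                n_related_pairs=20, n_third_degree_pairs=8, seed=7)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """Two independent end-to-end runs with the same seed, for determinism
    checks and downstream assertions on the bundle."""
    root = tmp_path_factory.mktemp("demo")
    out = []
    for sub in ("a", "b"):
        bundle, manifest = run_pipeline(demo_config(seed=3), root / sub)
        out.append((bundle, manifest, root / sub))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
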