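import numpy as np
import pytest

from depscan.synthetic import PanelConfig, generate_panel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """One small generated panel shared by read-only tests."""
    out = tmp_path_factory.mktemp("panel")
    cfg = PanelConfig(
        n_loci=400,
        n_pos_planted=30,
        n_neg_planted=30,
        effect_tau=0.7,
        dispersion=0.2,
        fp_sites_per_motif=120,
        seed=42,
    )
    truth = generate_panel(cfg, out)
    return out, truth
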