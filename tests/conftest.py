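import pytest

from metx.pipeline import run_screen
from metx.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study: 2000 genes, 5 timepoints x 3 replicates,
    fc_effect 1.5, delta_beta_effect 0.3, fixed seed."""
    cfg = SimConfig(seed=20240901)
    manifest, betas, expr, sheet, truth = generate_dataset(cfg)
    return {"config": cfg, "manifest": manifest, "betas": betas,
            "expr": expr, "sheet": sheet, "truth": truth}


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """Full pipeline result on the default synthetic study."""
    d = default_dataset
    return run_screen(d["manifest"], d["betas"], d["expr"], d["sheet"])


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 300-gene variant for file-level and CLI tests."""
    cfg = SimConfig(n_genes=300, seed=7)
    manifest, betas, expr, sheet, truth = generate_dataset(cfg)
    return {"config": cfg, "manifest": manifest, "betas": betas,
            "expr": expr, "sheet": sheet, "truth": truth}
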