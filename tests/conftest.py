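import numpy as np
import pytest

import stableselect as ss


@pytest.fixture
def tiny_raw(tmp_path):
    """2-sample, 3-SNP .raw file with known entries."""
    path = tmp_path / "tiny.raw"
    path.write_text(
        "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C rs3_G\n"
        "F1 S1 0 0 1 1 0 1 2\n"
        "F2 S2 0 0 2 2 2 NA 1\n"
    )
    return path


@pytest.fixture
def small_cohort():
    """Seeded 200-sample, 60-SNP cohort with one strong causal SNP."""
    cfg = ss.SimulationConfig(
        n_samples=200,
        n_snps=60,
        causal_indices=(0,),
        causal_betas=(float(np.log(3.0)),),
        rng_seed=11,
    )
    G, P, truth = ss.simulate_cohort(cfg)
    return G, P, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
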