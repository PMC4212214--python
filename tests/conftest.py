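import numpy as np
import pytest

from rootshift import (
    ExpressionDataset,
    SampleCondition,
    SimulationConfig,
    Tissue,
    generate_dataset,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 6 samples: two stem-base conditions with 3 replicates each."""
    design = [
        SampleCondition(Tissue.STEM_BASE, 0.0, r) for r in (1, 2, 3)
    ] + [SampleCondition(Tissue.STEM_BASE, 24.0, r) for r in (1, 2, 3)]
    values = np.array(
        [
            [100.0, 110.0, 90.0, 400.0, 420.0, 380.0],
            [500.0, 480.0, 520.0, 500.0, 510.0, 490.0],
            [80.0, 85.0, 75.0, 20.0, 22.0, 18.0],
        ]
    )
    return ExpressionDataset(["cn1774", "GO_drpoolB-CL42Contig2", "g3"], values, design)


@pytest.fixture(scope="session")
def noise_free_run():
    """Full-design noise-free simulation with step identity trajectories.

    All identity switches happen at 72 hpe, so every downstream count is
    exactly predictable.
    """
    config = SimulationConfig(
        n_genes=1500,
        timepoints_hpe=(0, 2, 6, 24, 72, 96, 144, 192),
        replicates=3,
        noise_cv=0.0,
        n_de_per_comparison=0,
        n_stem_identity=40,
        n_root_identity=30,
        stem_decay_schedule=((72.0, 40),),
        root_rise_schedule=((72.0, 30),),
        seed=11,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def noisy_run():
    """Moderate-noise simulation exercising every planted structure."""
    config = SimulationConfig(
        n_genes=3000,
        timepoints_hpe=(0, 2, 24, 72),
        replicates=3,
        noise_cv=0.2,
        n_de_per_comparison=60,
        de_fold=4.0,
        frac_wound_shared=0.5,
        n_stem_identity=40,
        n_root_identity=40,
        seed=7,
    )
    return generate_dataset(config)
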