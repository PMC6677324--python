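import numpy as np
import pytest

from rhythmatac.io import ExpressionMatrix
from rhythmatac.synthetic import (
    SimExpressionConfig,
    SimGenomeConfig,
    simulate_expression,
    simulate_genome,
)

WT_HOURS = np.repeat(np.arange(1, 24, 3), 2).astype(float)


@pytest.fixture(scope="session")
def toy_genome():
    """Small toy genome shared by peak/footprint tests (session-scoped: the
    placement rejection-sampling is the slow part)."""
    cfg = SimGenomeConfig(
        n_scaffolds=2,
        scaffold_len_bp=60_000,
        n_genes=10,
        n_peaks=12,
        n_footprints=15,
        seed=11,
    )
    return cfg, simulate_genome(cfg)


@pytest.fixture(scope="session")
def null_expression():
    cfg = SimExpressionConfig(n_genes=400, frac_rhythmic=0.0, noise_cv=0.2, seed=5)
    return simulate_expression(cfg)


def cosinor_series(hours, mesor=5.0, amp_rel=0.4, phase=7.0, period=24.0):
    return mesor * (1.0 + amp_rel * np.cos(2.0 * np.pi * (hours - phase) / period))
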