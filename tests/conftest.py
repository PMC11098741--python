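import numpy as np
import pytest

from scsnv.simulate import (
    clone_population,
    simulate_cells,
    simulate_panel,
    simulate_sample,
)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_panel(
        n_hap=20, n_sites=120, span_bp=120_000, recomb_intensity=1e-5,
        maf_min=0.05, seed=101,
    )


@pytest.fixture(scope="session")
def small_sample(small_panel):
    return simulate_sample(small_panel, expected_breakpoints=1.0, seed=102)


@pytest.fixture(scope="session")
def small_dataset(small_sample):
    clones = clone_population([0.7, 0.3], 60, seed=103)
    return simulate_cells(
        small_sample, clones, [], mean_depth=2.0, dropout=0.1,
        error_rate=1e-3, read_len=100, zero_inflation=0.3, seed=104,
    )


@pytest.fixture(scope="session")
def somatic_recovery():
    """Median p_s per simulated somatic fraction plus germline p_s scores.

    The conditions of the parameter-recovery design: 500 cells, mean
    depth 5, base-error rate 0.1%, allelic dropout 10%.
    """
    from scsnv.designs import germline_ps_scores, somatic_recovery_calls

    fractions = (0.1, 0.2, 0.3, 0.4)
    ps_by_f = {}
    calls_by_f = {}
    for i, f in enumerate(fractions):
        calls = somatic_recovery_calls(f, seed=1000 + 10 * i)
        calls_by_f[f] = calls
        ps_by_f[f] = np.array([c.ps for c in calls if c.n_informative_cells > 0])
    germline_ps = germline_ps_scores(seed=2000)
    return {"ps_by_f": ps_by_f, "calls_by_f": calls_by_f, "germline_ps": germline_ps}


@pytest.fixture(scope="session")
def tiny_random_matrices():
    """Random small count matrices (<=4 cells x <=5 loci) for oracle checks."""
    from scsnv.ld_refine import CellAlleleMatrix

    rng = np.random.default_rng(7)
    matrices = []
    for _ in range(120):
        n_sites = int(rng.integers(2, 6))
        n_cells = int(rng.integers(1, 5))
        positions = np.sort(rng.choice(np.arange(1, 2_000_000, 50), n_sites, replace=False))
        c1 = rng.integers(0, 3, size=(n_sites, n_cells))
        c2 = (rng.integers(0, 3, size=(n_sites, n_cells)) * (rng.random((n_sites, n_cells)) < 0.6)).astype(int)
        phased = np.ones(n_sites, dtype=bool)
        matrices.append(
            CellAlleleMatrix(positions=positions, c1=c1, c2=c2, phased=phased)
        )
    return matrices
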