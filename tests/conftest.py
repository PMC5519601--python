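import numpy as np
import pandas as pd
import pytest

import envgreml as eg


@pytest.fixture(scope="session")
def pool():
    """Shared genotype pool + GRM for the REML-level tests."""
    G = eg.simulate_genotypes(600, 1000, (0.05, 0.5), seed=11)
    A = eg.compute_grm(G)
    return G, A


@pytest.fixture(scope="session")
def cohort2(pool):
    """K=2 cohort with true h2 = 0.3 per group and r_G = 0.6."""
    G, A = pool
    cfg = eg.gxe_config([300, 300], 0.3, 0.6, G.n_variants, seed=12)
    return eg.simulate_gxe_cohort(G, cfg)


@pytest.fixture(scope="session")
def fitted2(pool, cohort2):
    G, A = pool
    blocks = eg.ModelBlocks.from_cohort(cohort2, A)
    return eg.reml_fit(blocks, A)


@pytest.fixture()
def toy_labels_cohort():
    """Tiny table exercising every breastfed x smoking x sex combination
    plus unknowns."""
    rows = []
    i = 0
    for bf in ("yes", "no"):
        for sm in ("yes", "no"):
            for sex in ("M", "F"):
                for _ in range(3):
                    rows.append((f"s{i}", bf, sm, sex))
                    i += 1
    rows.append((f"s{i}", "unknown", "no", "M"))
    rows.append((f"s{i + 1}", "yes", "unknown", "F"))
    return pd.DataFrame(rows, columns=["sample_id", "breastfed", "maternal_smoking", "sex"])


def hand_grm(dosages):
    """Independent elementwise evaluation of the GRM estimator (complete
    data): A_jk = mean_m (x_jm - 2p_m)(x_km - 2p_m) / (2 p_m (1 - p_m))."""
    n, m = dosages.shape
    p = dosages.mean(axis=0) / 2
    A = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for s in range(m):
                acc += (dosages[j, s] - 2 * p[s]) * (dosages[k, s] - 2 * p[s]) / (
                    2 * p[s] * (1 - p[s])
                )
            A[j, k] = acc / m
    return A
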