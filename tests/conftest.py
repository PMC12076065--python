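import numpy as np
import pandas as pd
import pytest

from droughtring import synth


@pytest.fixture(scope="session")
def small_layout():
    return synth.simulate_design(n_sites=1, n_families=12, n_sets=3, n_blocks=5, seed=11)


@pytest.fixture(scope="session")
def small_study(small_layout):
    """Layout + pedigree + truth + growth for a 12-family single-site trial."""
    ped = synth.build_op_pedigree(small_layout, seed=12)
    specs = {
        t: dict(sigma_a2=v, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0)
        for t, v in [
            ("resist", 0.0064),
            ("recov", 0.0225),
            ("height", 900.0),
            ("d13c", 0.09),
            ("density", 300.0),
        ]
    }
    truth = synth.simulate_genetics(ped, specs, seed=13)
    climate = synth.simulate_climate(seed=14)
    series, traits = synth.simulate_growth(small_layout, climate, truth, seed=15)
    return dict(layout=small_layout, pedigree=ped, truth=truth,
                climate=climate, series=series, traits=traits)


def halfsib_A(n_families, per_family):
    """Block half-sib relationship matrix among offspring (0.25 off-diag)."""
    n = n_families * per_family
    A = np.zeros((n, n))
    for f in range(n_families):
        sl = slice(f * per_family, (f + 1) * per_family)
        A[sl, sl] = 0.25
    np.fill_diagonal(A, 1.0)
    return A


def simulate_halfsib_trait(rng, n_families, per_family, sa2, se2, sb2=0.0, ss2=0.0,
                           n_blocks=5, n_sets=19, mu=10.0):
    """Direct phenotype simulation on a half-sib design with known truth.

    Returns (DataFrame with y/block_id/set_id/tree_id, A DataFrame).
    """
    n = n_families * per_family
    fam = np.repeat(np.arange(n_families), per_family)
    dam_bv = rng.normal(0.0, np.sqrt(sa2), n_families)
    a = 0.5 * dam_bv[fam] + rng.normal(0.0, np.sqrt(0.75 * sa2), n)
    block = rng.integers(0, n_blocks, n)
    sets = rng.integers(0, n_sets, n)
    set_id = block * n_sets + sets
    u_b = rng.normal(0.0, np.sqrt(sb2), n_blocks)
    u_s = rng.normal(0.0, np.sqrt(ss2), n_blocks * n_sets)
    y = mu + a + u_b[block] + u_s[set_id] + rng.normal(0.0, np.sqrt(se2), n)
    ids = [f"T{i}" for i in range(n)]
    df = pd.DataFrame({
        "tree_id": ids,
        "y": y,
        "block_id": [f"B{b}" for b in block],
        "set_id": [f"S{s}" for s in set_id],
        "family": [f"F{f}" for f in fam],
    })
    A = pd.DataFrame(halfsib_A(n_families, per_family), index=ids, columns=ids)
    return df, A, a
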