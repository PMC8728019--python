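import numpy as np
import pytest
from hypothesis import settings

from tagarray import design, ldtag, simgen

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_chain():
    """3-SNP instance: T(A)={A,B,C}, T(B)={A,B}, T(C)={A,C} at q=0.9."""
    return simgen.make_toy_instance("three_snp_chain")


@pytest.fixture(scope="session")
def sim_panel():
    """Mid-sized clean haplotype-block panel (2 founders, 5% missing)."""
    config = simgen.SimConfig(n_samples=120, n_chromosomes=2,
                              blocks_per_chromosome=6, seed=11)
    return simgen.simulate_panel(config)


@pytest.fixture(scope="session")
def sim_design(sim_panel):
    """Full design run on the session panel: (panel, records, selection, ld, order)."""
    panel, records, _ = sim_panel
    selection, ld, order = design.run_design(panel, records)
    return panel, records, selection, ld, order


def random_ld_instance(rng, n_snps=None):
    """Random positions + random sparse symmetric r² table for greedy tests.

    Returns (records, LDTable, F, m, tiers) over a single chromosome.
    """
    from tagarray.genodata import SNPRecord

    n = n_snps or int(rng.integers(5, 31))
    positions = np.sort(rng.choice(np.arange(1, 1_500_000), size=n, replace=False))
    records = [
        SNPRecord(snp_id=f"s{i:02d}", chromosome="chr1", position=int(positions[i]))
        for i in range(n)
    ]
    ids = [r.snp_id for r in records]
    a_list, b_list, r2_list = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            if positions[j] - positions[i] > 1_000_000:
                continue
            if rng.random() < 0.35:
                a_list.append(ids[i])
                b_list.append(ids[j])
                r2_list.append(float(rng.random()))
    table = ldtag.LDTable(a_list, b_list, np.array(r2_list))
    F = {s for s in ids if rng.random() < 0.7}
    m = int(rng.integers(2, 5))
    tiers = ((8, 3), (5, 2), (m, 1))
    return records, table, F, m, tiers
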