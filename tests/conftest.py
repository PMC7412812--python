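import numpy as np
import pytest

from rbpkit.pool import PoolDesignSpec, design_pool


def naive_kmer_counts(seqs, k):
    """Independent dictionary-based k-mer counter (oracle for the audits)."""
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            counts[km] = counts.get(km, 0) + 1
    return counts


@pytest.fixture(scope="session")
def toy_spec():
    # order-5 backbone tiled ~3x deep so the coverage-patch stage has slack
    return PoolDesignSpec(
        order=5,
        probe_count=300,
        variable_length=15,
        min_9mer_count=1,
        min_7mer_per_set=1,
        pool_audit_k=5,
        set_audit_k=3,
        patch_budget_frac=0.05,
    )


@pytest.fixture(scope="session")
def toy_design(toy_spec):
    return design_pool(toy_spec)


@pytest.fixture(scope="session")
def scoring_pool():
    """Mid-sized pool (order 7, 2000 probes) for intensity-scoring tests."""
    spec = PoolDesignSpec(
        order=7,
        probe_count=2000,
        variable_length=35,
        min_9mer_count=1,
        min_7mer_per_set=1,
        pool_audit_k=7,
        set_audit_k=5,
        patch_budget_frac=0.05,
    )
    return design_pool(spec).pool


@pytest.fixture(scope="session")
def spiked_pool():
    """2,000 random-context probes with GCGCGGG planted into 60 of them.

    Random contexts make the spiked 7-mer the only one shared by all its
    carrier probes, so intensity scoring can identify it (a de Bruijn toy
    pool places the 7-mer at a single locus, where its overlapping
    neighbours are inseparable from it).
    """
    from rbpkit.pool import ProbePool, assign_sets

    rng = np.random.default_rng(11)
    n, L = 4000, 35
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    mat = rng.integers(0, 4, size=(n, L))
    seqs = ["".join(chr(alphabet[c]) for c in row) for row in mat]
    planted = rng.choice(n, size=200, replace=False)
    for i in planted:
        pos = int(rng.integers(0, L - 7 + 1))
        seqs[i] = seqs[i][:pos] + "GCGCGGG" + seqs[i][pos + 7 :]
    return assign_sets(ProbePool.from_sequences(seqs))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
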