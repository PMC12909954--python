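import numpy as np
import pytest

from svsieve import cohort_sim as cs
from svsieve.sv_core import MatchParams, SVRecord


@pytest.fixture(scope="session")
def default_params():
    return MatchParams()


@pytest.fixture(scope="session")
def small_cohort():
    """2 quads + 20 controls over a 2,000-locus pool (error-free)."""
    pool = cs.simulate_sv_pool(2000, seed=7)
    ped = cs.PedigreeSpec.standard(n_quads=2, n_controls=20, seed=7)
    sim, truth = cs.simulate_cohort(pool, ped, denovo_rate=0.5, error_rate=0.0, seed=7)
    return pool, ped, sim, truth


def make_random_records(
    rng: np.random.Generator,
    n: int,
    n_samples: int = 5,
    chroms=("chr1", "chr2"),
    span: int = 5000,
    with_seq: bool = True,
):
    """Dense random SV records for collapse/matching oracle tests."""
    from svsieve.config import HET, HOM

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    recs = []
    for i in range(n):
        svtype = ("INS", "DEL", "INV")[rng.integers(0, 3)]
        svlen = int(np.clip(rng.lognormal(np.log(200), 0.8), 50, 3000))
        start = int(rng.integers(0, span))
        end = start if svtype == "INS" else start + svlen
        seq = None
        if with_seq and svtype != "INV" and rng.random() < 0.8:
            seq = bases[rng.integers(0, 4, svlen)].tobytes().decode()
        recs.append(
            (
                SVRecord(
                    sv_id=f"r{i:04d}",
                    chrom=chroms[rng.integers(0, len(chroms))],
                    start=start,
                    end=end,
                    svtype=svtype,
                    svlen=svlen,
                    seq=seq,
                    qual=float(rng.integers(1, 100)),
                    genotype=int(HET if rng.random() < 0.7 else HOM),
                ),
                f"s{rng.integers(0, n_samples)}",
            )
        )
    return recs


def brute_force_partition(entries, p):
    """All-pairs union-find over sv_match edges (the collapse oracle)."""
    from svsieve.config import HET
    from svsieve.sv_core import sv_match

    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (ra, sa), (rb, sb) = entries[i], entries[j]
            if sa == sb and ra.genotype == HET and rb.genotype == HET:
                continue
            if sv_match(ra, rb, p).matched:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return frozenset(
        frozenset(j for j in range(n) if find(j) == root)
        for root in {find(i) for i in range(n)}
    )
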