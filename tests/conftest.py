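import numpy as np
import pytest

from poolscan import fst, simulate
from poolscan.proximity import GeneModel


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One small synthetic study shared across tests (seed-fixed)."""
    cfg = simulate.SimConfig(n_loci=800, n_fixed_difference_loci=20, seed=11)
    out = tmp_path_factory.mktemp("study")
    genes, de, truth = simulate.simulate_study(
        cfg, str(out), n_genes=80, n_planted_deg=8, colocate_fraction=0.5
    )
    return {"cfg": cfg, "dir": str(out), "genes": genes, "de": de, "truth": truth}


@pytest.fixture(scope="session")
def pool_specs():
    return [fst.PoolSpec("SEIZURE", "seizure", 22)] + [
        fst.PoolSpec(f"CONTROL{i + 1}", "control", 10) for i in range(4)
    ]


@pytest.fixture
def plus_gene():
    """A + strand gene on [10_000, 20_000) with two exons."""
    return GeneModel(
        "g1", "G1", "1", 10_000, 20_000, "+",
        exons=((10_000, 12_000), (18_000, 20_000)),
    )


def random_genes(rng: np.random.Generator, n: int, chrom_len: int = 1_000_000):
    """Random (possibly overlapping) gene models for oracle comparisons."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 20_000))
        end = start + int(rng.integers(1_000, 20_000))
        mid = (start + end) // 2
        out.append(
            GeneModel(
                f"r{i}", f"r{i}", str(rng.integers(1, 3)), start, end,
                "+" if rng.random() < 0.5 else "-",
                exons=((start, mid), (mid + 1, end)) if end - mid > 2 else (),
            )
        )
    return out
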