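import numpy as np
import pytest

from cinscreen.signature import CountDataset, GeneSignature


@pytest.fixture
def balanced_dataset() -> CountDataset:
    """Small two-group dataset with identical samples (factors exactly 1)."""
    rng = np.random.default_rng(42)
    n_genes, n = 50, 3
    col = rng.poisson(100, size=n_genes) + 1
    col[0] = 80  # identical in every sample, like all other genes
    counts = np.tile(col[:, None], (1, 2 * n))
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    group_of = {s: ("control" if s.startswith("c") else "treated") for s in samples}
    return CountDataset("demo", [f"g{i}" for i in range(n_genes)], samples, counts, group_of)


@pytest.fixture
def small_signature() -> GeneSignature:
    return GeneSignature(up={"A", "B", "C"}, down={"D", "E"})
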