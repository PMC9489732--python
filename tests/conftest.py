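import numpy as np
import pandas as pd
import pytest

from hyperchrom import GenomicBin, GenomicInterval, Hypergraph, Monomer, MotifTable, MultiwayRead


@pytest.fixture
def worked_example() -> Hypergraph:
    """The two-hyperedge example {v1,v2,v3}, {v3,v4} on four loci."""
    nodes = [GenomicBin("chr1", i, 1_000_000) for i in range(4)]
    return Hypergraph(nodes, [{0, 1, 2}, {2, 3}])


@pytest.fixture
def worked_example_incidence(worked_example) -> np.ndarray:
    from hyperchrom import build_incidence

    return build_incidence(worked_example, weighted=True)


def make_read(read_id: str, loci: list[tuple[str, int, int]]) -> MultiwayRead:
    return MultiwayRead(
        read_id,
        [Monomer(read_id, GenomicInterval(c, s, e)) for c, s, e in loci],
    )


@pytest.fixture
def toy_motifs() -> MotifTable:
    """Three genes x three TFs with a self-binding (master-regulator) TF_A."""
    counts = pd.DataFrame(
        {
            "TF_A": [5, 3, 0],
            "TF_B": [4, 0, 0],
            "TF_C": [0, 0, 2],
        },
        index=["g1", "g2", "g3"],
    )
    return MotifTable(counts, {"TF_A": "g1", "TF_B": "gB"})
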