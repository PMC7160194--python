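import numpy as np
import pytest

from karyotrace import datasets
from karyotrace.tree_io import PhyloTree, parse_newick


@pytest.fixture(scope="session")
def study_tree() -> PhyloTree:
    return datasets.load_study_tree()


@pytest.fixture(scope="session")
def study_records():
    return datasets.load_karyotype_table()


def random_tree(rng: np.random.Generator, n_tips: int,
                allow_polytomy: bool = False,
                with_lengths: bool = False) -> PhyloTree:
    """Random topology by sequential joining; polytomies arise by joining
    three or more subtrees at once when allowed."""
    parts = [f"t{i}" + (f":{rng.uniform(0.1, 2.0):.4f}" if with_lengths else "")
             for i in range(1, n_tips + 1)]
    while len(parts) > 1:
        k = 2
        if allow_polytomy and len(parts) > 2 and rng.random() < 0.3:
            k = int(rng.integers(3, len(parts) + 1))
        picks = sorted(rng.choice(len(parts), size=k, replace=False),
                       reverse=True)
        joined = [parts.pop(i) for i in picks]
        blen = f":{rng.uniform(0.1, 2.0):.4f}" if with_lengths else ""
        parts.append("(" + ",".join(joined) + ")" + blen)
    return parse_newick(parts[0].rsplit(":", 1)[0] + ";"
                        if with_lengths else parts[0] + ";")
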