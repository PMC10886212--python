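import numpy as np
import pandas as pd
import pytest

from selsig import GenotypeMatrix
from selsig.genotype_io import MISSING


def make_matrix(calls, chroms=None, positions=None, populations=None,
                sample_ids=None, vids=None):
    """Build a GenotypeMatrix from a plain nested list of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    chroms = chroms or ["1"] * n_variants
    positions = positions or list(range(1000, 1000 + 1000 * n_variants, 1000))
    populations = populations or ["p1"] * n_samples
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    vids = vids or [f"v{j}" for j in range(n_variants)]
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "vid": vids,
            "ref": ["A"] * n_variants,
            "alt": ["G"] * n_variants,
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples)


@pytest.fixture
def two_pop_matrix():
    """6 samples x 4 variants over two populations, with one missing call."""
    calls = [
        [0, 1, 2, 0],
        [0, 1, 1, 0],
        [1, 2, 2, 0],
        [2, 1, 0, 1],
        [2, 2, 0, MISSING],
        [1, 2, 0, 1],
    ]
    return make_matrix(
        calls,
        populations=["hl", "hl", "hl", "low", "low", "low"],
    )
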